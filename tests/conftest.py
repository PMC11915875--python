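import numpy as np
import pandas as pd
import pytest

from microsurv import (SimulationConfig, batch_center, clr_transform,
                       filter_taxa, simulate_cohorts)


@pytest.fixture(scope="session")
def small_sim():
    """A small two-cohort simulation with strong effects, shared read-only."""
    config = SimulationConfig(n_per_cohort=(80, 50), n_taxa=50, n_causal=4,
                              true_log_hr=0.8, seed=11)
    bundles, truth = simulate_cohorts(config)
    counts = pd.concat([b.counts for b in bundles])
    metadata = pd.concat([b.metadata for b in bundles])
    filtered, _ = filter_taxa(counts)
    clr = batch_center(clr_transform(filtered), metadata["cohort"])
    return {"config": config, "bundles": bundles, "truth": truth,
            "counts": counts, "metadata": metadata, "filtered": filtered,
            "clr": clr}


@pytest.fixture()
def rng():
    return np.random.default_rng(202409)
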