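"""Alpha and beta diversity of the simulated tumors.

Chao1/Shannon/Simpson per sample, rank tests and adjusted linear models
across tumor stage, Cox models of survival on each index, the
Jensen-Shannon distance matrix and covariate-adjusted PERMANOVA on event
status.  In this generator the microbiome affects survival through a few
species, not through community-level diversity, so these tests are
expected to be mostly null.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from microsurv import diversity
from microsurv import io as msio
from microsurv.survival_meta import build_covariate_matrix


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", default="results/analysis/data")
    ap.add_argument("--outdir", default="results/analysis")
    ap.add_argument("--n-perm", type=int, default=999)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    data, out = Path(args.datadir), Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)

    counts = pd.concat([msio.read_counts(p)
                        for p in sorted(data.glob("*_counts.tsv"))])
    meta = pd.concat([msio.read_metadata(p)
                      for p in sorted(data.glob("*_metadata.tsv"))])

    alpha = diversity.alpha_diversity(counts)
    msio.write_matrix(alpha, out / "alpha_diversity.tsv")
    Z, _ = build_covariate_matrix(meta, ("age", "sex", "smoking"))
    tests = diversity.alpha_group_tests(alpha, meta["stage"],
                                        pd.DataFrame(Z, index=meta.index))
    msio.write_matrix(tests, out / "alpha_group_tests.tsv",
                      index_name="index")
    surv = pd.concat({oc: diversity.alpha_survival(alpha, meta, oc)
                      for oc in ("os", "rfs")}, names=["outcome"])
    msio.write_matrix(surv, out / "alpha_survival.tsv",
                      index_name="outcome")

    jsd = diversity.jsd_matrix(counts)
    msio.write_matrix(jsd, out / "jsd.tsv")
    perma = {}
    for oc in ("os", "rfs"):
        Zc, _ = build_covariate_matrix(meta)
        perma[oc] = diversity.permanova(
            jsd, meta[f"{oc}_event"],
            covariates=pd.DataFrame(Zc, index=meta.index),
            n_perm=args.n_perm, strata=meta["cohort"], seed=args.seed)
    (out / "permanova.json").write_text(json.dumps(perma, indent=2))

    print(alpha.describe().loc[["mean", "std"]].round(3))
    print("\nalpha vs stage (rank test p):")
    print(tests[["test", "rank_p", "lm_p"]].round(4))
    print("\nalpha vs survival (pooled Cox):")
    print(surv[["hr", "p_meta"]].round(3))
    for oc, res in perma.items():
        print(f"PERMANOVA {oc}-event: pseudo-F={res['pseudo_F']:.3f}, "
              f"p={res['p']:.3f}")


if __name__ == "__main__":
    main()
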