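"""Taxa filtering, centered log-ratio normalization, batch centering.

Filtering keeps species seen at >= ``min_count`` reads in at least
``min_prevalence`` of samples AND with mean relative abundance >=
``min_mean_relab``, both computed on the pooled cohorts; thresholds are
inclusive, so boundary taxa are retained.  The clr transform adds a
pseudocount (default 1) before taking per-sample log-ratios, making rows
sum to zero.  ``batch_center`` is a deliberately simple cohort-mean
centering of the clr matrix used in place of full distribution-matching
batch correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FilterSpec", "ClrMatrix", "filter_taxa", "clr_transform",
           "batch_center"]


@dataclass(frozen=True)
class FilterSpec:
    """Prevalence/abundance filter thresholds (all inclusive, >=)."""

    min_count: int = 2
    min_prevalence: float = 0.10
    min_mean_relab: float = 1e-5   # 0.001%

    def __post_init__(self):
        if self.min_count < 1:
            raise ValueError("min_count must be a positive integer")
        if not 0 <= self.min_prevalence <= 1:
            raise ValueError("min_prevalence must lie in [0, 1]")
        if not 0 <= self.min_mean_relab <= 1:
            raise ValueError("min_mean_relab must lie in [0, 1]")


@dataclass
class ClrMatrix:
    """clr-transformed abundances; rows (samples) sum to zero."""

    values: pd.DataFrame      # samples x taxa
    pseudocount: float

    def __post_init__(self):
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("clr matrix contains non-finite values")
        rowsums = self.values.sum(axis=1).to_numpy()
        if np.abs(rowsums).max() > 1e-8:
            raise ValueError("clr rows must sum to zero")

    @property
    def taxa(self):
        return list(self.values.columns)

    @property
    def samples(self):
        return list(self.values.index)


def filter_taxa(counts: pd.DataFrame, spec: FilterSpec = FilterSpec()):
    """Apply the prevalence and mean-relative-abundance filter.

    Parameters
    ----------
    counts : samples x taxa non-negative integer frame (pooled cohorts).

    Returns
    -------
    (filtered_counts, report) where report has one row per input taxon with
    its prevalence, mean relative abundance, kept flag and removal reason.
    """
    if counts.size == 0:
        raise ValueError("empty count matrix")
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("negative counts")
    totals = arr.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        bad = counts.index[(totals[:, 0] == 0)][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    prevalence = (arr >= spec.min_count).mean(axis=0)
    mean_relab = (arr / totals).mean(axis=0)
    keep_prev = prevalence >= spec.min_prevalence
    keep_relab = mean_relab >= spec.min_mean_relab
    kept = keep_prev & keep_relab
    reason = np.where(
        kept, "",
        np.where(~keep_prev & ~keep_relab, "prevalence+mean_relab",
                 np.where(~keep_prev, "prevalence", "mean_relab")))
    report = pd.DataFrame({
        "prevalence": prevalence,
        "mean_relab": mean_relab,
        "kept": kept,
        "removal_reason": reason,
    }, index=counts.columns)
    report.index.name = "taxon"
    if not kept.any():
        raise ValueError(
            "all taxa removed by the filter; relax min_count="
            f"{spec.min_count}, min_prevalence={spec.min_prevalence} or "
            f"min_mean_relab={spec.min_mean_relab}")
    return counts.loc[:, kept], report


def clr_transform(counts: pd.DataFrame, pseudocount: float = 1.0) -> ClrMatrix:
    """Centered log-ratio transform after adding a pseudocount.

    clr_i = log(x_i + pc) - mean_j log(x_j + pc), per sample.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = counts.to_numpy(dtype=float) + pseudocount
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return ClrMatrix(pd.DataFrame(clr, index=counts.index,
                                  columns=counts.columns), pseudocount)


def batch_center(clr: ClrMatrix, cohort_labels) -> ClrMatrix:
    """Remove per-cohort per-taxon mean shifts from a clr matrix.

    Subtracts each cohort's per-taxon mean and adds back the grand per-taxon
    mean, so cohorts share location while the overall level is preserved.
    Row sums stay zero because every per-taxon mean vector of a clr matrix
    itself sums to zero across taxa.
    """
    labels = pd.Series(np.asarray(cohort_labels), index=clr.values.index)
    sizes = labels.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index[0]
        raise ValueError(f"cohort {small!r} has fewer than 2 samples")
    vals = clr.values
    grand = vals.mean(axis=0)
    centered = vals.copy()
    for cohort, idx in labels.groupby(labels).groups.items():
        centered.loc[idx] = (vals.loc[idx]
                             - vals.loc[idx].mean(axis=0)
                             + grand)
    return ClrMatrix(centered, clr.pseudocount)
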