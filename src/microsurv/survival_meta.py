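"""Per-species survival associations pooled across cohorts.

The association pipeline for one outcome (OS or RFS):

1. within each cohort, a covariate-adjusted Cox proportional-hazards model
   per species, with the species' clr abundance as the exposure (Efron tie
   handling);
2. cohort-specific log hazard ratios pooled by DerSimonian-Laird
   random-effects meta-analysis, with Cochran's Q heterogeneity test;
3. stability selection: the scan is repeated on random 90% subsamples
   (drawn without replacement within each cohort) and a species' selection
   frequency O_j is the fraction of iterations in which its pooled p-value
   falls below alpha; species with O_j at or above the threshold (default
   0.60 over 100 iterations) are selected;
4. a permutation test re-runs the whole frequency computation on data whose
   outcome pairs are shuffled within cohort, giving permuted frequencies
   P_ij and p_perm,j = (sum_i I(P_ij >= O_j) + 1) / (n_perm + 1), with
   Benjamini-Hochberg q-values across species.

Covariate adjustment uses age (continuous), sex, tumor stage (I/IIA vs
IIB) and smoking status (indicator-coded, "Not reported" kept as an
explicit category).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from microsurv.coxph import CoxFit, cox_fit, cox_fit_batch

__all__ = [
    "CoxFit", "cox_fit", "cox_fit_batch", "MetaEstimate",
    "build_covariate_matrix", "meta_random_effects", "species_associations",
    "SelectionResult", "stability_select", "PermutationSummary",
    "permutation_test", "permutation_pvalues", "bh_fdr",
]

DEFAULT_COVARIATES = ("age", "sex", "stage", "smoking")


def build_covariate_matrix(metadata: pd.DataFrame,
                           covariates=DEFAULT_COVARIATES,
                           extra_columns=()):
    """Numeric design matrix for the adjustment covariates.

    age enters continuously; sex, stage and smoking as indicators
    (reference levels Female, I/IIA, Never; missing smoking is the explicit
    "Not reported" level).  ``extra_columns`` are passed through as given.
    Constant columns (e.g. a level absent from a cohort) are dropped.
    """
    pieces = []
    names = []
    for cov in covariates:
        if cov == "age":
            pieces.append(metadata["age"].to_numpy(dtype=float)[:, None])
            names.append("age")
        elif cov == "sex":
            pieces.append((metadata["sex"] == "Male")
                          .to_numpy(dtype=float)[:, None])
            names.append("sex_male")
        elif cov == "stage":
            pieces.append((metadata["stage"] == "IIB")
                          .to_numpy(dtype=float)[:, None])
            names.append("stage_IIB")
        elif cov == "smoking":
            smoking = metadata["smoking"].fillna("Not reported")
            for level in ("Current", "Former", "Not reported"):
                pieces.append((smoking == level)
                              .to_numpy(dtype=float)[:, None])
                names.append(f"smoking_{level.replace(' ', '_')}")
        else:
            pieces.append(metadata[cov].to_numpy(dtype=float)[:, None])
            names.append(cov)
    for col in extra_columns:
        pieces.append(np.asarray(metadata[col], dtype=float)[:, None])
        names.append(col)
    Z = np.hstack(pieces) if pieces else np.empty((len(metadata), 0))
    keep = [j for j in range(Z.shape[1]) if np.ptp(Z[:, j]) > 0]
    return Z[:, keep], [names[j] for j in keep]


@dataclass(frozen=True)
class MetaEstimate:
    """DerSimonian-Laird pooled effect for one species."""

    beta_pooled: float
    se_pooled: float
    tau2: float
    q_stat: float
    p_het: float
    p_meta: float
    k: int

    @property
    def hr(self):
        return float(np.exp(self.beta_pooled))

    @property
    def ci95(self):
        return (float(np.exp(self.beta_pooled - 1.96 * self.se_pooled)),
                float(np.exp(self.beta_pooled + 1.96 * self.se_pooled)))


def _dl_pool(betas, ses):
    """Vectorized DerSimonian-Laird pooling.

    betas, ses: (k, S) per-study estimates; returns dict of (S,) arrays.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    k = betas.shape[0]
    w = 1.0 / ses ** 2
    sw = w.sum(axis=0)
    beta_fixed = (w * betas).sum(axis=0) / sw
    q = (w * (betas - beta_fixed) ** 2).sum(axis=0)
    df = k - 1
    if df > 0:
        denom = sw - (w ** 2).sum(axis=0) / sw
        with np.errstate(invalid="ignore", divide="ignore"):
            tau2 = np.maximum(0.0, (q - df) / denom)
        p_het = stats.chi2.sf(q, df)
    else:
        tau2 = np.zeros_like(q)
        p_het = np.ones_like(q)
    wstar = 1.0 / (ses ** 2 + tau2)
    swstar = wstar.sum(axis=0)
    pooled = (wstar * betas).sum(axis=0) / swstar
    se_pooled = 1.0 / np.sqrt(swstar)
    z = pooled / se_pooled
    p_meta = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    return {"beta": pooled, "se": se_pooled, "tau2": tau2, "q": q,
            "p_het": p_het, "p_meta": p_meta, "k": k}


def meta_random_effects(fits) -> MetaEstimate:
    """Pool a list of per-cohort :class:`CoxFit` results (DL method)."""
    fits = list(fits)
    if not fits:
        raise ValueError("no cohort fits to pool")
    res = _dl_pool(np.array([[f.beta] for f in fits]),
                   np.array([[f.se] for f in fits]))
    return MetaEstimate(float(res["beta"][0]), float(res["se"][0]),
                        float(res["tau2"][0]), float(res["q"][0]),
                        float(res["p_het"][0]), float(res["p_meta"][0]),
                        len(fits))


def _cohort_blocks(clr: pd.DataFrame, metadata: pd.DataFrame, outcome: str,
                   covariates=DEFAULT_COVARIATES):
    """Split aligned clr/metadata into per-cohort numpy blocks."""
    if not clr.index.equals(metadata.index):
        metadata = metadata.loc[clr.index]
    blocks = []
    for cohort in metadata["cohort"].unique():
        mask = (metadata["cohort"] == cohort).to_numpy()
        sub = metadata.loc[mask]
        Z, _ = build_covariate_matrix(sub, covariates)
        blocks.append({
            "cohort": cohort,
            "time": sub[f"{outcome}_time"].to_numpy(dtype=float),
            "event": sub[f"{outcome}_event"].to_numpy(dtype=int),
            "W": clr.loc[mask].to_numpy(dtype=float),
            "Z": Z,
            "ids": np.asarray(sub.index),
        })
    return blocks


def _scan(blocks, rows_per_block=None, ties="efron"):
    """Batched per-species fits per cohort; returns (k,S) beta/se/converged."""
    betas, ses, conv = [], [], []
    for b, block in enumerate(blocks):
        if rows_per_block is None:
            rows = slice(None)
        else:
            rows = rows_per_block[b]
        time = block["time"][rows]
        event = block["event"][rows]
        if event.sum() < 2:
            S = block["W"].shape[1]
            betas.append(np.zeros(S))
            ses.append(np.full(S, np.inf))
            conv.append(np.zeros(S, dtype=bool))
            continue
        res = cox_fit_batch(time, event, block["W"][rows], block["Z"][rows],
                            ties=ties)
        betas.append(res["beta"])
        ses.append(res["se"])
        conv.append(res["converged"])
    return np.array(betas), np.array(ses), np.array(conv)


def species_associations(clr: pd.DataFrame, metadata: pd.DataFrame,
                         outcome: str = "os",
                         covariates=DEFAULT_COVARIATES,
                         ties: str = "efron") -> pd.DataFrame:
    """Full-data per-species association table for one outcome.

    One row per species: per-cohort beta/se/HR/CI/p, pooled HR with CI,
    p_meta, heterogeneity Q and P-het, and the number of converged cohort
    fits.  Pooling uses the converged cohort fits only.
    """
    blocks = _cohort_blocks(clr, metadata, outcome, covariates)
    betas, ses, conv = _scan(blocks, ties=ties)
    S = clr.shape[1]
    out = {}
    for b, block in enumerate(blocks):
        tag = block["cohort"]
        z = np.divide(betas[b], ses[b], out=np.zeros(S), where=ses[b] > 0)
        out[f"beta_{tag}"] = betas[b]
        out[f"se_{tag}"] = ses[b]
        out[f"hr_{tag}"] = np.exp(betas[b])
        out[f"p_{tag}"] = np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1)
        out[f"converged_{tag}"] = conv[b]

    pooled = np.full(S, np.nan)
    se_p = np.full(S, np.nan)
    tau2 = np.full(S, np.nan)
    qstat = np.full(S, np.nan)
    p_het = np.full(S, np.nan)
    p_meta = np.full(S, np.nan)
    n_conv = conv.sum(axis=0)
    for s in range(S):
        ok = conv[:, s]
        if not ok.any():
            continue
        res = _dl_pool(betas[ok][:, [s]], ses[ok][:, [s]])
        pooled[s] = res["beta"][0]
        se_p[s] = res["se"][0]
        tau2[s] = res["tau2"][0]
        qstat[s] = res["q"][0]
        p_het[s] = res["p_het"][0]
        p_meta[s] = res["p_meta"][0]
    out.update({
        "beta_pooled": pooled, "se_pooled": se_p,
        "hr_pooled": np.exp(pooled),
        "hr_ci_low": np.exp(pooled - 1.96 * se_p),
        "hr_ci_high": np.exp(pooled + 1.96 * se_p),
        "tau2": tau2, "q_het": qstat, "p_het": p_het, "p_meta": p_meta,
        "n_converged_cohorts": n_conv,
    })
    return pd.DataFrame(out, index=clr.columns)


@dataclass
class SelectionResult:
    """Stability-selection frequencies O_j and selected species."""

    frequency: pd.Series          # O_j in [0, 1], per species
    selected: pd.Series           # O_j >= threshold
    n_iter: int
    subsample_frac: float
    alpha: float
    threshold: float
    outcome: str
    n_failed_cohort_iterations: int = 0

    @property
    def selected_taxa(self):
        return list(self.selected.index[self.selected])


def _subsample_rows(blocks, frac, rng):
    """Without-replacement subsample within each cohort, by sorted sample id.

    Drawing from the id-sorted order makes the chosen sample sets invariant
    to the row order of the input.
    """
    rows = []
    for block in blocks:
        order = np.argsort(block["ids"])
        m = int(round(frac * len(order)))
        chosen = rng.choice(len(order), size=m, replace=False)
        rows.append(np.sort(order[chosen]))
    return rows


def _selection_frequencies(blocks, n_iter, frac, alpha, rng, ties="efron"):
    """Fraction of subsample iterations with p_meta < alpha, per species.

    A species counts as significant in an iteration only when every cohort
    fit converged there (non-convergence is conservative, never a hit).
    """
    S = blocks[0]["W"].shape[1]
    hits = np.zeros(S)
    failed = 0
    for _ in range(n_iter):
        rows = _subsample_rows(blocks, frac, rng)
        betas, ses, conv = _scan(blocks, rows, ties=ties)
        all_conv = conv.all(axis=0)
        if not all_conv.all():
            failed += 1
        res = _dl_pool(betas, ses)
        hits += all_conv & (res["p_meta"] < alpha)
    return hits / n_iter, failed


def stability_select(clr: pd.DataFrame, metadata: pd.DataFrame,
                     outcome: str = "os", n_iter: int = 100,
                     frac: float = 0.9, alpha: float = 0.05,
                     threshold: float = 0.60, seed: int = 0,
                     covariates=DEFAULT_COVARIATES,
                     ties: str = "efron") -> SelectionResult:
    """Repeated-subsampling stability selection of survival-associated taxa.

    For each of ``n_iter`` iterations, ``frac`` of each cohort's samples are
    drawn without replacement, the per-species cohort Cox fits are pooled by
    random-effects meta-analysis, and species with pooled p < ``alpha`` are
    marked.  O_j is each species' marked fraction; species with
    O_j >= ``threshold`` are selected.  Deterministic under ``seed``.
    """
    blocks = _cohort_blocks(clr, metadata, outcome, covariates)
    rng = np.random.default_rng(seed)
    freq, failed = _selection_frequencies(blocks, n_iter, frac, alpha, rng,
                                          ties)
    freq = pd.Series(freq, index=clr.columns, name="O_j")
    return SelectionResult(freq, freq >= threshold, n_iter, frac, alpha,
                           threshold, outcome, failed)


@dataclass
class PermutationSummary:
    """Permutation-calibrated significance of the selection frequencies."""

    p_perm: pd.Series             # in [1/(n_perm+1), 1]
    q_value: pd.Series            # BH over species
    permuted_frequencies: np.ndarray = field(repr=False)  # (n_perm, S)
    n_perm: int = 0


def permutation_test(clr: pd.DataFrame, metadata: pd.DataFrame,
                     outcome: str, observed: SelectionResult,
                     n_perm: int = 500, seed: int = 0,
                     covariates=DEFAULT_COVARIATES,
                     ties: str = "efron",
                     permute: str = "outcomes") -> PermutationSummary:
    """Permutation analogue of the stability-selection frequencies.

    Each permutation shuffles the (time, event) outcome pairs against the
    exposure/covariate rows within each cohort (``permute="outcomes"``; with
    ``"abundances"`` the clr rows are shuffled instead, leaving the
    covariate-outcome link intact), then re-runs the full subsampling
    frequency computation with the observed run's n_iter/frac/alpha.

    p_perm,j = (sum_i I(P_ij >= O_j) + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if permute not in ("outcomes", "abundances"):
        raise ValueError(f"unknown permutation scheme {permute!r}")
    blocks = _cohort_blocks(clr, metadata, outcome, covariates)
    rng = np.random.default_rng(seed)
    o_j = observed.frequency.to_numpy()
    S = len(o_j)
    pfreqs = np.empty((n_perm, S))
    for i in range(n_perm):
        perm_blocks = []
        for block in blocks:
            nb = len(block["time"])
            perm = rng.permutation(nb)
            newb = dict(block)
            if permute == "outcomes":
                newb["time"] = block["time"][perm]
                newb["event"] = block["event"][perm]
            else:
                newb["W"] = block["W"][perm]
            perm_blocks.append(newb)
        pfreqs[i], _ = _selection_frequencies(
            perm_blocks, observed.n_iter, observed.subsample_frac,
            observed.alpha, rng, ties)
    p_perm = pd.Series(permutation_pvalues(pfreqs, o_j),
                       index=observed.frequency.index, name="p_perm")
    q = bh_fdr(p_perm)
    return PermutationSummary(p_perm, q, pfreqs, n_perm)


def permutation_pvalues(permuted_frequencies, observed_frequencies):
    """p_j = (sum_i I(P_ij >= O_j) + 1) / (n_perm + 1).

    ``permuted_frequencies`` is (n_perm, S); the +1 in numerator and
    denominator counts the observed data as one more permutation, so the
    smallest attainable p is 1/(n_perm+1) and an observed frequency of 0
    yields exactly 1.
    """
    pfreqs = np.atleast_2d(np.asarray(permuted_frequencies, dtype=float))
    o_j = np.asarray(observed_frequencies, dtype=float)
    n_perm = pfreqs.shape[0]
    exceed = (pfreqs >= o_j[None, :] - 1e-12).sum(axis=0)
    return (exceed + 1) / (n_perm + 1)


def bh_fdr(pvalues) -> pd.Series:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = pd.Series(pvalues)
    if p.empty:
        raise ValueError("no p-values to adjust")
    _, q, _, _ = multipletests(p.to_numpy(), method="fdr_bh")
    return pd.Series(q, index=p.index, name="q_value")
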