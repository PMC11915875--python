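"""Microbial Risk Score (MRS) construction and survival assessment.

The MRS for an outcome is a per-sample weighted sum of the clr-normalized
abundances of the stability-selected species, the weights being their
pooled (random-effects) Cox log hazard ratios, z-scored across the combined
cohorts.  It is assessed with covariate-adjusted Cox models (per cohort,
pooled by the same meta-analysis machinery) and by a median split with
Kaplan-Meier curves and the log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from microsurv.coxph import CoxFit, cox_fit, partial_loglik
from microsurv.survival_meta import (DEFAULT_COVARIATES, MetaEstimate,
                                     SelectionResult, build_covariate_matrix,
                                     meta_random_effects)

__all__ = ["MRSVector", "build_mrs", "cox_mrs", "KMResult", "km_logrank",
           "stratified_rerun"]


@dataclass
class MRSVector:
    """Z-scored per-sample Microbial Risk Score with its weight map."""

    score: pd.Series              # z-scored over the combined samples
    raw_score: pd.Series
    weights: dict[str, float]     # selected species -> pooled log-HR
    outcome_tag: str

    def __post_init__(self):
        if abs(float(self.score.mean())) > 1e-8:
            raise ValueError("MRS must have mean 0 after z-scoring")
        if abs(float(self.score.std(ddof=0)) - 1.0) > 1e-8:
            raise ValueError("MRS must have unit variance after z-scoring")

    @property
    def raw_sd(self):
        return float(self.raw_score.std(ddof=0))


def build_mrs(clr: pd.DataFrame, selection: SelectionResult, meta,
              outcome_tag: str | None = None) -> MRSVector:
    """Weighted sum of selected species' clr abundances, z-scored.

    ``meta`` supplies the weights (pooled log hazard ratios): either the
    association table from :func:`~microsurv.survival_meta.
    species_associations` (its ``beta_pooled`` column) or a mapping
    species -> :class:`MetaEstimate` / float.
    """
    taxa = selection.selected_taxa
    if not taxa:
        raise ValueError("no selected species: MRS is undefined")
    if isinstance(meta, pd.DataFrame):
        weights = {t: float(meta.loc[t, "beta_pooled"]) for t in taxa}
    else:
        weights = {
            t: float(v.beta_pooled) if isinstance(v, MetaEstimate)
            else float(v)
            for t, v in ((t, meta[t]) for t in taxa)}
    w = np.array([weights[t] for t in taxa])
    raw = pd.Series(clr[taxa].to_numpy() @ w, index=clr.index,
                    name="raw_mrs")
    sd = raw.std(ddof=0)
    if sd == 0:
        raise ValueError("MRS is constant across samples")
    score = (raw - raw.mean()) / sd
    score.name = "mrs"
    tag = outcome_tag or ("Mortality" if selection.outcome == "os"
                          else "Relapse")
    return MRSVector(score, raw, weights, tag)


def cox_mrs(mrs: MRSVector, metadata: pd.DataFrame, outcome: str,
            covariates=DEFAULT_COVARIATES, per_cohort: bool = True):
    """Covariate-adjusted Cox model of survival on the MRS.

    With ``per_cohort=True`` (default) the model is fitted within each
    cohort and the log hazard ratios are pooled by random-effects
    meta-analysis; the return value is ``(pooled MetaEstimate, dict of
    per-cohort CoxFit)``.  Otherwise a single combined fit with a cohort
    indicator among the covariates is returned as a :class:`CoxFit`.

    The hazard ratio is per 1 SD of the z-scored score; divide the log-HR
    by ``mrs.raw_sd`` for the per-raw-unit effect.
    """
    meta = metadata.loc[mrs.score.index]
    time = meta[f"{outcome}_time"]
    event = meta[f"{outcome}_event"]
    if per_cohort:
        fits = {}
        for cohort, sub in meta.groupby("cohort"):
            Z, _ = build_covariate_matrix(sub, covariates)
            try:
                fits[cohort] = cox_fit(time.loc[sub.index],
                                       event.loc[sub.index],
                                       mrs.score.loc[sub.index], Z)
            except ValueError as exc:
                warnings.warn(f"cohort {cohort!r} excluded from MRS "
                              f"pooling: {exc}")
        pooled = meta_random_effects(
            [f for f in fits.values() if f.converged])
        return pooled, fits
    Z, _ = build_covariate_matrix(meta, covariates)
    cohort_dummies = pd.get_dummies(meta["cohort"], drop_first=True,
                                    dtype=float).to_numpy()
    Z = np.hstack([Z, cohort_dummies]) if cohort_dummies.size else Z
    return cox_fit(time, event, mrs.score, Z)


@dataclass
class KMResult:
    """Kaplan-Meier curves and two-group log-rank test for a median split."""

    curves: pd.DataFrame          # columns: group, time, survival, at_risk
    median_survival: dict[str, float]   # NaN when never reaching S<=0.5
    logrank_chi2: float
    logrank_p: float
    lr_p: float                   # likelihood-ratio p from the Cox deviance
    groups: pd.Series = field(repr=False)


def km_logrank(mrs: MRSVector, metadata: pd.DataFrame,
               outcome: str) -> KMResult:
    """Median-split Kaplan-Meier analysis of the MRS.

    High risk is score > median, ties go to the low-risk group.  Median
    survival per group is the earliest time with S <= 0.5 (NaN and flagged
    by a warning when a group never reaches it).  Alongside the log-rank
    test, a likelihood-ratio p-value from the deviance of the two-group Cox
    model is reported.
    """
    meta = metadata.loc[mrs.score.index]
    time = meta[f"{outcome}_time"].to_numpy(dtype=float)
    event = meta[f"{outcome}_event"].to_numpy(dtype=int)
    if event.sum() < 1:
        raise ValueError("no events for Kaplan-Meier analysis")
    med = float(mrs.score.median())
    groups = pd.Series(np.where(mrs.score > med, "high", "low"),
                       index=mrs.score.index, name="risk_group")

    frames = []
    medians = {}
    for g in ("low", "high"):
        mask = (groups == g).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=g)
        surv = kmf.survival_function_[g]
        at_risk = kmf.event_table["at_risk"].reindex(surv.index)
        frames.append(pd.DataFrame({
            "group": g, "time": surv.index.to_numpy(),
            "survival": surv.to_numpy(),
            "at_risk": at_risk.to_numpy()}))
        m = kmf.median_survival_time_
        if np.isinf(m):
            warnings.warn(f"median survival undefined for group {g!r} "
                          "(curve never reaches 0.5)")
            m = np.nan
        medians[g] = float(m)
    curves = pd.concat(frames, ignore_index=True)

    hi = (groups == "high").to_numpy()
    lr = logrank_test(time[hi], time[~hi], event[hi], event[~hi])
    # deviance-based p: two-group Cox model vs null
    ind = hi.astype(float)
    fit = cox_fit(time, event, ind) if ind.std() > 0 else None
    if fit is not None and fit.converged:
        ll0 = partial_loglik(time, event)
        lr_chi2 = 2.0 * (fit.loglik - ll0)
        lr_p = float(stats.chi2.sf(max(lr_chi2, 0.0), 1))
    else:
        lr_p = np.nan
    return KMResult(curves, medians, float(lr.test_statistic),
                    float(lr.p_value), lr_p, groups)


def stratified_rerun(mrs: MRSVector, metadata: pd.DataFrame, outcome: str,
                     strata_variable: str,
                     covariates=DEFAULT_COVARIATES,
                     min_events: int = 2) -> pd.DataFrame:
    """Re-fit the MRS Cox model within each level of a stratifying variable.

    The stratifying variable is dropped from the adjustment set inside its
    own strata.  Strata with fewer than ``min_events`` events are skipped
    with a warning.  Returns one row per retained stratum with the pooled
    HR, CI and p.
    """
    meta = metadata.loc[mrs.score.index]
    covs = tuple(c for c in covariates if c != strata_variable)
    rows = []
    for level, sub in meta.groupby(strata_variable):
        n_events = int(sub[f"{outcome}_event"].sum())
        if len(sub) == 0 or n_events < min_events:
            warnings.warn(
                f"stratum {strata_variable}={level!r} skipped "
                f"({n_events} events)")
            continue
        sub_mrs = MRSVector.__new__(MRSVector)  # re-slice without re-zscore
        object.__setattr__(sub_mrs, "score", mrs.score.loc[sub.index])
        object.__setattr__(sub_mrs, "raw_score", mrs.raw_score.loc[sub.index])
        object.__setattr__(sub_mrs, "weights", mrs.weights)
        object.__setattr__(sub_mrs, "outcome_tag", mrs.outcome_tag)
        try:
            pooled, _ = cox_mrs(sub_mrs, sub, outcome, covs, per_cohort=True)
        except ValueError as exc:
            warnings.warn(
                f"stratum {strata_variable}={level!r} skipped: {exc}")
            continue
        rows.append({"stratum": f"{strata_variable}={level}",
                     "n": len(sub), "n_events": n_events,
                     "hr": pooled.hr, "ci_low": pooled.ci95[0],
                     "ci_high": pooled.ci95[1], "p_meta": pooled.p_meta})
    return pd.DataFrame(rows)
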