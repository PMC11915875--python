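"""Links between the microbiome, immune infiltration and gene expression.

Immune-cell fractions (CIBERSORT-style 22-column table) are binarized at
their per-cell-type median and regressed on the continuous MRS by logistic
models adjusted for the clinical covariates — either a single combined
model with a cohort indicator, or per-cohort fits pooled by random-effects
meta-analysis of the log odds ratios.  Species-level relationships use
Spearman rank correlations of clr abundances against cell fractions or
gene expression.  A minimal hypergeometric over-representation analysis
covers pathway enrichment of microbiome-correlated genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from microsurv.survival_meta import (DEFAULT_COVARIATES, _dl_pool,
                                     bh_fdr, build_covariate_matrix)

__all__ = ["binarize_by_median", "logistic_assoc", "spearman_matrix",
           "hypergeom_ora"]


def binarize_by_median(values) -> pd.Series:
    """1 where the value exceeds the median, else 0 (ties count as low)."""
    v = pd.Series(values).astype(float)
    if v.nunique() < 2:
        raise ValueError("constant column cannot be median-binarized")
    return (v > v.median()).astype(int)


def _fit_logistic(y, x, Z):
    """Logistic ML fit; returns (log-OR, se, p, separated flag)."""
    X = sm.add_constant(np.column_stack([x, Z]), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.
                PerfectSeparationError):
            return np.nan, np.inf, np.nan, True
    beta = fit.params[1]
    se = fit.bse[1]
    separated = (not fit.mle_retvals.get("converged", True)
                 or not np.isfinite(se) or se > 50 or abs(beta) > 50)
    p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else np.nan
    return float(beta), float(se), p, separated


def logistic_assoc(immune: pd.DataFrame, mrs, metadata: pd.DataFrame,
                   covariates=DEFAULT_COVARIATES,
                   mode: str = "meta") -> pd.DataFrame:
    """Logistic regression of median-binarized immune infiltrates on the MRS.

    One row per cell type: odds ratio per 1 SD of the MRS with Wald CI and
    p-value.  ``mode="meta"`` fits per cohort and pools log-ORs by
    DerSimonian-Laird; ``mode="combined"`` fits one model with a cohort
    indicator.  Perfect separation is flagged and the CI reported as
    unbounded.
    """
    if mode not in ("meta", "combined"):
        raise ValueError(f"unknown mode {mode!r}")
    score = mrs.score if hasattr(mrs, "score") else pd.Series(mrs)
    meta = metadata.loc[score.index]
    rows = []
    for cell in immune.columns:
        try:
            y_all = binarize_by_median(immune.loc[score.index, cell])
        except ValueError:
            rows.append({"cell_type": cell, "or": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan, "separated": False,
                         "note": "constant"})
            continue
        if mode == "combined":
            Z, _ = build_covariate_matrix(meta, covariates)
            dummies = pd.get_dummies(meta["cohort"], drop_first=True,
                                     dtype=float).to_numpy()
            Zc = np.hstack([Z, dummies]) if dummies.size else Z
            beta, se, p, sep = _fit_logistic(
                y_all.to_numpy(), score.to_numpy(), Zc)
        else:
            betas, ses = [], []
            sep = False
            for _, sub in meta.groupby("cohort"):
                y = y_all.loc[sub.index].to_numpy()
                if len(np.unique(y)) < 2:
                    continue
                Z, _ = build_covariate_matrix(sub, covariates)
                b, s, _, flagged = _fit_logistic(
                    y, score.loc[sub.index].to_numpy(), Z)
                if flagged or not np.isfinite(b):
                    sep = sep or flagged
                    continue
                betas.append(b)
                ses.append(s)
            if betas:
                pooled = _dl_pool(np.array(betas)[:, None],
                                  np.array(ses)[:, None])
                beta, se = pooled["beta"][0], pooled["se"][0]
                p = pooled["p_meta"][0]
            else:
                beta, se, p = np.nan, np.inf, np.nan
        with np.errstate(over="ignore"):
            rows.append({
                "cell_type": cell,
                "or": float(np.exp(beta)) if np.isfinite(beta) else np.nan,
                "ci_low": float(np.exp(beta - 1.96 * se))
                if np.isfinite(beta) and np.isfinite(se) else np.nan,
                "ci_high": float(np.exp(beta + 1.96 * se))
                if np.isfinite(beta) and np.isfinite(se) else np.nan,
                "p": p, "separated": bool(sep), "note": "",
            })
    return pd.DataFrame(rows).set_index("cell_type")


def spearman_matrix(features: pd.DataFrame,
                    targets: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation of every feature against every target.

    Flat table with one row per (feature, target) pair: tie-corrected r and
    p; constant vectors yield NaN r with a flag instead of an error.
    """
    common = features.index.intersection(targets.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired observations")
    F = features.loc[common]
    T = targets.loc[common]
    rows = []
    for f in F.columns:
        x = F[f].to_numpy(dtype=float)
        for t in T.columns:
            y = T[t].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"feature": f, "target": t, "r": np.nan,
                             "p": np.nan, "constant_input": True})
                continue
            r, p = stats.spearmanr(x, y)
            rows.append({"feature": f, "target": t, "r": float(r),
                         "p": float(p), "constant_input": False})
    return pd.DataFrame(rows)


def hypergeom_ora(query_genes, universe, gene_sets: dict) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in gene sets.

    Upper-tail p-value per set (probability of an overlap at least as large
    given the universe), Benjamini-Hochberg adjusted across sets.
    """
    query = set(query_genes)
    if not query:
        raise ValueError("empty query gene list")
    uni = set(universe)
    if not query <= uni:
        raise ValueError("query genes must be a subset of the universe")
    M = len(uni)
    N = len(query)
    rows = []
    for name, genes in gene_sets.items():
        members = set(genes) & uni
        n = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append({"gene_set": name, "set_size": n, "overlap": k,
                     "expected": N * n / M if M else np.nan,
                     "p": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("gene_set")
    out["q"] = bh_fdr(out["p"]).to_numpy()
    return out
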