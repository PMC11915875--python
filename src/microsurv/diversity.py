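"""Alpha diversity, Jensen-Shannon beta diversity, PERMANOVA, rarefaction.

Alpha indices follow the usual ecology conventions: bias-corrected Chao1
(S_obs + F1(F1-1)/(2(F2+1))), Shannon entropy in nats, Simpson as
1 - sum p^2.  Beta diversity is the Jensen-Shannon divergence (natural log,
bounded by log 2).  Group significance on the distance matrix is assessed
by a distance-based PERMANOVA that fits covariates first (sequential sums
of squares) and permutes the variable of interest, optionally within
cohort strata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, mannwhitneyu
from skbio.diversity.alpha import chao1, shannon, simpson

from microsurv.coxph import CoxFit

__all__ = ["alpha_diversity", "alpha_group_tests", "alpha_survival",
           "jsd_matrix", "permanova", "rarefaction_curves"]


def alpha_diversity(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Chao1, Shannon (nats) and Simpson (1 - sum p^2) indices."""
    arr = counts.to_numpy()
    if (arr.sum(axis=1) == 0).any():
        bad = counts.index[arr.sum(axis=1) == 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    rows = []
    for row in arr:
        rows.append({
            "chao1": chao1(row, bias_corrected=True),
            "shannon": shannon(row, base=np.e),
            "simpson": simpson(row),
        })
    return pd.DataFrame(rows, index=counts.index)


def alpha_group_tests(alpha: pd.DataFrame, grouping,
                      covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Rank tests plus covariate-adjusted linear models per alpha index.

    Two groups are compared with the Wilcoxon rank-sum test, more with
    Kruskal-Wallis.  The adjusted model regresses the index on group
    membership and the covariate design; for two groups the group
    coefficient and its p-value are reported, otherwise a partial F-test of
    the group dummies.
    """
    import statsmodels.api as sm

    groups = pd.Series(np.asarray(grouping), index=alpha.index)
    levels = groups.dropna().unique()
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    small = groups.value_counts() < 2
    if small.any():
        raise ValueError(f"group {small.idxmax()!r} has fewer than 2 samples")

    dummies = pd.get_dummies(groups, drop_first=True, dtype=float)
    rows = []
    for index_name in alpha.columns:
        vals = alpha[index_name]
        samples = [vals[groups == lv].to_numpy() for lv in levels]
        if len(levels) == 2:
            stat, p_rank = mannwhitneyu(*samples, alternative="two-sided")
            test = "wilcoxon"
        else:
            stat, p_rank = kruskal(*samples)
            test = "kruskal-wallis"

        X = dummies
        if covariates is not None:
            X = pd.concat([dummies, covariates.loc[alpha.index]], axis=1)
        X = sm.add_constant(X.astype(float))
        fit = sm.OLS(vals.to_numpy(), X.to_numpy()).fit()
        if len(levels) == 2:
            lm_coef = fit.params[1]
            lm_p = fit.pvalues[1]
        else:
            k = dummies.shape[1]
            contrast = np.zeros((k, X.shape[1]))
            contrast[:, 1:k + 1] = np.eye(k)
            lm_coef = np.nan
            lm_p = float(fit.f_test(contrast).pvalue)
        rows.append({"index": index_name, "test": test,
                     "rank_stat": float(stat), "rank_p": float(p_rank),
                     "lm_coef": float(lm_coef) if np.isfinite(lm_coef)
                     else np.nan,
                     "lm_p": float(lm_p)})
    return pd.DataFrame(rows).set_index("index")


def alpha_survival(alpha: pd.DataFrame, metadata: pd.DataFrame,
                   outcome: str = "os") -> pd.DataFrame:
    """Cohort-wise Cox models of survival on each alpha index, DL-pooled."""
    from microsurv.survival_meta import (build_covariate_matrix, cox_fit,
                                         meta_random_effects)

    rows = []
    for index_name in alpha.columns:
        fits = []
        for _, sub in metadata.groupby("cohort"):
            Z, _ = build_covariate_matrix(sub)
            fits.append(cox_fit(sub[f"{outcome}_time"],
                                sub[f"{outcome}_event"],
                                alpha.loc[sub.index, index_name], Z))
        est = meta_random_effects([f for f in fits if f.converged])
        rows.append({"index": index_name, "hr": float(np.exp(est.beta_pooled)),
                     "beta": est.beta_pooled, "se": est.se_pooled,
                     "p_meta": est.p_meta, "p_het": est.p_het})
    return pd.DataFrame(rows).set_index("index")


def jsd_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jensen-Shannon divergence (natural log) between samples."""
    arr = counts.to_numpy(dtype=float)
    totals = arr.sum(axis=1)
    if (totals == 0).any():
        bad = counts.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    rel = arr / totals[:, None]
    # scipy's jensenshannon is the square root of the divergence
    dist = squareform(pdist(rel, metric="jensenshannon") ** 2)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=counts.index, columns=counts.index)


def _hat(X):
    return X @ np.linalg.pinv(X)


def _rank(X):
    return np.linalg.matrix_rank(X)


def _encode_variable(variable, index):
    v = pd.Series(np.asarray(variable), index=index)
    if v.nunique() < 2:
        raise ValueError("PERMANOVA variable is constant")
    if v.dtype.kind in "ifu" and v.nunique() > 2:
        return v.to_numpy(dtype=float)[:, None]
    return pd.get_dummies(v, drop_first=True, dtype=float).to_numpy()


def permanova(beta: pd.DataFrame, variable, covariates=None,
              n_perm: int = 10_000, strata=None, seed: int = 0) -> dict:
    """Distance-based PERMANOVA with covariates fitted first.

    Partitions the Gower-centered inner-product matrix of the (squared)
    distances sequentially: covariates, then the variable of interest.
    The permutation p-value shuffles the variable's rows (within strata if
    given), keeping covariates attached to samples:
    p = (#{F_perm >= F_obs} + 1) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    D = beta.to_numpy(dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J

    ones = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(pd.DataFrame(covariates).loc[beta.index],
                       dtype=float)
        X0 = np.hstack([ones, C])
    else:
        X0 = ones
    V = _encode_variable(variable, beta.index)
    H0G_tr = np.trace(_hat(X0) @ G)
    r0 = _rank(X0)
    ss_total = np.trace(G)

    def f_stat(Vperm):
        X1 = np.hstack([X0, Vperm])
        tr1 = np.trace(_hat(X1) @ G)
        r1 = _rank(X1)
        df_var = r1 - r0
        df_res = n - r1
        if df_var <= 0 or df_res <= 0:
            return np.nan, np.nan, np.nan
        ss_var = tr1 - H0G_tr
        ss_res = ss_total - tr1
        return (ss_var / df_var) / (ss_res / df_res), ss_var, ss_res

    f_obs, ss_var, ss_res = f_stat(V)
    rng = np.random.default_rng(seed)
    if strata is None:
        strata_groups = [np.arange(n)]
    else:
        s = pd.Series(np.asarray(strata), index=beta.index)
        strata_groups = [np.flatnonzero((s == lv).to_numpy())
                         for lv in s.unique()]
    count = 0
    for _ in range(n_perm):
        perm = np.arange(n)
        for idx in strata_groups:
            perm[idx] = idx[rng.permutation(len(idx))]
        f_perm, _, _ = f_stat(V[perm])
        if f_perm >= f_obs - 1e-12:
            count += 1
    return {
        "pseudo_F": float(f_obs),
        "p": (count + 1) / (n_perm + 1),
        "ss_variable": float(ss_var),
        "ss_residual": float(ss_res),
        "n_perm": n_perm,
    }


def rarefaction_curves(counts: pd.DataFrame, depths, n_draws: int = 10,
                       seed: int = 0) -> pd.DataFrame:
    """Mean observed richness under subsampling without replacement.

    Returns a samples x depths frame of mean richness over ``n_draws``
    random subsamples at each depth; raises if a depth exceeds a sample's
    total count (naming that sample).
    """
    rng = np.random.default_rng(seed)
    depths = list(depths)
    arr = counts.to_numpy().astype(np.int64)
    out = np.zeros((arr.shape[0], len(depths)))
    for i, row in enumerate(arr):
        total = int(row.sum())
        for j, d in enumerate(depths):
            if d > total:
                raise ValueError(
                    f"depth {d} exceeds total count {total} of sample "
                    f"{counts.index[i]!r}")
            rich = [np.count_nonzero(
                rng.multivariate_hypergeometric(row, int(d)))
                for _ in range(n_draws)]
            out[i, j] = np.mean(rich)
    return pd.DataFrame(out, index=counts.index, columns=depths)
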