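"""Cox proportional-hazards engine for per-feature survival scans.

Implements Newton-Raphson maximization of the Cox partial likelihood with
Efron (default) or Breslow handling of tied event times.  The engine is
batched: many models that share the same covariate block but differ in a
single exposure column (one microbial species each) are fitted
simultaneously, which is what makes repeated-subsampling stability selection
and its permutation analogue tractable (tens of thousands of fits per
analysis).

Monotone partial likelihoods (e.g. all exposed subjects failing first) do
not have a finite maximizer; such fits are returned with ``converged=False``
rather than raising, so that scan-level callers can discard them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CoxFit", "cox_fit", "cox_fit_batch", "partial_loglik"]

_MAX_ABS_BETA = 20.0  # |log-HR| beyond this is treated as divergence
_MAX_ITER = 40
_TOL = 1e-9


@dataclass(frozen=True)
class CoxFit:
    """Result of a single Cox proportional-hazards fit.

    ``beta`` is the log hazard ratio of the exposure (first column of the
    design); ``ci95`` is the Wald interval on the hazard-ratio scale and
    ``p`` the two-sided normal test on ``beta/se``.
    """

    beta: float
    se: float
    hr: float
    ci95: tuple[float, float]
    p: float
    converged: bool
    n_events: int
    loglik: float

    @classmethod
    def from_beta_se(cls, beta, se, converged, n_events, loglik=np.nan):
        with np.errstate(over="ignore"):
            hr = float(np.exp(beta))
            lo, hi = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
        z = beta / se if se > 0 else np.inf
        p = float(2.0 * stats.norm.sf(abs(z)))
        p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
        return cls(float(beta), float(se), hr, (float(lo), float(hi)), p,
                   bool(converged), int(n_events), float(loglik))


class _SurvivalLayout:
    """Pre-sorted survival data with tie-group bookkeeping.

    Samples are sorted by descending time so that the risk set at any event
    time is a prefix of the sorted arrays.  Groups are blocks of identical
    times; Efron corrections need the event members of each group.
    """

    def __init__(self, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if time.ndim != 1 or time.shape != event.shape:
            raise ValueError("time and event must be aligned 1-D arrays")
        if np.any(time < 0):
            raise ValueError("negative survival times")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        self.n = time.size
        self.n_events = int(event.sum())
        if self.n_events == 0:
            raise ValueError("no events: Cox model is undefined")
        # stable descending sort, events placed after censored at equal time
        # (irrelevant for the likelihood; groups are by time only)
        self.order = np.argsort(-time, kind="stable")
        t_sorted = time[self.order]
        self.event_sorted = event[self.order].astype(bool)
        # group boundaries over identical times
        new_group = np.empty(self.n, dtype=bool)
        new_group[0] = True
        new_group[1:] = t_sorted[1:] != t_sorted[:-1]
        self.group_start = np.flatnonzero(new_group)
        self.group_end = np.append(self.group_start[1:], self.n)


def _nll_grad_hess(layout, X, beta, ties):
    """Efron/Breslow partial log-likelihood, gradient, Hessian for a batch.

    X: (n, S, p) design per species (sorted order); beta: (S, p).
    Returns ll (S,), grad (S, p), hess (S, p, p) of the log-likelihood.
    """
    n, S, p = X.shape
    eta = np.einsum("nsp,sp->ns", X, beta)
    np.clip(eta, -200, 200, out=eta)
    r = np.exp(eta)

    ll = np.zeros(S)
    grad = np.zeros((S, p))
    hess = np.zeros((S, p, p))

    run_r = np.zeros(S)
    run_rx = np.zeros((S, p))
    run_rxx = np.zeros((S, p, p))

    efron = ties == "efron"
    for start, end in zip(layout.group_start, layout.group_end):
        blk = slice(start, end)
        rb = r[blk]                       # (m, S)
        xb = X[blk]                       # (m, S, p)
        rxb = rb[:, :, None] * xb
        run_r += rb.sum(axis=0)
        run_rx += rxb.sum(axis=0)
        run_rxx += np.einsum("msp,msq->spq", rxb, xb)

        ev = layout.event_sorted[blk]
        d = int(ev.sum())
        if d == 0:
            continue
        xe = xb[ev]                       # (d, S, p)
        ll += eta[blk][ev].sum(axis=0)
        grad += xe.sum(axis=0)

        if efron and d > 1:
            t_r = rb[ev].sum(axis=0)
            t_rx = rxb[ev].sum(axis=0)
            t_rxx = np.einsum("msp,msq->spq", rxb[ev], xb[ev])
            fracs = np.arange(d) / d
        else:
            t_r = t_rx = t_rxx = None
            fracs = np.zeros(d)  # Breslow: d copies of the full risk-set term

        for frac in fracs:
            if t_r is None or frac == 0.0:
                denom, num, sq = run_r, run_rx, run_rxx
            else:
                denom = run_r - frac * t_r
                num = run_rx - frac * t_rx
                sq = run_rxx - frac * t_rxx
            ll -= np.log(denom)
            w = num / denom[:, None]
            grad -= w
            hess -= sq / denom[:, None, None] - w[:, :, None] * w[:, None, :]
    return ll, grad, hess


def cox_fit_batch(time, event, exposures, covariates=None, ties="efron"):
    """Fit one Cox model per exposure column, sharing the covariate block.

    Parameters
    ----------
    time, event : (n,) arrays
    exposures : (n, S) array, one model per column (its coefficient is the
        reported log hazard ratio)
    covariates : optional (n, q) array of adjustment columns
    ties : "efron" or "breslow"

    Returns
    -------
    dict with (S,) arrays ``beta``, ``se``, ``p``, ``converged``, ``loglik``
    and scalar ``n_events``.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    W = np.atleast_2d(np.asarray(exposures, dtype=float))
    if W.shape[0] == 1 and np.asarray(time).size != 1:
        W = W.T
    n, S = W.shape
    layout = _SurvivalLayout(time, event)
    if layout.n != n:
        raise ValueError("exposures not aligned to time/event")
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != n:
            Z = Z.T
    p = 1 + Z.shape[1]

    # sorted design, (n, S, p); exposure in column 0
    X = np.empty((n, S, p))
    X[:, :, 0] = W[layout.order]
    X[:, :, 1:] = Z[layout.order][:, None, :]

    beta = np.zeros((S, p))
    converged = np.zeros(S, dtype=bool)
    diverged = np.zeros(S, dtype=bool)
    ll, grad, hess = _nll_grad_hess(layout, X, beta, ties)
    for _ in range(_MAX_ITER):
        active = ~(converged | diverged)
        if not active.any():
            break
        info = -hess
        # guard singular information (e.g. constant exposure in a subsample)
        try:
            step = np.linalg.solve(info, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.einsum(
                "spq,sq->sp", np.linalg.pinv(info), grad)
        bad = ~np.isfinite(step).all(axis=1)
        step[bad] = 0.0
        diverged |= bad
        new_beta = np.where(active[:, None], beta + step, beta)
        new_ll, new_grad, new_hess = _nll_grad_hess(layout, X, new_beta, ties)
        # step-halving where the likelihood decreased
        for _half in range(5):
            worse = active & (new_ll < ll - 1e-12)
            if not worse.any():
                break
            step[worse] *= 0.5
            new_beta = np.where(active[:, None], beta + step, beta)
            new_ll, new_grad, new_hess = _nll_grad_hess(
                layout, X, new_beta, ties)
        moved = np.abs(new_beta - beta).max(axis=1)
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        diverged |= np.abs(beta[:, 0]) > _MAX_ABS_BETA
        diverged |= ~np.isfinite(beta).all(axis=1)
        converged |= active & ~diverged & (moved < _TOL)

    info = -hess
    se = np.full(S, np.nan)
    ok = np.zeros(S, dtype=bool)
    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(info)
            var0 = cov[:, 0, 0]
            ok = np.isfinite(var0) & (var0 > 0)
            se[ok] = np.sqrt(var0[ok])
        except np.linalg.LinAlgError:
            for s in range(S):
                try:
                    v = np.linalg.inv(info[s])[0, 0]
                    if np.isfinite(v) and v > 0:
                        se[s] = np.sqrt(v)
                        ok[s] = True
                except np.linalg.LinAlgError:
                    pass
    # a flat (monotone) likelihood can "converge" numerically at a large
    # beta with a near-singular information matrix; a log-HR SE this large
    # means the effect is unidentified, so flag it as non-convergence
    ok &= np.nan_to_num(se, nan=np.inf) < 1e3
    converged = converged & ~diverged & ok
    z = np.divide(beta[:, 0], se, out=np.full(S, np.inf), where=se > 0)
    pvals = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    return {
        "beta": beta[:, 0],
        "se": se,
        "p": pvals,
        "converged": converged,
        "loglik": ll,
        "n_events": layout.n_events,
        "coef_full": beta,
    }


def partial_loglik(time, event, X=None, beta=None, ties="efron"):
    """Cox partial log-likelihood at a given coefficient vector.

    With ``X=None`` (or ``beta=None``) returns the null log-likelihood of
    the empty model, the reference point of likelihood-ratio tests.
    """
    layout = _SurvivalLayout(time, event)
    n = layout.n
    if X is None or beta is None:
        Xs = np.zeros((n, 1, 1))
        b = np.zeros((1, 1))
    else:
        X2 = np.atleast_2d(np.asarray(X, dtype=float))
        if X2.shape[0] != n:
            X2 = X2.T
        Xs = X2[layout.order][:, None, :]
        b = np.atleast_2d(np.asarray(beta, dtype=float))
    ll, _, _ = _nll_grad_hess(layout, Xs, b, ties)
    return float(ll[0])


def cox_fit(time, event, exposure, covariates=None, ties="efron") -> CoxFit:
    """Fit a covariate-adjusted Cox model for a single exposure.

    Raises on a constant exposure or on data with no events; a monotone
    likelihood is flagged via ``converged=False`` instead of raising.
    """
    exposure = np.asarray(exposure, dtype=float)
    if np.ptp(exposure) == 0:
        raise ValueError("constant exposure: hazard ratio is unidentifiable")
    res = cox_fit_batch(time, event, exposure[:, None], covariates, ties)
    beta, se = res["beta"][0], res["se"][0]
    if not res["converged"][0]:
        se = res["se"][0] if np.isfinite(res["se"][0]) else np.inf
    return CoxFit.from_beta_se(beta, se, res["converged"][0],
                               res["n_events"], res["loglik"][0])
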