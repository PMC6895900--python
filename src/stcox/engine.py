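"""Per-stratum Cox partial likelihood machinery and unpenalized comparators.

The partial likelihood uses the Breslow convention for ties: the risk set
at an event time t is every subject with observed time >= t, so with the
stratum sorted ascending by time all risk-set sums are suffix sums,
computed in a single reverse cumulative-sum pass. Linear predictors are
max-shifted before exponentiation, so no overflow occurs for |x'beta| up
to ~700.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import PanelData, StratumData

__all__ = [
    "StratumDerivatives",
    "stratum_loglik",
    "stratum_gradient",
    "stratum_diag_curvature",
    "stratum_derivatives",
    "total_loglik",
    "fit_stratum_mle",
    "fit_separate",
    "fit_pooled",
    "concatenate_strata",
]


@dataclass
class StratumDerivatives:
    """Log partial likelihood, its gradient, and the diagonal of its Hessian."""

    loglik: float
    gradient: np.ndarray  # (m,)
    diag_curvature: np.ndarray  # (m,), entries <= 0


def _risk_starts(s: StratumData) -> tuple[np.ndarray, np.ndarray]:
    """Indices of event rows and, for each, the start of its (suffix) risk set."""
    ev = np.flatnonzero(s.events == 1)
    starts = np.searchsorted(s.times, s.times[ev], side="left")
    return ev, starts


def _check_beta(s: StratumData, beta: np.ndarray) -> np.ndarray:
    beta = np.asarray(beta, dtype=float).ravel()
    if s.n and beta.size != s.m:
        raise ValueError(f"beta has length {beta.size}, stratum has {s.m} covariates")
    return beta


def stratum_derivatives(s: StratumData, beta: np.ndarray) -> StratumDerivatives:
    """Log-likelihood, gradient and diagonal curvature in one suffix-sum pass."""
    beta = _check_beta(s, beta)
    if s.n == 0 or s.n_events == 0:
        m = beta.size
        return StratumDerivatives(0.0, np.zeros(m), np.zeros(m))
    X = s.covariates
    eta = X @ beta
    shift = eta.max()
    w = np.exp(eta - shift)
    # suffix sums: S0[k] = sum_{l >= k} w_l, similarly for x*w and x^2*w
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((X * w[:, None])[::-1], axis=0)[::-1]
    s2 = np.cumsum((X * X * w[:, None])[::-1], axis=0)[::-1]
    ev, starts = _risk_starts(s)
    d0 = s0[starts]
    mean1 = s1[starts] / d0[:, None]
    mean2 = s2[starts] / d0[:, None]
    loglik = float(np.sum(eta[ev] - (np.log(d0) + shift)))
    grad = (X[ev] - mean1).sum(axis=0)
    curv = -(mean2 - mean1 * mean1).sum(axis=0)
    return StratumDerivatives(loglik, grad, np.minimum(curv, 0.0))


def stratum_loglik(s: StratumData, beta: np.ndarray) -> float:
    """Breslow log partial likelihood of one stratum at ``beta``."""
    return stratum_derivatives(s, beta).loglik


def stratum_gradient(s: StratumData, beta: np.ndarray) -> np.ndarray:
    return stratum_derivatives(s, beta).gradient


def stratum_diag_curvature(s: StratumData, beta: np.ndarray) -> np.ndarray:
    return stratum_derivatives(s, beta).diag_curvature


def stratum_hessian(s: StratumData, beta: np.ndarray) -> np.ndarray:
    """Full m x m Hessian of the log partial likelihood (negative semidefinite)."""
    beta = _check_beta(s, beta)
    m = beta.size
    if s.n == 0 or s.n_events == 0:
        return np.zeros((m, m))
    X = s.covariates
    eta = X @ beta
    w = np.exp(eta - eta.max())
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((X * w[:, None])[::-1], axis=0)[::-1]
    outer = X[:, :, None] * X[:, None, :] * w[:, None, None]
    s2 = np.cumsum(outer[::-1], axis=0)[::-1]
    ev, starts = _risk_starts(s)
    H = np.zeros((m, m))
    for st in starts:
        mu = s1[st] / s0[st]
        H -= s2[st] / s0[st] - np.outer(mu, mu)
    return H


def total_loglik(panel: PanelData, beta_grid: np.ndarray) -> float:
    """Sum of stratum log partial likelihoods over the whole p x q grid."""
    beta_grid = np.asarray(beta_grid, dtype=float)
    return sum(stratum_loglik(s, beta_grid[i, j]) for i, j, s in panel.cells())


def fit_stratum_mle(
    s: StratumData,
    gtol: float = 1e-6,
    max_iter: int = 50,
    max_step: float = 5.0,
    separation_threshold: float = 10.0,
) -> tuple[np.ndarray, bool, int]:
    """Unpenalized Cox MLE for a single stratum by full-Hessian Newton-Raphson.

    Returns ``(beta_hat, converged, iterations)``. Convergence means the
    gradient max-norm fell below ``gtol`` at a plausible iterate. Under
    monotone likelihood (separation) the gradient only vanishes as
    ``|beta| -> inf``; iterates whose max absolute coordinate exceeds
    ``separation_threshold`` (log hazard-ratio 10, i.e. a hazard ratio
    above 22000) are therefore flagged ``converged=False`` and returned
    rather than raising, since small registry cells routinely exhibit
    separation.
    """
    if s.n_events == 0:
        raise ValueError("no events in stratum")
    m = s.m
    beta = np.zeros(m)
    ll = stratum_loglik(s, beta)
    for it in range(1, max_iter + 1):
        g = stratum_gradient(s, beta)
        if np.abs(g).max() < gtol:
            return beta, bool(np.abs(beta).max() <= separation_threshold), it - 1
        H = stratum_hessian(s, beta)
        diag = np.abs(np.diag(H))
        if (diag < 1e-12).any():
            k = int(np.argmin(diag))
            raise ValueError(f"singular Hessian: covariate {k} is degenerate in this stratum")
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            raise ValueError("singular Hessian: covariates are collinear in this stratum")
        nrm = np.linalg.norm(step)
        if nrm > max_step:
            step *= max_step / nrm
        # halve until the likelihood does not decrease
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new = stratum_loglik(s, cand)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        beta, ll = beta + t * step, ll_new
    converged = bool(
        np.abs(stratum_gradient(s, beta)).max() < gtol
        and np.abs(beta).max() <= separation_threshold
    )
    return beta, converged, max_iter


def fit_separate(panel: PanelData, gtol: float = 1e-6, max_iter: int = 50):
    """Per-cell unpenalized Cox MLEs (the heterogeneity-preserving comparator).

    Returns ``(beta_grid, flags)`` where ``beta_grid`` is (p, q, m) and
    ``flags`` is a (p, q) boolean mask marking cells that could not be
    estimated cleanly: empty cells and cells with no events or a
    degenerate covariate get NaN, cells hitting the iteration cap
    (monotone likelihood) keep their capped estimate. Flagged cells never
    raise.
    """
    beta = np.full((panel.p, panel.q, panel.m), np.nan)
    flags = np.zeros((panel.p, panel.q), dtype=bool)
    for i, j, s in panel.cells():
        if s.n == 0 or s.n_events == 0:
            flags[i, j] = True
            continue
        try:
            b, conv, _ = fit_stratum_mle(s, gtol=gtol, max_iter=max_iter)
        except ValueError:
            flags[i, j] = True
            continue
        beta[i, j] = b
        if not conv:
            flags[i, j] = True
    return beta, flags


def concatenate_strata(strata: list[StratumData]) -> StratumData:
    """Merge strata into one (single common risk set), re-sorting canonically."""
    times = np.concatenate([s.times for s in strata]) if strata else np.empty(0)
    events = np.concatenate([s.events for s in strata]) if strata else np.empty(0, dtype=int)
    X = np.vstack([s.covariates for s in strata]) if strata else np.empty((0, 0))
    return StratumData(times, events, X)


def fit_pooled(panel: PanelData, mode: str, gtol: float = 1e-6, max_iter: int = 50) -> np.ndarray:
    """Pooled Cox fits: concatenate cells across the pooled dimension(s).

    mode='over_locations' pools all locations within each period (q vectors,
    shape (q, m)); 'over_times' pools all periods within each location
    ((p, m)); 'over_both' pools everything ((1, m)).
    """
    if mode == "over_locations":
        groups = [[panel.cell(i, j) for i in range(panel.p)] for j in range(panel.q)]
    elif mode == "over_times":
        groups = [[panel.cell(i, j) for j in range(panel.q)] for i in range(panel.p)]
    elif mode == "over_both":
        groups = [[s for _, _, s in panel.cells()]]
    else:
        raise ValueError(f"unknown pooling mode {mode!r}")
    out = np.empty((len(groups), panel.m))
    for g, members in enumerate(groups):
        pooled = concatenate_strata(members)
        if pooled.n_events == 0:
            raise ValueError(f"pooled group {g} has no events")
        out[g], _, _ = fit_stratum_mle(pooled, gtol=gtol, max_iter=max_iter)
    return out
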