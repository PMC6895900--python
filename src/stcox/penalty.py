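"""Spatial weights and the two-part quadratic smoothing penalty.

The penalty on a (p, q, m) coefficient grid is

    P(beta) = 1/2 * lambda1 * sum_i sum_{j>=2} g_{j-1} ||beta_{i,j} - beta_{i,j-1}||^2
            + 1/2 * lambda2 * sum_j sum_{i<r} omega_{i,r} ||beta_{i,j} - beta_{r,j}||^2

i.e. a fused (first-difference) ridge along consecutive time periods and a
Laplacian-type ridge over location pairs weighted by inverse distance
omega = 1/d. The optional per-gap temporal weights g (default all 1) let
non-consecutive periods be penalized more weakly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import validate_distance_matrix

__all__ = [
    "PenaltyConfig",
    "weights_from_distances",
    "penalty_value",
    "penalty_gradient_block",
    "shrink_diagonal",
]


@dataclass
class PenaltyConfig:
    """Tuning parameters of the smoothing penalty.

    lambda1 >= 0 scales the temporal fused penalty, lambda2 >= 0 the
    spatial one; gap_weights (length q-1, positive) optionally reweight
    each consecutive-period difference.
    """

    lambda1: float = 1.0
    lambda2: float = 1.0
    gap_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be nonnegative")
        if self.gap_weights is not None:
            self.gap_weights = np.asarray(self.gap_weights, dtype=float).ravel()
            if (self.gap_weights <= 0).any():
                raise ValueError("gap_weights must be positive")

    def gaps(self, q: int) -> np.ndarray:
        if self.gap_weights is None:
            return np.ones(max(q - 1, 0))
        if self.gap_weights.size != q - 1:
            raise ValueError(f"gap_weights must have length q-1 = {q - 1}")
        return self.gap_weights


def weights_from_distances(d: np.ndarray) -> np.ndarray:
    """Inverse-distance spatial weights omega[i, r] = 1 / d[i, r], zero diagonal."""
    d = validate_distance_matrix(d)
    w = np.zeros_like(d)
    off = ~np.eye(d.shape[0], dtype=bool)
    w[off] = 1.0 / d[off]
    return w


def _check_grid(beta: np.ndarray) -> np.ndarray:
    beta = np.asarray(beta, dtype=float)
    if beta.ndim != 3:
        raise ValueError(f"coefficient grid must be (p, q, m), got shape {beta.shape}")
    return beta


def penalty_value(beta: np.ndarray, omega: np.ndarray, cfg: PenaltyConfig) -> float:
    beta = _check_grid(beta)
    p, q, m = beta.shape
    if omega.shape != (p, p):
        raise ValueError(f"omega shape {omega.shape} does not match p={p}")
    val = 0.0
    if q > 1 and cfg.lambda1 > 0:
        diffs = beta[:, 1:] - beta[:, :-1]  # (p, q-1, m)
        g = cfg.gaps(q)
        val += 0.5 * cfg.lambda1 * float(np.einsum("ijm,ijm,j->", diffs, diffs, g))
    if p > 1 and cfg.lambda2 > 0:
        iu, ru = np.triu_indices(p, k=1)
        d2 = ((beta[iu] - beta[ru]) ** 2).sum(axis=2)  # (n_pairs, q)
        val += 0.5 * cfg.lambda2 * float((omega[iu, ru][:, None] * d2).sum())
    return val


def _temporal_terms(beta, i, j, cfg):
    """(coef on beta_ij, weighted neighbor sum) of the temporal penalty gradient."""
    p, q, m = beta.shape
    g = cfg.gaps(q)
    coef, nb = 0.0, np.zeros(m)
    if q > 1:
        if j > 0:
            coef += g[j - 1]
            nb += g[j - 1] * beta[i, j - 1]
        if j < q - 1:
            coef += g[j]
            nb += g[j] * beta[i, j + 1]
    return cfg.lambda1 * coef, cfg.lambda1 * nb


def _spatial_terms(beta, i, j, omega, cfg):
    p = beta.shape[0]
    wsum = float(omega[i].sum())  # diagonal is zero
    nb = omega[i] @ beta[:, j]
    return cfg.lambda2 * wsum, cfg.lambda2 * nb


def penalty_gradient_block(
    beta: np.ndarray, i: int, j: int, omega: np.ndarray, cfg: PenaltyConfig
) -> np.ndarray:
    """dP/d(beta_{i,j}): the block of the penalty gradient for one cell."""
    beta = _check_grid(beta)
    tc, tnb = _temporal_terms(beta, i, j, cfg)
    sc, snb = _spatial_terms(beta, i, j, omega, cfg)
    return (tc + sc) * beta[i, j] - tnb - snb


def shrink_diagonal(i: int, j: int, omega: np.ndarray, cfg: PenaltyConfig, q: int) -> float:
    """Diagonal shrinkage constant c_{i,j} of the block-wise closed-form update.

    Equals 2*lambda1 + lambda2 * sum_{r != i} omega_{i,r} for interior
    periods and lambda1 + lambda2 * sum omega at j=0 or j=q-1 (uniform gap
    weights); the lambda1 part vanishes when q=1.
    """
    g = cfg.gaps(q)
    coef = 0.0
    if q > 1:
        if j > 0:
            coef += g[j - 1]
        if j < q - 1:
            coef += g[j]
    return cfg.lambda1 * coef + cfg.lambda2 * float(omega[i].sum())
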