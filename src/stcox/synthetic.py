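"""Survival-panel simulator with known coefficient surfaces.

Emulates the structure of multi-registry cancer survival data: a p x q
grid of (location, period) strata, mixed continuous/binary covariates,
proportional-hazards event times with an exponential baseline, and
uniform right censoring calibrated to a target censoring fraction. The
true coefficient surface is either *smooth* (affine in the period index
and in the first spatial coordinate, the regime the smoothing penalty is
designed for) or *abrupt* (independent random sign flips cell to cell, a
worst case for smoothing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import PanelData, StratumData, validate_distance_matrix

__all__ = ["SimConfig", "SimulatedPanel", "make_locations", "make_coefficient_surface", "simulate_panel"]


@dataclass
class SimConfig:
    p: int = 4
    q: int = 5
    n_continuous: int = 4
    n_binary: int = 4
    n_per_cell: int = 100  # scalar or (p, q) array
    baseline_rate: float = 1.0
    target_censoring: float = 0.3
    surface: str = "smooth"  # or "abrupt"
    effect_scale: float = 1.0
    location_layout: str = "grid"  # or "unit_square_random"
    seed: int = 0

    @property
    def m(self) -> int:
        return self.n_continuous + self.n_binary

    def cell_sizes(self) -> np.ndarray:
        n = np.asarray(self.n_per_cell)
        if n.ndim == 0:
            return np.full((self.p, self.q), int(n))
        if n.shape != (self.p, self.q):
            raise ValueError(f"n_per_cell table must be (p, q) = {(self.p, self.q)}")
        return n.astype(int)


@dataclass
class SimulatedPanel:
    panel: PanelData
    truth: np.ndarray  # (p, q, m)
    distances: np.ndarray  # (p, p)
    coordinates: np.ndarray  # (p, 2)
    realized_censoring: float


def make_locations(p: int, layout: str = "grid", seed: int = 0):
    """Place p locations in the unit square; return (coordinates, distances)."""
    rng = np.random.default_rng(seed)
    if layout == "grid":
        side = int(np.ceil(np.sqrt(p)))
        axis = np.linspace(0.0, 1.0, side) if side > 1 else np.array([0.5])
        xx, yy = np.meshgrid(axis, axis, indexing="ij")
        coords = np.column_stack([xx.ravel(), yy.ravel()])[:p]
    elif layout == "unit_square_random":
        for _ in range(100):
            coords = rng.uniform(0.0, 1.0, size=(p, 2))
            diff = coords[:, None] - coords[None, :]
            dmin = np.sqrt((diff**2).sum(-1))[~np.eye(p, dtype=bool)].min()
            if dmin > 1e-6:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not place distinct locations")
    else:
        raise ValueError(f"unknown layout {layout!r}")
    diff = coords[:, None] - coords[None, :]
    d = np.sqrt((diff**2).sum(-1))
    return coords, validate_distance_matrix(d)


def make_coefficient_surface(
    p: int, q: int, m: int, coordinates: np.ndarray,
    surface: str = "smooth", effect_scale: float = 1.0, seed: int = 0,
) -> np.ndarray:
    """True (p, q, m) coefficient grid, deterministic given the seed.

    Smooth mode: beta[i, j, l] = a_l + b_l * (j)/(q-1) + c_l * s_i with s_i
    the first spatial coordinate and a, b, c drawn uniform on (-1, 1),
    rescaled by a single grid-wide factor so the maximum absolute
    coefficient equals ``effect_scale``. Abrupt mode: independent
    +-effect_scale signs per cell and covariate.
    """
    rng = np.random.default_rng(seed)
    if effect_scale == 0:
        return np.zeros((p, q, m))
    if surface == "smooth":
        a, b, c = rng.uniform(-1.0, 1.0, size=(3, m))
        t = (np.arange(q) / (q - 1)) if q > 1 else np.zeros(1)
        s = coordinates[:, 0]
        beta = a[None, None, :] + b[None, None, :] * t[None, :, None] + c[None, None, :] * s[:, None, None]
        return beta * (effect_scale / np.abs(beta).max())
    if surface == "abrupt":
        signs = rng.choice([-1.0, 1.0], size=(p, q, m))
        return effect_scale * signs
    raise ValueError(f"unknown surface {surface!r}")


def _calibrate_cmax(T: np.ndarray, target: float, tol: float = 0.01) -> float:
    """Bisection for the uniform-censoring upper bound c.

    With C ~ Uniform(0, c), the expected censoring fraction given the
    event-time sample T is f(c) = mean(min(T, c)) / c, which decreases
    monotonically from 1 to 0; solve f(c) = target to ``tol``.
    """
    def frac(c):
        return float(np.minimum(T, c).mean() / c)

    lo, hi = 1e-9, float(T.max()) + 1.0
    while frac(hi) > target:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f = frac(mid)
        if abs(f - target) <= tol * 0.1:
            return mid
        if f > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_panel(cfg: SimConfig) -> SimulatedPanel:
    """Draw one panel from the generative model; deterministic given cfg.seed."""
    if cfg.target_censoring != 0 and not 0.01 <= cfg.target_censoring <= 0.99:
        raise ValueError("target_censoring must be 0 (none) or within [0.01, 0.99]")
    if cfg.baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    rng = np.random.default_rng(cfg.seed)
    coords, dist = make_locations(cfg.p, cfg.location_layout, rng.integers(0, 2**31 - 1))
    truth = make_coefficient_surface(
        cfg.p, cfg.q, cfg.m, coords, cfg.surface, cfg.effect_scale, rng.integers(0, 2**31 - 1)
    )
    sizes = cfg.cell_sizes()

    cell_X, cell_T = {}, {}
    for i in range(cfg.p):
        for j in range(cfg.q):
            n = sizes[i, j]
            Xc = rng.standard_normal((n, cfg.n_continuous))
            Xb = rng.binomial(1, 0.5, size=(n, cfg.n_binary)).astype(float)
            X = np.hstack([Xc, Xb])
            u = rng.uniform(size=n)
            T = -np.log(u) / (cfg.baseline_rate * np.exp(X @ truth[i, j]))
            cell_X[(i, j)], cell_T[(i, j)] = X, T

    all_T = np.concatenate([cell_T[k] for k in cell_T])
    if cfg.target_censoring > 0:
        cmax = _calibrate_cmax(all_T, cfg.target_censoring)

    strata, n_events, n_total = [], 0, 0
    for i in range(cfg.p):
        row = []
        for j in range(cfg.q):
            T, X = cell_T[(i, j)], cell_X[(i, j)]
            if cfg.target_censoring > 0:
                C = rng.uniform(0.0, cmax, size=T.size)
            else:
                C = np.full(T.size, np.inf)
            time = np.minimum(T, C)
            event = (T <= C).astype(int)
            time = np.maximum(time, 1e-12)  # guard against a zero draw
            row.append(StratumData(time, event, X))
            n_events += int(event.sum())
            n_total += T.size
        strata.append(row)

    panel = PanelData(
        strata,
        location_ids=[f"L{i}" for i in range(cfg.p)],
        period_ids=list(range(1, cfg.q + 1)),
        covariate_names=[f"z{k}" for k in range(cfg.n_continuous)]
        + [f"b{k}" for k in range(cfg.n_binary)],
    )
    return SimulatedPanel(
        panel=panel,
        truth=truth,
        distances=dist,
        coordinates=coords,
        realized_censoring=1.0 - n_events / n_total,
    )
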