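import numpy as np
import pytest

from stcox.data import PanelData, StratumData
from stcox.penalty import weights_from_distances
from stcox.synthetic import SimConfig, simulate_panel


def random_stratum(rng, n=20, m=2, censor_frac=0.3, beta=None):
    """Small random stratum with continuous times (no ties unless forced)."""
    X = rng.standard_normal((n, m))
    b = np.zeros(m) if beta is None else np.asarray(beta, float)
    T = -np.log(rng.uniform(size=n)) / np.exp(X @ b)
    events = (rng.uniform(size=n) > censor_frac).astype(int)
    return StratumData(T, events, X)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_stratum():
    """Two subjects, both events: the hand-checkable example."""
    return StratumData([1.0, 2.0], [1, 1], [[1.0], [0.0]])


@pytest.fixture(scope="session")
def small_sim():
    """p=3, q=3, m=3 smooth panel used by several solver tests."""
    return simulate_panel(
        SimConfig(p=3, q=3, n_continuous=2, n_binary=1, n_per_cell=200,
                  target_censoring=0.3, effect_scale=0.8, seed=11)
    )


@pytest.fixture(scope="session")
def small_omega(small_sim):
    return weights_from_distances(small_sim.distances)


def naive_derivatives(s: StratumData, beta):
    """Brute-force O(n^2) risk-set evaluation of loglik/gradient/diag curvature."""
    beta = np.asarray(beta, float)
    ll = 0.0
    grad = np.zeros_like(beta)
    curv = np.zeros_like(beta)
    for k in range(s.n):
        if s.events[k] != 1:
            continue
        risk = s.times >= s.times[k]
        w = np.exp(s.covariates[risk] @ beta)
        s0 = w.sum()
        mean = (s.covariates[risk] * w[:, None]).sum(axis=0) / s0
        mean2 = (s.covariates[risk] ** 2 * w[:, None]).sum(axis=0) / s0
        ll += s.covariates[k] @ beta - np.log(s0)
        grad += s.covariates[k] - mean
        curv -= mean2 - mean**2
    return ll, grad, curv


def grid_panel(strata_rows, location_ids=None, period_ids=None, names=None):
    p = len(strata_rows)
    q = len(strata_rows[0])
    return PanelData(
        strata_rows,
        location_ids or [f"L{i}" for i in range(p)],
        period_ids or list(range(q)),
        names or [],
    )
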