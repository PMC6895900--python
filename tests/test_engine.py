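import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stcox.data import StratumData
from stcox.engine import (
    concatenate_strata,
    fit_pooled,
    fit_separate,
    fit_stratum_mle,
    stratum_diag_curvature,
    stratum_gradient,
    stratum_hessian,
    stratum_loglik,
    total_loglik,
)
from stcox.synthetic import SimConfig, simulate_panel

from .conftest import grid_panel, naive_derivatives, random_stratum


class TestHandValues:
    def test_loglik_at_zero_is_minus_log_risk_sets(self):
        s = StratumData([1, 2], [1, 1], [[0.0], [0.0]])
        assert stratum_loglik(s, [0.0]) == pytest.approx(-np.log(2))

    def test_loglik_hand_evaluated(self, toy_stratum):
        # event 1: ln2 - ln(2+1); event 2: 0 - ln 1
        assert stratum_loglik(toy_stratum, [np.log(2)]) == pytest.approx(np.log(2) - np.log(3))

    def test_gradient_hand_evaluated(self, toy_stratum):
        np.testing.assert_allclose(stratum_gradient(toy_stratum, [0.0]), [0.5])

    def test_curvature_hand_evaluated(self, toy_stratum):
        np.testing.assert_allclose(stratum_diag_curvature(toy_stratum, [0.0]), [-0.25])

    def test_empty_stratum_is_zero(self):
        s = StratumData(np.empty(0), np.empty(0, int), np.empty((0, 2)))
        assert stratum_loglik(s, [1.0, 2.0]) == 0.0
        np.testing.assert_array_equal(stratum_gradient(s, [1.0, 2.0]), [0.0, 0.0])

    def test_all_censored_is_zero(self, rng):
        s = random_stratum(rng, n=10, m=2)
        s = StratumData(s.times, np.zeros(10, int), s.covariates)
        assert stratum_loglik(s, [0.3, -0.2]) == 0.0

    def test_dimension_mismatch_raises(self, toy_stratum):
        with pytest.raises(ValueError, match="covariates"):
            stratum_loglik(toy_stratum, [0.0, 1.0])


class TestAgainstBruteForce:
    """Fast suffix-sum engine vs the naive O(n^2) risk-set oracle."""

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_on_random_strata(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        m = int(rng.integers(1, 4))
        s = random_stratum(rng, n=n, m=m, beta=rng.normal(size=m) * 0.5)
        if rng.uniform() < 0.5:  # force ties
            t = np.round(s.times, 1) + 0.1
            s = StratumData(t, s.events, s.covariates)
        beta = rng.normal(size=m)
        ll, g, c = naive_derivatives(s, beta)
        assert stratum_loglik(s, beta) == pytest.approx(ll, abs=1e-10)
        np.testing.assert_allclose(stratum_gradient(s, beta), g, atol=1e-10)
        np.testing.assert_allclose(stratum_diag_curvature(s, beta), c, atol=1e-10)

    def test_no_overflow_at_large_linear_predictor(self):
        s = StratumData([1, 2, 3], [1, 1, 1], [[1.0], [0.5], [0.0]])
        val = stratum_loglik(s, [650.0])
        assert np.isfinite(val)


class TestDerivativeConsistency:
    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(100 + seed)
        m = 3
        s = random_stratum(rng, n=30, m=m, beta=[0.4, -0.4, 0.0])
        beta = rng.normal(size=m) * 0.5
        g = stratum_gradient(s, beta)
        h = 1e-5
        for k in range(m):
            e = np.zeros(m)
            e[k] = h
            fd = (stratum_loglik(s, beta + e) - stratum_loglik(s, beta - e)) / (2 * h)
            assert g[k] == pytest.approx(fd, rel=1e-6, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_curvature_matches_finite_differences(self, seed):
        rng = np.random.default_rng(200 + seed)
        m = 2
        s = random_stratum(rng, n=30, m=m)
        beta = rng.normal(size=m) * 0.5
        c = stratum_diag_curvature(s, beta)
        h = 1e-5
        for k in range(m):
            e = np.zeros(m)
            e[k] = h
            fd = (stratum_gradient(s, beta + e)[k] - stratum_gradient(s, beta - e)[k]) / (2 * h)
            assert c[k] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_curvature_nonpositive_and_constant_column_zero(self, rng):
        s = random_stratum(rng, n=25, m=2)
        X = s.covariates.copy()
        X[:, 1] = 3.0  # constant column
        s = StratumData(s.times, s.events, X)
        c = stratum_diag_curvature(s, [0.2, -0.1])
        assert (c <= 0).all()
        assert c[1] == pytest.approx(0.0, abs=1e-12)
        assert stratum_gradient(s, [0.7, 0.7])[1] == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), t=st.floats(-1, 1))
    def test_loglik_concave_along_random_lines(self, seed, t):
        rng = np.random.default_rng(seed)
        s = random_stratum(rng, n=15, m=2)
        b0 = rng.normal(size=2)
        d = rng.normal(size=2)
        h = 1e-3
        f = lambda u: stratum_loglik(s, b0 + u * d)
        second = (f(t + h) - 2 * f(t) + f(t - h)) / h**2
        assert second <= 1e-8


class TestTotalLoglik:
    def test_additivity_over_identical_cells(self, rng):
        s = random_stratum(rng, n=15, m=2)
        panel = grid_panel([[s], [s]])
        beta = np.tile(np.array([0.3, -0.2]), (2, 1, 1))
        assert total_loglik(panel, beta) == pytest.approx(2 * stratum_loglik(s, [0.3, -0.2]))


class TestStratumMLE:
    def test_monotone_likelihood_flagged(self, toy_stratum):
        beta, converged, _ = fit_stratum_mle(toy_stratum)
        assert not converged
        assert np.isfinite(beta).all()

    def test_symmetric_data_gives_zero(self):
        # covariate exchangeable between the two event orders
        s = StratumData([1, 1, 2, 2], [1, 0, 1, 0], [[1.0], [-1.0], [-1.0], [1.0]])
        beta, converged, _ = fit_stratum_mle(s)
        assert converged
        assert beta[0] == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(5)
        s = random_stratum(rng, n=500, m=2, beta=[0.5, -0.5], censor_frac=0.2)
        beta, converged, _ = fit_stratum_mle(s)
        assert converged
        se = np.sqrt(np.diag(np.linalg.inv(-stratum_hessian(s, beta))))
        assert np.all(np.abs(beta - [0.5, -0.5]) < 3 * se)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        rng = np.random.default_rng(17)
        s = random_stratum(rng, n=150, m=2, beta=[0.6, -0.3])  # continuous times: no ties
        beta, converged, _ = fit_stratum_mle(s)
        assert converged
        df = pd.DataFrame(s.covariates, columns=["a", "b"])
        df["T"], df["E"] = s.times, s.events
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(beta, cph.params_[["a", "b"]].to_numpy(), atol=1e-4)

    def test_no_events_raises(self):
        s = StratumData([1, 2], [0, 0], [[1.0], [0.0]])
        with pytest.raises(ValueError, match="no events"):
            fit_stratum_mle(s)

    def test_degenerate_covariate_raises(self):
        s = StratumData([1, 2, 3], [1, 1, 0], [[1.0, 2.0], [1.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="covariate 0"):
            fit_stratum_mle(s)


class TestSeparateAndPooled:
    def test_empty_cell_flagged_not_fatal(self, rng):
        s = random_stratum(rng, n=40, m=1, beta=[0.5])
        empty = StratumData(np.empty(0), np.empty(0, int), np.empty((0, 1)))
        panel = grid_panel([[s], [empty]])
        beta, flags = fit_separate(panel)
        assert flags[1, 0] and not flags[0, 0]
        assert np.isnan(beta[1, 0]).all() and np.isfinite(beta[0, 0]).all()

    def test_single_cell_equals_stratum_mle(self, rng):
        s1 = random_stratum(rng, n=60, m=2, beta=[0.4, 0.0])
        s2 = random_stratum(rng, n=60, m=2, beta=[0.4, 0.0])
        panel = grid_panel([[s1], [s2]])
        beta, flags = fit_separate(panel)
        ref, _, _ = fit_stratum_mle(s1)
        np.testing.assert_allclose(beta[0, 0], ref, atol=1e-10)

    def test_pool_over_both_equals_concatenated_mle(self, rng):
        s1 = random_stratum(rng, n=40, m=2, beta=[0.3, -0.3])
        s2 = random_stratum(rng, n=40, m=2, beta=[0.3, -0.3])
        panel = grid_panel([[s1], [s2]])
        pooled = fit_pooled(panel, "over_both")
        ref, _, _ = fit_stratum_mle(concatenate_strata([s1, s2]))
        np.testing.assert_allclose(pooled[0], ref, atol=1e-10)

    def test_pool_over_locations_on_p1_panel_is_per_period(self, rng):
        row = [random_stratum(rng, n=80, m=2, beta=[0.4, -0.2]) for _ in range(2)]
        panel = grid_panel([row])
        pooled = fit_pooled(panel, "over_locations")
        sep, _ = fit_separate(panel)
        np.testing.assert_allclose(pooled, sep[0], atol=1e-8)

    def test_homogeneous_recovery_over_both(self):
        sim = simulate_panel(
            SimConfig(p=2, q=2, n_continuous=2, n_binary=0, n_per_cell=400,
                      effect_scale=0.0, target_censoring=0.2, seed=3)
        )
        # effect_scale 0: true beta is 0 everywhere
        pooled = fit_pooled(sim.panel, "over_both")
        big = concatenate_strata([s for _, _, s in sim.panel.cells()])
        se = np.sqrt(np.diag(np.linalg.inv(-stratum_hessian(big, pooled[0]))))
        assert np.all(np.abs(pooled[0]) < 3 * se)

    def test_pooled_shapes(self, small_sim):
        panel = small_sim.panel
        assert fit_pooled(panel, "over_locations").shape == (panel.q, panel.m)
        assert fit_pooled(panel, "over_times").shape == (panel.p, panel.m)
        assert fit_pooled(panel, "over_both").shape == (1, panel.m)
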