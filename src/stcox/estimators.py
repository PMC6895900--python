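"""scikit-learn-style estimator classes over the functional core.

All estimators take a :class:`~stcox.data.PanelData` as ``X`` in
``fit`` and expose fitted coefficient arrays with trailing underscores;
``get_params``/``set_params`` come from :class:`sklearn.base.BaseEstimator`
so the classes compose with scikit-learn model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .data import PanelData, validate_distance_matrix
from .engine import fit_pooled, fit_separate, total_loglik
from .inference import bootstrap_se
from .penalty import PenaltyConfig, weights_from_distances
from .solver import SolverOptions, fit_smoothed
from .tuning import select_lambdas

__all__ = ["SmoothedCoxPH", "SeparateCoxPH", "PooledCoxPH"]


def _as_panel(X) -> PanelData:
    if not isinstance(X, PanelData):
        raise TypeError("X must be a PanelData (see stcox.data.read_panel_csv)")
    return X


class SmoothedCoxPH(BaseEstimator):
    """Spatial- and temporal-smoothed Cox proportional hazards estimator.

    Location/period-specific coefficient vectors are estimated jointly
    under a fused l2 penalty on consecutive periods (strength ``lambda1``)
    and an inverse-distance-weighted l2 penalty on location pairs
    (``lambda2``). Setting ``lambda1="cv"`` (equivalently ``lambda2``)
    selects both by V-fold cross-validated partial likelihood.

    Parameters
    ----------
    lambda1, lambda2 : float or "cv"
        Temporal / spatial penalty strengths.
    cv_folds : int
        V for cross-validation when lambdas are selected.
    lambda_grid : sequence or None
        1-d grid (Cartesian square taken) or list of pairs for CV.
    gap_weights : array-like or None
        Optional per-gap weights for non-consecutive periods.
    outer_tol, inner_tol, max_outer, max_inner, init, step_halving
        Solver controls; see :class:`~stcox.solver.SolverOptions`.

    Attributes
    ----------
    coef_ : (p, q, m) ndarray of fitted coefficients.
    converged_ : bool
    n_iter_ : int, outer iterations used.
    objective_trace_ : ndarray of penalized objective values.
    lambda1_, lambda2_ : floats actually used (post-CV).
    """

    def __init__(
        self,
        lambda1=1.0,
        lambda2=1.0,
        cv_folds: int = 5,
        lambda_grid=None,
        gap_weights=None,
        outer_tol: float = 1e-3,
        inner_tol: float = 1e-4,
        max_outer: int = 100,
        max_inner: int = 50,
        init: str = "zero",
        step_halving: bool = True,
        random_state: int = 0,
    ):
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.cv_folds = cv_folds
        self.lambda_grid = lambda_grid
        self.gap_weights = gap_weights
        self.outer_tol = outer_tol
        self.inner_tol = inner_tol
        self.max_outer = max_outer
        self.max_inner = max_inner
        self.init = init
        self.step_halving = step_halving
        self.random_state = random_state

    def _solver_options(self) -> SolverOptions:
        return SolverOptions(
            outer_tol=self.outer_tol,
            inner_tol=self.inner_tol,
            max_outer=self.max_outer,
            max_inner=self.max_inner,
            init=self.init,
            step_halving=self.step_halving,
        )

    def fit(self, X: PanelData, y=None, distances=None):
        """Fit on a panel. ``distances`` is the p x p inter-location matrix."""
        panel = _as_panel(X)
        if distances is None:
            raise ValueError("distances (p x p matrix) is required")
        omega = weights_from_distances(validate_distance_matrix(distances))
        opts = self._solver_options()

        l1, l2 = self.lambda1, self.lambda2
        self.cv_result_ = None
        if l1 == "cv" or l2 == "cv":
            cv = select_lambdas(
                panel, omega, lambda_grid=self.lambda_grid, V=self.cv_folds,
                seed=self.random_state, opts=opts, gap_weights=self.gap_weights,
            )
            l1, l2 = cv.best_lambda1, cv.best_lambda2
            self.cv_result_ = cv
        cfg = PenaltyConfig(lambda1=float(l1), lambda2=float(l2), gap_weights=self.gap_weights)
        res = fit_smoothed(panel, omega, cfg, opts)
        self.coef_ = res.beta
        self.converged_ = res.converged
        self.n_iter_ = res.outer_iterations
        self.objective_trace_ = res.objective_trace
        self.lambda1_, self.lambda2_ = float(l1), float(l2)
        self.result_ = res
        self.omega_ = omega
        self.panel_ = panel
        return self

    def score(self, X: PanelData, y=None) -> float:
        """Total log partial likelihood of a panel under the fitted grid."""
        check_is_fitted(self, "coef_")
        return total_loglik(_as_panel(X), self.coef_)

    def bootstrap(self, B: int = 200, level: float = 0.95, seed: int | None = None):
        """Stratified bootstrap SEs/CIs at the fitted tuning parameters."""
        check_is_fitted(self, "coef_")
        cfg = PenaltyConfig(self.lambda1_, self.lambda2_, gap_weights=self.gap_weights)
        res = bootstrap_se(
            self.panel_, self.omega_, cfg, B=B, level=level,
            seed=self.random_state if seed is None else seed,
            opts=self._solver_options(),
        )
        self.se_ = res.se
        self.ci_low_ = res.ci_low
        self.ci_high_ = res.ci_high
        return res


class SeparateCoxPH(BaseEstimator):
    """Per-cell unpenalized Cox MLEs (the heterogeneity-preserving comparator).

    Attributes: ``coef_`` (p, q, m), ``flags_`` (p, q) boolean mask of
    cells that were empty, event-free, degenerate, or hit the iteration
    cap (monotone likelihood).
    """

    def __init__(self, gtol: float = 1e-6, max_iter: int = 50):
        self.gtol = gtol
        self.max_iter = max_iter

    def fit(self, X: PanelData, y=None, distances=None):
        panel = _as_panel(X)
        self.coef_, self.flags_ = fit_separate(panel, gtol=self.gtol, max_iter=self.max_iter)
        self.panel_ = panel
        return self

    def score(self, X: PanelData, y=None) -> float:
        check_is_fitted(self, "coef_")
        return total_loglik(_as_panel(X), np.nan_to_num(self.coef_, nan=0.0))


class PooledCoxPH(BaseEstimator):
    """Pooled Cox fits: one model per unpooled dimension.

    ``mode`` is one of ``over_locations`` (one coefficient vector per
    period), ``over_times`` (one per location), ``over_both`` (a single
    vector). Attribute ``coef_`` has shape (q, m), (p, m) or (1, m).
    """

    def __init__(self, mode: str = "over_both", gtol: float = 1e-6, max_iter: int = 50):
        self.mode = mode
        self.gtol = gtol
        self.max_iter = max_iter

    def fit(self, X: PanelData, y=None, distances=None):
        panel = _as_panel(X)
        self.coef_ = fit_pooled(panel, self.mode, gtol=self.gtol, max_iter=self.max_iter)
        self.panel_ = panel
        return self
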