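# stcox — spatial- and temporal-smoothed Cox regression for survival panels

`stcox` estimates Cox proportional-hazards models on *survival panels*:
registry-style data collected from `p` locations over `q` consecutive time
periods, with one coefficient vector per (location, period) cell. It is
aimed at population-based cancer survival analysis (multi-registry data
such as SEER) and any setting where per-cell sample sizes are too small for
reliable separate estimation, yet pooling across space or time would mask
real heterogeneity.

## The model

For subject `k` in location `i` and period `j`, the hazard is

    h_{i,j,k}(t) = h0(t) · exp(x_{i,j,k}' β_{i,j}),

with cell-specific coefficients `β_{i,j} ∈ R^m`. The smoothed estimator
maximizes the penalized sum of Breslow log partial likelihoods

    Σ_{i,j} LL(β_{i,j}) − ½ λ1 Σ_i Σ_{j≥2} ||β_{i,j} − β_{i,j−1}||²
                        − ½ λ2 Σ_j Σ_{i<r} ω_{i,r} ||β_{i,j} − β_{r,j}||²,

a fused l2 penalty along consecutive periods plus a Laplacian-type l2
penalty over location pairs with inverse-distance weights `ω_{i,r} = 1/d_{i,r}`.
The penalties borrow information across neighboring cells — coefficient
surfaces are assumed smooth, not constant — and `(λ1, λ2)` are chosen by
V-fold cross-validated partial likelihood.

The optimizer is an outer Taylor-surrogate loop (score and *diagonal*
curvature frozen at the current iterate) with inner closed-form block
updates cycling over cells Gauss–Seidel style; standard errors come from a
stratified nonparametric bootstrap that resamples within each cell.
Comparators — per-cell unpenalized MLEs and location/time/fully pooled
fits — are built in.

## Worked example

```python
from stcox import SmoothedCoxPH, SeparateCoxPH, SimConfig, simulate_panel

sim = simulate_panel(SimConfig(p=4, q=5, n_per_cell=100, seed=3))
est = SmoothedCoxPH(lambda1=1.0, lambda2=1.0).fit(sim.panel, distances=sim.distances)
sep = SeparateCoxPH().fit(sim.panel)

import numpy as np
print("converged:", est.converged_, "in", est.n_iter_, "outer iterations")
print("smoothed MSE:", round(float(np.mean((est.coef_ - sim.truth) ** 2)), 4))
print("separate MSE:", round(float(np.nanmean((sep.coef_ - sim.truth) ** 2)), 4))
```

Output:

```
converged: True in 17 outer iterations
smoothed MSE: 0.0332
separate MSE: 0.0536
```

The simulated panel has 20 cells of 100 subjects each with a smooth true
coefficient surface and ~30% censoring. The smoothed estimator's grid mean
squared error (average squared deviation of all `p·q·m` fitted coefficients
from the truth) is well below separate estimation's: borrowing
information across neighboring cells stabilizes cells whose own likelihood
is weak. Setting `lambda1="cv"` selects both penalties by cross-validation;
`est.bootstrap(B=200)` adds stratified-bootstrap standard errors and
normal-approximation confidence intervals.

The same workflow is available from the shell:

```bash
stcox simulate --out data/ --p 4 --q 5 --n-per-cell 100 --seed 3
stcox fit --input data/panel.csv --distances data/distances.csv \
          --out results/ --lambda1 cv --lambda2 cv --seed 3
```

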