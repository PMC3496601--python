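# stochmle

Maximum-likelihood estimation of rate constants for **discrete-state
stochastic biochemical systems** observed at sparse time points — with
honest, multivariate uncertainty.

## The problem

A well-stirred chemical system with `N` species evolves by `M` mass-action
reactions; reaction `j` fires with propensity `a_j(x) = θ_j h_j(x)`, where
`h_j` counts reactant combinations (`1`, `x₁`, `x₁(x₁−1)/2` or `x₁x₂`) and
`θ_j > 0` is the kinetic constant to be inferred. Given the **complete**
firing record `z = ((τ₁, j₁), …, (τ_r, j_r))` over `[0, T]`, the
log-likelihood is

    log f_θ(x₀, z) = Σ_j [ r_j log θ_j − θ_j H_j ] + Σ_i log h_{j_i}(x_{i−1}),

with `r_j` the number of firings of reaction `j` and
`H_j = Σ_i h_j(x_{i−1}) τ_i`, and the MLE is simply `θ̂_j = r_j / H_j`.
Experiments, however, record only molecule counts of (a subset of) species
at `d` discrete times `y = (x₀, x′₁, …, x′_d)`. The EM route treats the
unrecorded path as missing data: the E-step needs trajectories *consistent*
with `y` (hitting every observed count exactly), and simulating even one
such trajectory by rejection is an extremely rare event when the current
estimate is wrong.

`stochmle` implements a three-stage estimator:

1. **Modified cross-entropy (CE) phase** — simulate `K` SSA trajectories
   one observation interval at a time; after each interval keep the elite
   fraction `ρ` closest to the data in normalized-L1 distance and resample
   them to size `K` (multilevel splitting), jittering the rates per member
   and interval on `[(1−λ)θ, (1+λ)θ]`. The elite pool's pooled
   statistics update `θ` until the elite distance `δ` reaches 0 (or
   plateaus), giving `θ̂_CE`.
2. **Ascent-based Monte Carlo EM** — draw `K′` data-consistent trajectories
   by segment-wise rejection at the current estimate, update
   `θ̂_j = Σ r_j / Σ H_j`, accept only when a normal lower confidence bound
   on the conditional log-likelihood change is non-negative (otherwise grow
   `K′`), and stop when the upper bound stays below `.005`.
3. **Uncertainty** — on `ω = log θ` the MLE is asymptotically normal with
   `Σ⁻¹ = diag(mean θ_j H_j) − Var(score)` estimated from one final
   consistent ensemble; exponentiating interval endpoints and ellipse
   boundaries keeps all confidence bounds strictly positive.

Eight benchmark systems are built in, from the analytically solvable
pure-birth process to an eight-reaction yeast-polarization G-protein cycle.

## Worked example

`examples/02_fit_birth_death.py` fits a birth-death process
(`∅ → S` at `θ₁`, `S → ∅` at `θ₂ x`) from 40 counts sampled every 5 time
units of a single trajectory with true rates `(1, .06)`:

```
CE phase: 4 iterations -> theta_CE = [3.625 0.219]
MCEM: 182 iterations (converged=True)
theta_hat = [1.1414 0.0682]  truth = [1.   0.06]
error = 13.9 %
  theta_1 95% CI: [0.8115, 1.6054]
  theta_2 95% CI: [0.0487, 0.0955]
```

The CE phase needs only four iterations to reach rates whose trajectories
can hit the data (note it overshoots the magnitudes but nails the ratio
`.219/3.625 ≈ .06`); MCEM then walks down the `θ₂/θ₁` ridge to the MLE.
`examples/03_confidence_ellipse.py` continues with the joint uncertainty:

```
log-scale covariance:
 [[0.0583 0.053 ]
 [0.053  0.0565]]
truth inside 95% ellipse: True
major-axis angle on the log scale: 44.5 deg (45 = constant-ratio ray)
```

The near-unit correlation says the data pin the *ratio* of the rates
sharply while their common magnitude stays uncertain — exactly the
degeneracy a discretely observed birth-death record implies.

The other examples cover dataset synthesis (`01`), interval calibration
over a model family (`04`) and the cost asymmetry that motivates the CE
phase (`05`): with a shared simulated-event budget, plain ascent-based
MCEM started at `θ = 1` times out already at `θ* = 4`, while the
CE-initialized pipeline finishes with ~42 M firings.

A thin CLI mirrors the library (`stochmle simulate / fit / uncertainty /
evaluate`; `fit --skip-ce` gives the plain-MCEM baseline). Model files are
YAML (`reactants -> products` equations with named rates), datasets are CSV
time-series with NA cells for unobserved species, results are JSON with
n/a intervals as nulls.

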