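# Methods

## Model and likelihood

A discrete-state stochastic chemical system holds `N` species with counts
`X(t) ∈ ℕ^N` and `M` mass-action reactions of total reactant molecularity
at most two. Reaction `j` fires with propensity `a_j(x) = θ_j h_j(x)`;
`h_j` is the combinatorial count of reactant configurations (1 for
zeroth-order, `x₁` unimolecular, `x₁(x₁−1)/2` homo-bimolecular, `x₁x₂`
hetero-bimolecular). Orders are derived from the reactant stoichiometry at
construction; order > 2 is rejected. Trajectories are generated exactly
with the direct-method SSA: exponential waiting times with rate
`a₀ = Σ a_j`, categorical reaction choice with weights `a_j/a₀`.

For a complete trajectory the log-likelihood separates, per reaction, into
`r_j log θ_j − θ_j H_j` plus θ-free `log h` terms (kept by default so the
likelihood value is exact; a `theta_kernel_only` flag drops them for
optimisation). `(r_j, H_j)` are the sufficient statistics and
`θ̂_j = r_j / H_j` the complete-data MLE; pooling statistics over a set of
trajectories gives the same formula on sums, which is the single code path
behind both the cross-entropy update and the EM update.

Observed data are `y = (x₀, x′₁, …, x′_d)`: a fully known initial state
plus counts of the *observed* species at `d` strictly increasing times.
`x₀` is separate from the `d` observations (the `t = 0` table row holds
it), and observability is a per-species property — a species is recorded
at every `t > 0` or at none.

## Cross-entropy phase

Each iteration simulates an ensemble of `K` trajectories interval by
interval. Per interval and member the current estimate is perturbed
componentwise, uniform on `[(1−λ)θ̂_j, (1+λ)θ̂_j]`; perturbed rates drive
the simulation only — updates always use the realized trajectories'
statistics. After each interval the member's running normalized-L1
distance (`Σ |sim − obs| / (1 + obs)` over observed species and times so
far) is extended, the `⌈ρ′K⌉`-th smallest distance becomes the threshold
`δ`, and (except after the last interval) the ensemble is resampled with
replacement from members with distance ≤ δ, clones inheriting state,
accumulated statistics and distance. Ties at δ all enter the pool, so the
pool may exceed `⌈ρ′K⌉`. After the final interval the elite pool under
`ρ` feeds the pooled-MLE update; a reaction that never fired among the
elites is shrunk geometrically (`θ̂_j/10`, floored at `1e-10`) instead of
being zeroed, preserving exploration while honouring the signal that the
reaction is rare. The loop ends at `δ = 0`, when the elites reproduce
every observed count exactly.

**Plateau rule.** Some models cannot reach `δ = 0` at an affordable `K`;
the phase then stops once δ has reached a steady minimum. Because δ
fluctuates stochastically around its floor, the criterion is the
improvement of the *running minimum*: stop when the best δ in the last
`plateau_window` (default 10) iterations fails to beat the best before the
window by more than `plateau_tolerance` (default 1e-3, relative). A
consecutive-change rule was rejected: with δ bouncing inside a band the
iteration-to-iteration relative change is O(1) and such a rule never
fires, while the record-improvement form is insensitive to the bounce yet
keeps running whenever δ is still genuinely falling.

Setting `ρ′ = 1` disables splitting pressure and `λ = 0` the jitter,
recovering the unmodified cross-entropy method.

## Ascent-based MCEM

From `θ̂_CE`, each iteration draws `K′` trajectories consistent with every
data point by segment-wise rejection: each of the `K′` slots simulates one
observation interval at a time and retries (up to `max_segment_retries`,
default 1e6) until the end state matches the datum on all observed
species. Under partial observation a slot continues from its own
simulated end state, carrying the unobserved species forward; full
observation is the special case where that state equals the datum. The
pooled MLE of the ensemble is the EM update (the unfired-reaction shrink
applies here too).

Monte Carlo noise control uses the per-trajectory log-likelihood
differences `ℓ_k = log f_new(z_k) − log f_old(z_k)` (the `log h` terms
cancel): with `ΔQ̂ = mean(ℓ)` and `SE = sd(ℓ)/√K′`,

* if the upper `1−γ` bound `ΔQ̂ + z_{1−γ}SE` is below the stopping
  tolerance, the iteration counts toward stopping whether or not the
  update was accepted — a certified-small change is convergence evidence,
  not grounds for more sampling;
* else if the lower `1−α` bound `ΔQ̂ − z_{1−α}SE` is negative, the
  apparent ascent may be noise: the update is rejected and the ensemble
  redrawn at `K′ ← K′ + ⌈K′/k⌉` (a hard cap, default 1e5, turns pathological
  growth into a diagnosable error);
* otherwise the update is accepted.

Treating the two bounds asymmetrically in exactly this order matters:
gating stopping on acceptance lets `K′` grow without bound once the EM
increments fall below the tolerance, because near the fixed point the
mean and spread of `ℓ` shrink together and the lower bound keeps dipping
below zero. Termination requires the upper bound below `stop_tolerance`
(default .005) for `stop_consecutive` (default 3) iterations; expensive
models may set `stop_consecutive = 1`. `β` is accepted in the
configuration for compatibility with a power-based sample-size rule but
is unused by default. Rejected iterations discard their ensemble and
redraw at the enlarged `K′`.

## Uncertainty

With `ω = log θ`, the MLE is modelled as multivariate normal on the log
scale. One fresh ensemble of `K′` consistent trajectories (default 1e4)
at `θ̂` provides per-trajectory curvature components `θ̂_j H_j` and score
components `s_j = r_j − θ̂_j H_j`; the information matrix is
`Σ̂⁻¹ = diag(mean θ̂_j H_j) − [mean(ssᵀ) − s̄ s̄ᵀ]` (observed information
minus the missing-information score variance), assembled from centred
outer products in one pass. Inversion goes through a symmetric
eigendecomposition with a condition-number guard (1e12); a non-positive
eigenvalue, a non-positive diagonal variance, or a reaction with no
firings in the ensemble flags the affected parameters and their intervals
render "n/a" — never a hard failure. Intervals are
`exp(ω̂_j ± z√Σ̂_jj)`; pairwise ellipses are the level-`q` χ²₂ contours of
the 2×2 log-scale submatrix mapped through `exp` componentwise, and
containment checks use the quadratic form directly. All bounds are
strictly positive by construction.

The ensemble is redrawn at `θ̂` rather than reusing MCEM's last ensemble:
the final ensemble was drawn at the penultimate estimate, and a fresh
draw at the reported MLE is what the covariance expression assumes.

## Tunable parameters

| symbol | name | default | meaning |
|---|---|---|---|
| K | `ensemble_size` | 1e4 | CE trajectories per iteration |
| ρ | `elite_fraction` | .001 | elite fraction; `⌈ρK⌉` elites feed the update |
| ρ′ | `split_fraction` | = ρ | splitting fraction at interior intervals |
| λ | `perturbation` | .25 | uniform jitter half-width, in [0, 1] |
| K′₀ | `k_prime_init` | 10 | initial consistent-ensemble size |
| α | `alpha` | .25 | acceptance-bound level |
| γ | `gamma` | .25 | stopping-bound level |
| k | `k` | 3 | growth increment `K′ + ⌈K′/k⌉` |
| — | `stop_tolerance` | .005 | stopping threshold on the upper bound |
| — | `stop_consecutive` | 3 | consecutive sub-threshold iterations required |
| K′ | `k_prime` (uncertainty) | 1e4 | final covariance ensemble |

All rates are in 1/time under the `h_j` convention above. The remedy for
a CE phase that cannot produce `⌈ρK⌉` consistent elites is `K × 10` with
`ρ / 10` (stated in the non-convergence error), or the plateau rule.

## Synthetic data and what passing tests show

The generator simulates one exact SSA trajectory per benchmark
configuration at the true rates and subsamples it at `d` equally spaced
times (`t_i = i·T/d`, state closed on the right), optionally masking
species — emulating a noiselessly counted, sparsely sampled experiment.
It does **not** emulate measurement error, cell-to-cell variability,
non-equidistant sampling, or model misspecification; passing tests
therefore certify the estimator under exact-count observation of the
assumed mass-action model, not robustness to those real-data features.
(The indicator-based consistency notion would need replacing by an error
density to handle noisy counts; out of scope here.)

Built-in configurations (rates, initial states, `T`, `d`) follow the
published benchmark suite exactly; the pure-birth sweep uses 100
logarithmically spaced true rates over [.01, 10] (the spacing over three
decades is this package's recorded choice).

## Problem sizes used in the shipped experiments

Chosen once as desk-scale study conditions and fixed:

* coverage sweep and all sweep-style experiments: CE with `K = 10³`,
  `ρ = .01` (same elite count, 10, as the headline `K = 10⁴`, `ρ = .001`)
  and a reduced uncertainty ensemble `K′ = 10³`; the headline sizes remain
  the library defaults and a config switch away;
* birth-death replicate study: 20 independent datasets of the published
  low-equilibrium variant (`θ* = (.5, .1)`, `x₀ = 5`, `T = 25`, `d = 25`)
  with `K′ = 2·10³`, plus one complete fit of the primary dataset
  (`θ* = (1, .06)`, `T = 200`, `d = 40`) with `K′ = 10⁴`;
* cost comparison: simulated-event counts (hardware-independent) under a
  shared 4·10⁸-firing budget;
* yeast-polarization: cross-entropy smoke run, 5 iterations at `K = 10³`
  (a full fit of this model is a multi-day computation by construction).

## Numerical choices

* `H_j` integrals accumulate with Kahan compensation everywhere (a horizon
  may split into 1e6 waiting times).
* The SSA inner loops are numba-jitted, consuming an explicit
  `numpy.random.Generator`; every stochastic operation takes its own
  stream, spawned by name (data / ce / mcem / uncertainty) from one root
  seed, so phases are independently reproducible and results are invariant
  to slot evaluation order. Seeded runs are bit-reproducible.
* The firing that would overshoot an interval end is discarded and the
  residual time recorded — exact for exponential waiting times by
  memorylessness, so no clock state crosses interval boundaries.
* Observation times are closed on the right: the state "at `t_i`"
  includes firings with cumulative time exactly `t_i`.
* Ellipse boundaries use the Cholesky factor of the 2×2 submatrix on a
  uniform angular grid (default 200 points).

## Known limitations

* Rejection sampling of consistent segments scales poorly with molecule
  counts (acceptance ~ the terminal-count point mass); large systems rely
  on the CE phase finishing close to the MLE.
* EM converges linearly along weakly identified directions (e.g. the
  birth-death magnitude ridge): hundreds of iterations are normal, and
  the `.005` stopping tolerance is calibrated to datasets of roughly the
  benchmark sizes — much smaller datasets can stop early simply because
  the conditional log-likelihood moves less than the tolerance.
* The information-matrix estimate can lose positive definiteness at small
  `K′` or far from the MLE; this is reported via flags ("n/a" intervals)
  rather than repaired.
* Non-mass-action kinetics, time-varying rates, volume conventions,
  measurement error and tau-leaping/hybrid simulation are out of scope.
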