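"""Simulate a birth-death trajectory and extract a sparse dataset.

The birth-death process (0 -> S at rate theta1, S -> 0 at rate theta2 S)
is started in stochastic equilibrium at x0 = 17 with theta* = (1, .06).
One exact SSA trajectory over T = 200 is subsampled at d = 40 equally
spaced times — the kind of sparse, discretely observed record an
experiment would provide.
"""

import numpy as np

import stochmle as sm
from stochmle.streams import named_streams

model = sm.builtin_model("birth_death")
rng = named_streams(42)["data"]

trajectory = sm.simulate_trajectory(
    model.network, model.theta_star, model.x0,
    sm.SimulationConfig(model.horizon), rng,
)
data = sm.extract_observations(model.network, trajectory, model.d)

print(f"simulated {trajectory.n_events} reaction firings over [0, {model.horizon:g}]")
print(f"dataset: {data.d} observations of S at dt = {data.times[1] - data.times[0]:g}")
print("first five counts:", data.values[:5, 0].tolist())

stats = sm.sufficient_statistics(model.network, trajectory)
theta_full, _ = sm.complete_data_mle(stats)
print("complete-data MLE (needs the full trajectory):", np.round(theta_full, 4))
print("true rates:", model.theta_star)
# The complete-data MLE is exact given the whole firing record; the rest
# of the package exists because real data only contain the sparse counts.
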