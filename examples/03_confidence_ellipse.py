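"""Joint uncertainty of a rate pair: the warped confidence ellipse.

The MLE is modelled as log-normal, so confidence regions are ellipses
for omega = log theta and exponentiation warps them on the theta scale.
For birth-death data the ellipse is strongly skewed: its major axis
follows the ray of constant theta2/theta1, showing that the data pin
the rate ratio far better than the rate magnitudes.
"""

import numpy as np

import stochmle as sm
from stochmle.streams import named_streams

model = sm.builtin_model("birth_death")
streams = named_streams(42)

trajectory = sm.simulate_trajectory(
    model.network, model.theta_star, model.x0,
    sm.SimulationConfig(model.horizon), streams["data"],
)
data = sm.extract_observations(model.network, trajectory, model.d)
ce = sm.run_ce_phase(
    model.network, data, np.ones(2),
    sm.CEConfig(ensemble_size=1000, elite_fraction=0.01), streams["ce"],
)
mcem = sm.run_mcem(model.network, data, ce.theta, sm.MCEMConfig(), streams["mcem"])
est = sm.estimate_log_covariance(
    model.network, data, mcem.theta, 5000, streams["uncertainty"]
)

print("theta_hat =", np.round(mcem.theta, 4))
print("log-scale covariance:\n", np.round(est.sigma_hat, 4))
for level in (0.68, 0.95, 0.99):
    inside = sm.ellipse_contains(est, (0, 1), tuple(model.theta_star), level)
    print(f"truth inside {level:.0%} ellipse: {inside}")

boundary = sm.confidence_ellipse(est, (0, 1), 0.95, n_points=200)
print("95%% ellipse spans theta1 in [%.3f, %.3f], theta2 in [%.4f, %.4f]"
      % (boundary[:, 0].min(), boundary[:, 0].max(),
         boundary[:, 1].min(), boundary[:, 1].max()))
w, V = np.linalg.eigh(est.sigma_hat)
v = V[:, np.argmax(w)]
print("major-axis angle on the log scale: %.1f deg (45 = constant-ratio ray)"
      % np.degrees(np.arctan2(abs(v[1]), abs(v[0]))))
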