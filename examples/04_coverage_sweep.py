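"""Confidence-interval coverage over a family of pure-birth models.

For the pure-birth process the MLE from discrete observations is exact
(x_d / T), making it the clean testbed for interval calibration: across
many independent models, ~95% of nominal 95% intervals should contain
the true rate.  This desk version runs 10 models; the full benchmark
sweep (100 models, rates .01 to 10) is what scripts/acceptance.py
recomputes.
"""

from stochmle.evaluation import coverage_experiment, pure_birth_sweep

models = pure_birth_sweep(10)
result = coverage_experiment(models, level=0.95, seed=7)

for _, row in result.records.iterrows():
    lo, hi = row.intervals[0]
    mark = "covers" if row.covers else "MISSES"
    print(f"theta* = {row.theta_star[0]:7.4f}  theta_hat = {row.theta_hat[0]:7.4f}  "
          f"95% CI = [{lo:8.4f}, {hi:8.4f}]  {mark}")
print(f"\n{result.covering}/{result.n_models} intervals cover the truth "
      f"(expected misses at 95%: {0.05 * result.n_models:.1f})")
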