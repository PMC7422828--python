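"""One complete simulated visual-field test.

Simulates an observer with a normal hill of vision (plus the default 2.8%
false-positive / 7.3% false-negative behaviour), runs the full
gaze-contingent session -- growth-pattern scheduling, placement,
classification, ZEST updates, catch and refixation trials -- and prints
the summary a clinician-facing report would carry.
"""

import numpy as np

from gazeperim.grid import build_grid
from gazeperim.observer import HillModel, sample_observer
from gazeperim.session import run_session
from gazeperim.stats import mean_sensitivity

grid = build_grid("right")
hill = HillModel()
obs = sample_observer(hill, grid, seed=8)
res = run_session(obs, grid, seed=80, normative_hill=hill)

truth = np.array([obs.thresholds[l.key] for l in grid])
test = np.array([l.role == "test" for l in grid])

measured = test & ~res.unmeasured
print("trials:", dict(res.n_trials_by_type))
if res.unmeasured.any():
    keys = [grid.locations[i].key for i in np.flatnonzero(res.unmeasured)]
    print(f"unmeasured locations (placement failed): {keys}")
print(f"mean sensitivity (measured test points): "
      f"{res.estimates[measured].mean():.2f} dB"
      f"  (true MS {mean_sensitivity(truth, grid):.2f} dB)")
print(f"mean absolute pointwise error    : "
      f"{np.nanmean(np.abs(res.estimates[test] - truth[test])):.2f} dB")
bs = [res.estimate_at(15.0, 3.0), res.estimate_at(15.0, -3.0)]
print(f"blind-spot estimates             : {bs[0]:.2f}, {bs[1]:.2f} dB")
fp = "undefined" if res.fp_rate_est is None else f"{res.fp_rate_est:.3f}"
fn = "undefined" if res.fn_rate_est is None else f"{res.fn_rate_est:.3f}"
print(f"catch-trial error rates          : fp={fp}, fn={fn}")
print(f"presentations per location       : "
      f"{res.n_presentations[test].mean():.1f} (mean), "
      f"{res.n_presentations[test].max()} (max)")
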