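"""Saccadic hit/miss classification of a synthetic gaze stream.

Synthesizes a 50 Hz gaze stream for a seen target at (+9, +9) degrees --
fixation jitter, a ~300 ms saccade, landing error with corrective decay --
and classifies it with the eccentricity-dependent N/D/R criterion
(at this eccentricity: N = 6 samples in a 2.77 deg box within 1.62 s).
"""

import numpy as np

from gazeperim.classifier import classify, params_for_eccentricity
from gazeperim.grid import build_grid
from gazeperim.observer import HillModel, ObserverBehavior, gaze_stream, \
    sample_observer

target = (9.0, 9.0)
params = params_for_eccentricity(target)
print(f"classifier params at {target}: N={params.n_samples}, "
      f"D={params.box_size_deg:.2f} deg, R={params.deadline_s:.2f} s")

grid = build_grid("right")
obs = sample_observer(HillModel(), grid, ObserverBehavior(), seed=0)
rng = np.random.default_rng(4)

for seen in (True, False):
    stream = gaze_stream(obs, seen, target, params.deadline_s + 0.5, rng)
    c = classify(stream, target, params)
    ttc = f"{c.time_to_criterion_s:.2f} s" if c.time_to_criterion_s else "-"
    print(f"seen={str(seen):5} -> classified {'HIT ' if c.hit else 'MISS'}"
          f" (in-box samples: {c.n_in_box:2d}, time to criterion: {ttc})")
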