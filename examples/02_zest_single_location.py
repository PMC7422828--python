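"""ZEST thresholding at a single visual-field location.

Drives the Bayesian staircase against a simulated frequency-of-seeing
observer with a true threshold of 17 dB, printing the stimulus level,
response, posterior mean and posterior SD after each presentation.  The
procedure stops once the posterior SD falls to 1.5 dB or below.
"""

import numpy as np

from gazeperim.zest import (PriorSpec, ZestConfig, estimate, new_state,
                            next_stimulus, p_seen, posterior_mean,
                            posterior_sd, update)

rng = np.random.default_rng(2)
cfg = ZestConfig()
true_threshold = 17.0

state = new_state(cfg, PriorSpec(healthy_mean=21.0))
print(f"true threshold {true_threshold} dB; prior mean "
      f"{posterior_mean(state, cfg):.2f} dB, prior SD {posterior_sd(state, cfg):.2f} dB")
print(f"{'trial':>5} {'stimulus':>9} {'seen':>5} {'post mean':>10} {'post SD':>8}")
while not state.terminated:
    s = next_stimulus(state, cfg)
    seen = rng.random() < p_seen(s, true_threshold, cfg.likelihood_slope_sigma)
    update(state, s, seen, cfg)
    print(f"{state.n_presentations:>5} {s:>7.0f} dB {str(seen):>5} "
          f"{posterior_mean(state, cfg):>8.2f} dB {posterior_sd(state, cfg):>6.2f} dB")

print(f"\nfinal estimate: {estimate(state, cfg):.2f} dB "
      f"(error {estimate(state, cfg) - true_threshold:+.2f} dB)")
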