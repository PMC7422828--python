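# Methods

This note documents the models, defaults, and numerical choices behind
`gazeperim`, and what the simulation-based tests do and do not establish.

## The procedure being modelled

A gaze-contingent perimeter measures differential light sensitivity
(DLS) at fixed retinal locations without a chin rest or button box.  At
each trial the current fixation point is read from a 50 Hz remote
eye-tracker, a Goldmann III (0.43°) increment is drawn on the screen at
the desired visual-field offset *from that fixation point*, and the
response is an eye movement: the trial is a hit if enough gaze samples
land near the target quickly enough.  An adaptive Bayesian staircase
(ZEST) selects intensities and decides when each location is finished.

Everything upstream of the photons — rendering, photometric calibration,
tracker drivers — is out of scope; intensities live on the attenuation-dB
scale throughout, and the stimulus edge-blur used on real hardware is
carried as a configuration field only.

## Sensitivity scale

`DLS_dB = 10·log10(ΔL_max/ΔL_jnd)` with ΔL_max = 225 cd/m² over a
10 cd/m² background, giving a 0–34 dB working range (the 34 dB grid top
corresponds to a ≈0.09 cd/m² increment; the dB grid, not any printed
minimum increment, is treated as authoritative).  Values from a
Humphrey-type reference device (ΔL′_max = 3183.1 cd/m²) are rescaled by
converting to linear units and re-expressing them against 225 cd/m²;
negative rescaled values are rounded up to 0 after conversion, and the
result is capped at the 34 dB domain top (inert for physiological
inputs).  Conversion to and from linear units is exact and bijective on
the domain, so the inverse (`increment_from_db`) is provided for the
stimulus path even though only the forward direction appears in reports.

## Test grid and growth pattern

The 24-2 lattice is reconstructed from its standard definition: points
at odd multiples of 3°, rows at y = ±21, ±15, ±9, ±3 with 4/6/8/8 points
per half-row plus the two nasal-extension points at (−27°, ±3°)
(right-eye format).  Removing the y = ±21 rows (eye-trackers track only
about ±15° vertically) leaves 46 locations; (15°, ±3°) overlie the optic
disc and are blind-spot controls, the other 44 are test points.

The growth pattern defaults to breadth-first expansion from the four
quadrant seeds (±9°, ±9°) using one-lattice-step adjacency (Chebyshev
distance ≤ 6°), which yields stages of size 4/30/8/2.  Published figures
of such patterns are rendered graphically rather than printed as
coordinates, so the exact published grouping may differ; the grouping is
therefore config-overridable (`build_grid(stages=...)`), and the default
is a faithful-in-spirit reconstruction.  Blind-spot points are stage 0:
active from the first trial, outside the stage ordering.

## Geometry

The eye is assumed on the normal through the screen centre; per-axis,
the angle of a pixel u cm off-centre at distance d is `atan(u/d)`.
Gaze-relative placement adds the requested offset to the fixation
angles and projects back through the tangent.  A lateral head offset is
equivalent, in this model, to a shifted fixation point, which the
procedure is contingent on anyway.  The rendered footprint of the
stimulus at screen angle θ is `d·(tan(θ+δ/2) − tan(θ−δ/2))` per axis
(δ = 0.43°), so it grows with screen eccentricity and scales with the
moment-to-moment viewing distance; retinal size constancy holds within
0.5% over the 50–70 cm operating range by construction and is asserted
in tests.  Prohibited zones default to two 300 × 200 px bottom-corner
rectangles, where gaze classification degrades on real hardware; the
zones are configuration.

## ZEST

Per location the posterior lives on the integer grid 0..34 dB.  The
prior is a mixture `(1−w)·N(healthy_mean, 2 dB) + w·N(5 dB, 8 dB)` with
w = 0.2, renormalized on the domain.  The mixture constants follow the
healthy/glaucomatous bimodal construction that is conventional for this
algorithm; the exact published constants are not printed in validation
reports, so all four are configuration.  The healthy mode is centred on
the location's normative value and, for locations opened in later
growth-pattern stages, shifted by the mean deviation from normative of
already-completed neighbours within one lattice step.

The likelihood is `Φ((t − s)/1.25)` for a seen response (complement for
unseen), with optional guess/lapse floors defaulting to 0.  Stimuli are
placed at the posterior mean snapped to the nearest grid value, ties
rounding to the brighter (lower-dB) level; the final estimate is the
unsnapped posterior mean clamped to the domain.  Termination is dynamic:
posterior SD ≤ 1.5 dB (inclusive), with a safety cap of 20 presentations
and a floor of 1 presentation so no location can terminate on its prior
alone (relevant for the tightly-peaked blind-spot prior, a half-normal
at 0 dB with 3 dB scale).  Placement-at-mean, estimate-by-mean, and the
cap are unprinted conventions of the algorithm family and are exposed in
configuration.

With the default (fairly informative) prior, a consistent observer
terminates most locations in 2–4 presentations, giving ~110–130
stimulus trials per session.  Clinical sessions with broader priors and
noisier observers run longer; session length here is an emergent
quantity, not a target.

## Response classification

Hit iff at least N valid samples with t ≤ R lie in the closed
D° × D° box centred on the target.  Counting is cumulative, not
consecutive, because the criterion is stated as a count of gaze
estimates falling in the box; invalid samples are skipped, never
interpolated; the deadline runs from stimulus onset.  The
eccentricity dependence is an affine placeholder anchored to the one
printed triple — N = 6 constant, D = 2.77·(1 + 0.06·(e − 12.73)),
R = 1.62·(1 + 0.04·(e − 12.73)), clipped to D ≥ 1°, 0.8 s ≤ R ≤ 3 s —
because the true functional forms are supplementary-only; every
coefficient is configuration, and a constant override reproduces fixed
parameters at all eccentricities.

## Simulated observers

The generator stands in for a normally-sighted adult cohort:

* **Hill of vision**: threshold = peak − slope·eccentricity + observer
  offset + pointwise noise, clamped to [0, 34]; defaults peak 23 dB,
  slope 0.25 dB/°, interobserver SD 1 dB, pointwise SD 1 dB.  These were
  chosen once so that cohort mean sensitivity lands in the ~18–20 dB
  regime typical of such cohorts on this scale; they are a calibration
  choice, not measured constants.  Blind-spot locations are 0 dB and
  behave as blind: no displayable stimulus is detected there, so their
  detection probability is the false-positive rate (the mixture formula
  below would otherwise give 0.5 at maximal intensity, which
  contradicts the physiology).
* **Frequency of seeing**: `p = fp + (1 − fp − fn)·Φ((t − s)/σ_fos)`,
  σ_fos defaulting to the 1.25 dB likelihood slope so that noiseless
  recovery is well posed (set it differently to create model mismatch).
  fp = 2.8% and fn = 7.3% by default — the error rates measured for this
  kind of test in normally sighted adults.
* **Gaze**: 0.1° fixation jitter; saccade latency N(0.30 s, 0.05 s)
  floored at 0.1 s; per-trial landing offset with SD 0.1° + 0.03°/° of
  eccentricity decaying geometrically (factor 0.85/sample) toward the
  target, standing in for corrective saccades; 2% tracker dropouts; on
  unseen trials, a stray saccade to a random trackable point with
  probability fp (behavioural colour only — false-positive *responses*
  come from the frequency-of-seeing term, and a random landing almost
  never falls in a classification box).  Viewing distance performs a
  1 cm/trial random walk clamped to 50–70 cm.

What the generator does **not** emulate: realistic eye-tracker noise
spectra, blinks/pupil artifacts beyond validity dropouts, smooth
pursuit, fatigue or learning effects, and response-time structure beyond
a Gaussian latency.  Passing recovery tests therefore show the
*algorithmic* pipeline is correct and calibrated, not that the test is
robust to every behaviour of real eyes.

## Session orchestration

Trials draw uniformly at random from the active set (current stage plus
unterminated blind spots).  Catch trials are inserted per-trial with
probability 0.07, half blank and half maximal-luminance, at test-point
locations, and never touch any posterior; false-positive and
false-negative rates are estimated as blank-hit and supra-miss
fractions, flagged undefined (not zero) when no catch of that type
occurred.  With ~120-trial sessions this yields ~8 catch trials per
test; the per-trial rate, not the per-session count, is the invariant
checked.  Fixation instability at onset (dispersion over a 10-sample
window > 1°, or dropouts) and placement failures trigger refixation
trials; the refixation cue is placed at a fixation point from which the
pending target is placeable (solved per axis against screen extent and
trackable cone, with jitter only when escaping a prohibited zone), and
the simulated observer complies with 0.5° noise.  A location that stays
unplaceable after 3 retries is flagged unmeasured and the session
continues; with default geometry this affects ≲0.1% of location-runs.
Sessions are bit-reproducible given (observer, seed).  A
`response_mode="direct"` switch bypasses gaze synthesis (hit = seen) for
fast calibration studies.

## Statistics

* MS is the mean over the 44 test points, blind spots excluded.
* CoR₉₅ = 1.96 × sample SD (n−1) of run2 − run1 differences; limits of
  agreement are mean ± CoR₉₅.  This is the convention fixed by plotting
  µ ± CoR₉₅.
* BCa intervals come from `scipy.stats.bootstrap(method="BCa")`
  (N = 20,000 default); data are sorted internally so the interval is
  invariant to input ordering, degenerate bootstrap distributions fall
  back to the percentile interval with a warning, and constant data
  short-circuit to a zero-width interval.
* The CoR-difference test permutes device labels within observer
  (each observer's paired-difference swaps devices with probability ½),
  rebuilding Δ = CoR_A − CoR_B under exchangeability; two-sided p with
  add-one smoothing, so p ∈ (0, 1].  The published description of this
  test ("similar in principle to a Mann–Whitney U") leaves the
  resampling scheme open; within-observer label permutation is our
  reconstruction and the scheme is pluggable.
* Pointwise device comparisons are paired t-tests with Bonferroni
  division by the number of comparable (test-role) locations — α/44 on
  the full grid; zero-variance (undefined-p) locations are never
  flagged.
* Normative tables report per-location mean and 2.5th/97.5th
  percentiles pooled over tests, right-eye format, using linear
  interpolation between order statistics (recorded in the table
  metadata, since percentile conventions differ).
* The minimum detectable paired difference uses the central-t
  approximation `(t_{1−α/2,n−1} + t_{power,n−1})·sd/√n`; with n = 64,
  sd = 1.548 dB, α = 0.05 and an assumed power of 0.80 (the power behind
  the published 0.55 dB figure is not printed; 0.80 reproduces it to
  2 d.p.).

## Problem sizes in the test suite

The suite calibrates stochastic properties at sizes chosen for a
desk-scale run: update-vs-brute-force equivalence is exhaustive over all
126 response sequences of length ≤ 6 on a 5-point domain (tolerance
1e−12); threshold recovery uses 500 direct-mode sessions (mean |error|
≤ 1.5 dB, |bias| ≤ 0.5 dB); error-rate recovery pools catch trials from
50 full gaze-mode sessions against binomial 95% bounds; the
CoR-difference test's type-I rate is measured over 1,000 null replicates
at n_boot = 2,000 (bound 0.07 at nominal 0.05); BCa coverage uses 100
replications of a Gaussian mean at n = 200 (bound ≥ 93/100).  All
stochastic tests are seeded; the error-rate check uses the package's
master-seed cohort spawning.  Note that "within binomial 95% bounds" is
itself a ~95%-coverage event for any fixed sample size, which is why the
test pins its seed rather than resampling.

## Known limitations

* The classifier's eccentricity model and the growth-pattern grouping
  are reconstructions of graphically/supplementary-published components;
  both are configuration-overridable.
* Durations are counted in trials, not minutes; wall-clock timing is
  hardware- and human-bound and out of scope.
* No patient-mode validation: the glaucoma defect generator exists but
  default calibrations target normally sighted cohorts.
* Displayable intensities are continuous (no 10-bit panel quantization);
  the integer dB presentation grid is the only discretization.
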