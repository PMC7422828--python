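"""Simulated observers: hill of vision, frequency of seeing, gaze streams.

Stands in for a human cohort.  Each observer carries:

* **True thresholds** on the test grid, drawn from a parametric hill of
  vision (peak sensitivity at fixation, linear radial falloff, an
  observer-level offset, and pointwise noise).  Blind-spot locations are
  fixed at 0 dB and treated as blind: nothing displayable is detected
  there, so their detection probability collapses to the false-positive
  rate.
* **Frequency-of-seeing behaviour**: detection of a stimulus at ``s`` dB
  given threshold ``t`` occurs with probability
  ``fp + (1 - fp - fn) * Phi((t - s) / fos_slope)``, where ``fp`` and
  ``fn`` are the lapse-style false-positive / false-negative rates.
* **Oculomotor behaviour** used to synthesize 50 Hz gaze streams: saccade
  latency, eccentricity-dependent landing error with geometric corrective
  decay, per-sample fixation jitter, tracker dropouts, and a slow
  random-walk in viewing distance.

Default fp/fn rates are 2.8% and 7.3%, the error rates measured for the
gaze-based test in normally sighted adults; the hill defaults put cohort
mean sensitivity near the ~19.7 dB regime of such a cohort on the 0-34 dB
scale.  The frequency-of-seeing slope defaults to the ZEST likelihood
slope (1.25 dB) so that noiseless threshold recovery is well posed;
setting it differently creates deliberate model mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from matplotlib.path import Path as _MplPath
from scipy import stats

from .classifier import GazeStream
from .grid import ROLE_BLIND_SPOT, GridLocation, TestGrid

__all__ = [
    "HillModel",
    "ObserverBehavior",
    "SimulatedObserver",
    "normative_mean",
    "sample_observer",
    "sample_cohort",
    "respond",
    "gaze_stream",
    "apply_defect",
]


@dataclass(frozen=True)
class HillModel:
    """Parametric hill of vision on the attenuation-dB scale.

    ``mean(x, y) = peak_db - slope_db_per_deg * eccentricity`` clamped to
    [0, 34]; observers add a shared offset (interobserver_sd) and
    per-location noise (pointwise_sd).
    """

    peak_db: float = 23.0
    slope_db_per_deg: float = 0.25
    interobserver_sd: float = 1.0
    pointwise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.peak_db < 0 or self.slope_db_per_deg < 0:
            raise ValueError("peak and slope must be non-negative")
        if self.interobserver_sd < 0 or self.pointwise_sd < 0:
            raise ValueError("noise SDs must be non-negative")


def normative_mean(hill: HillModel, x: float, y: float,
                   db_max: float = 34.0) -> float:
    """Expected (normative) sensitivity at a visual-field location."""
    ecc = float(np.hypot(x, y))
    return float(np.clip(hill.peak_db - hill.slope_db_per_deg * ecc, 0.0, db_max))


@dataclass(frozen=True)
class ObserverBehavior:
    """Response and oculomotor parameters shared by a simulated cohort."""

    fos_slope: float = 1.25          # frequency-of-seeing slope, dB
    fp_rate: float = 0.028           # false-positive (guess) rate
    fn_rate: float = 0.073           # false-negative (lapse) rate
    saccade_latency_mean_s: float = 0.30
    saccade_latency_sd_s: float = 0.05
    landing_error_base_deg: float = 0.10   # landing sd at fixation
    landing_error_per_deg: float = 0.03    # landing sd growth per deg ecc
    landing_decay: float = 0.85            # corrective decay per sample
    fixation_jitter_sd_deg: float = 0.10
    dropout_prob: float = 0.02
    stray_saccade_prob: float | None = None  # default: fp_rate
    sample_rate_hz: float = 50.0
    distance_drift_sd_cm: float = 1.0      # random walk per trial

    def __post_init__(self) -> None:
        if not (0.0 <= self.fp_rate < 1.0 and 0.0 <= self.fn_rate < 1.0):
            raise ValueError("fp/fn rates must be in [0, 1)")
        if self.fos_slope <= 0:
            raise ValueError("fos_slope must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def effective_stray_prob(self) -> float:
        return self.fp_rate if self.stray_saccade_prob is None else self.stray_saccade_prob


@dataclass
class SimulatedObserver:
    """One synthetic participant: true field plus behaviour, seeded."""

    thresholds: dict[tuple[float, float], float]
    behavior: ObserverBehavior = ObserverBehavior()
    rng_seed: int = 0

    def threshold_at(self, location: GridLocation) -> float:
        return self.thresholds[location.key]


def sample_observer(hill: HillModel, grid: TestGrid,
                    behavior: ObserverBehavior = ObserverBehavior(),
                    seed: int | np.random.SeedSequence = 0,
                    db_max: float = 34.0) -> SimulatedObserver:
    """Draw one observer's true thresholds from the hill model.

    Blind-spot locations are set to 0 dB (blind).  Reproducible: the same
    seed yields the same observer.
    """
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(seq)
    offset = rng.normal(0.0, hill.interobserver_sd) if hill.interobserver_sd > 0 else 0.0
    thresholds: dict[tuple[float, float], float] = {}
    for loc in grid:
        if loc.role == ROLE_BLIND_SPOT:
            thresholds[loc.key] = 0.0
            continue
        noise = rng.normal(0.0, hill.pointwise_sd) if hill.pointwise_sd > 0 else 0.0
        base = hill.peak_db - hill.slope_db_per_deg * loc.eccentricity
        thresholds[loc.key] = float(np.clip(base + offset + noise, 0.0, db_max))
    seed_int = int(seq.generate_state(1)[0] % (2**31))
    return SimulatedObserver(thresholds, behavior, seed_int)


def sample_cohort(n: int, hill: HillModel, grid: TestGrid,
                  behavior: ObserverBehavior = ObserverBehavior(),
                  seed: int = 0) -> list[SimulatedObserver]:
    """n independent observers with per-observer seeds spawned from one master."""
    master = np.random.SeedSequence(seed)
    return [sample_observer(hill, grid, behavior, child)
            for child in master.spawn(n)]


def respond(observer: SimulatedObserver, location: GridLocation,
            stimulus_db: float | None, rng: np.random.Generator) -> bool:
    """Did the observer detect this presentation?

    ``stimulus_db=None`` means a blank (nothing displayed): detection is a
    false positive.  A true threshold <= 0 marks a blind location, where no
    displayable stimulus is seen and detection likewise collapses to the
    false-positive rate.
    """
    b = observer.behavior
    t = observer.threshold_at(location)
    if stimulus_db is None or t <= 0.0:
        p = b.fp_rate
    else:
        p = b.fp_rate + (1.0 - b.fp_rate - b.fn_rate) * stats.norm.cdf(
            (t - stimulus_db) / b.fos_slope)
    return bool(rng.random() < p)


def _landing_sd(behavior: ObserverBehavior, eccentricity: float) -> float:
    return behavior.landing_error_base_deg + behavior.landing_error_per_deg * eccentricity


def gaze_stream(observer: SimulatedObserver, seen: bool,
                target_deg: tuple[float, float], duration_s: float,
                rng: np.random.Generator,
                trackbox_deg: tuple[float, float] = (27.0, 15.0)) -> GazeStream:
    """Synthesize one presentation's 50 Hz gaze stream.

    Seen trials: fixation jitter around the onset fixation until a
    saccade-latency draw, then samples around the target with a per-trial
    landing offset that decays geometrically (corrective saccades).
    Unseen trials: jitter throughout, except that with a small probability
    an erroneous saccade lands at a uniformly random trackable point.
    Validity flags carry tracker dropouts.
    """
    b = observer.behavior
    dt = 1.0 / b.sample_rate_hz
    n = max(int(round(duration_s * b.sample_rate_hz)), 1)
    t = np.arange(n) * dt
    x = rng.normal(0.0, b.fixation_jitter_sd_deg, n)
    y = rng.normal(0.0, b.fixation_jitter_sd_deg, n)

    dest: tuple[float, float] | None = None
    if seen:
        dest = target_deg
    elif rng.random() < b.effective_stray_prob:
        dest = (rng.uniform(-trackbox_deg[0], trackbox_deg[0]),
                rng.uniform(-trackbox_deg[1], trackbox_deg[1]))
    if dest is not None:
        latency = max(rng.normal(b.saccade_latency_mean_s, b.saccade_latency_sd_s), 0.1)
        k0 = int(np.searchsorted(t, latency))
        if k0 < n:
            ecc = float(np.hypot(*dest))
            sd = _landing_sd(b, ecc)
            off = rng.normal(0.0, sd, 2)
            decay = b.landing_decay ** np.arange(n - k0)
            x[k0:] += dest[0] + off[0] * decay
            y[k0:] += dest[1] + off[1] * decay
    valid = rng.random(n) >= b.dropout_prob
    return GazeStream(t, x, y, valid)


def apply_defect(observer: SimulatedObserver,
                 vertices: Sequence[tuple[float, float]],
                 depth_db: float) -> SimulatedObserver:
    """Carve a localized defect into an observer's field.

    Subtracts ``depth_db`` (floor 0) at every grid location inside the
    polygon ``vertices`` (visual-field degrees) -- e.g. an arcuate,
    nerve-fibre-bundle-shaped region for a glaucoma-like field.
    """
    path = _MplPath(np.asarray(vertices, dtype=float))
    new = dict(observer.thresholds)
    for xy, t in new.items():
        if path.contains_point(xy):
            new[xy] = max(t - depth_db, 0.0)
    return SimulatedObserver(new, observer.behavior, observer.rng_seed)
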