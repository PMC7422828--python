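"""Saccadic response classification: was the stimulus seen?

A presentation counts as a "hit" if at least N valid gaze samples
(50 Hz) fall within a closed D x D degree box centred on the target
within R seconds of stimulus onset.  The count is cumulative, not
consecutive, and the box boundary is inclusive.  N, D and R vary with
stimulus eccentricity: peripheral targets draw longer-latency, less
accurate saccades, so the box widens and the deadline lengthens with
eccentricity.  The default eccentricity model is affine around the
printed anchor (a target at (+9, +9), eccentricity ~12.73 deg, uses
N = 6, D = 2.77 deg, R = 1.62 s); all coefficients are configurable.

Gaze positions here are visual-field degrees relative to the fixation
point at stimulus onset, the same frame in which targets are specified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClassifierParams",
    "EccentricityModel",
    "GazeStream",
    "Classification",
    "params_for_eccentricity",
    "classify",
    "fixation_stable",
]

#: eccentricity of the printed anchor target (+9, +9)
ANCHOR_ECCENTRICITY_DEG = math.hypot(9.0, 9.0)


@dataclass(frozen=True)
class ClassifierParams:
    """Hit criterion for one presentation: N samples in a D-deg box by R s."""

    n_samples: int = 6
    box_size_deg: float = 2.77  # full box width D (box is D x D)
    deadline_s: float = 1.62

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.box_size_deg <= 0 or self.deadline_s <= 0:
            raise ValueError("box size and deadline must be positive")


@dataclass(frozen=True)
class EccentricityModel:
    """Affine-in-eccentricity N/D/R model anchored at (+9, +9).

    D and R grow with eccentricity, N is constant; setting the slopes to
    zero makes the parameters constant at the anchor values.
    """

    anchor_eccentricity_deg: float = ANCHOR_ECCENTRICITY_DEG
    n_samples: int = 6
    box_size_at_anchor_deg: float = 2.77
    box_slope_per_deg: float = 0.06       # fractional growth of D per degree
    deadline_at_anchor_s: float = 1.62
    deadline_slope_per_deg: float = 0.04  # fractional growth of R per degree
    min_box_deg: float = 1.0
    min_deadline_s: float = 0.8
    max_box_deg: float = 8.0
    max_deadline_s: float = 3.0


def params_for_eccentricity(target_deg: tuple[float, float] | float,
                            model: EccentricityModel = EccentricityModel(),
                            ) -> ClassifierParams:
    """Classifier parameters for a target at the given position/eccentricity."""
    if isinstance(target_deg, (tuple, list, np.ndarray)):
        ecc = float(np.hypot(target_deg[0], target_deg[1]))
    else:
        ecc = float(target_deg)
    de = ecc - model.anchor_eccentricity_deg
    box = model.box_size_at_anchor_deg * (1.0 + model.box_slope_per_deg * de)
    deadline = model.deadline_at_anchor_s * (1.0 + model.deadline_slope_per_deg * de)
    box = min(max(box, model.min_box_deg), model.max_box_deg)
    deadline = min(max(deadline, model.min_deadline_s), model.max_deadline_s)
    return ClassifierParams(model.n_samples, box, deadline)


@dataclass
class GazeStream:
    """Timestamped gaze samples from one presentation.

    ``t`` is seconds from stimulus onset; ``x``/``y`` are visual-field
    degrees relative to the fixation point at onset; ``valid`` flags
    tracker dropouts.  Nominal rate 50 Hz.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    distance_cm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.valid)):
            raise ValueError("gaze arrays must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) < 0):
            raise ValueError("gaze samples must be time-ordered")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class Classification:
    hit: bool
    n_in_box: int
    time_to_criterion_s: float | None
    reason: str = ""


def classify(stream: GazeStream, target_deg: tuple[float, float],
             params: ClassifierParams) -> Classification:
    """Hit iff >= N valid samples within the closed box by the deadline."""
    if len(stream) == 0:
        return Classification(False, 0, None, "no_data")
    half = params.box_size_deg / 2.0
    ok = (stream.valid
          & (stream.t <= params.deadline_s)
          & (np.abs(stream.x - target_deg[0]) <= half)
          & (np.abs(stream.y - target_deg[1]) <= half))
    n_in = int(ok.sum())
    if n_in >= params.n_samples:
        t_crit = float(stream.t[np.flatnonzero(ok)[params.n_samples - 1]])
        return Classification(True, n_in, t_crit)
    reason = "deadline" if stream.valid.any() else "no_valid_samples"
    return Classification(False, n_in, None, reason)


def fixation_stable(stream: GazeStream, window: int = 10,
                    dispersion_limit_deg: float = 1.0) -> bool:
    """Gate for trial onset: are the last ``window`` valid samples stable?

    Stability is max per-axis dispersion (range) over the most recent
    ``window`` valid samples; fewer than ``window`` valid samples counts
    as unstable.
    """
    idx = np.flatnonzero(stream.valid)
    if len(idx) < window:
        return False
    idx = idx[-window:]
    disp = max(np.ptp(stream.x[idx]), np.ptp(stream.y[idx]))
    return bool(disp <= dispersion_limit_deg)
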