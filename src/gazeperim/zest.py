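"""ZEST: Bayesian adaptive threshold estimation on a discrete dB domain.

ZEST maintains, per test location, a probability mass function over
candidate detection thresholds on the integer attenuation grid
0..34 dB.  The starting prior is a bimodal mixture of a "healthy" mode
(centred on the normative sensitivity for that location) and a broad
"abnormal" mode near 0 dB, reflecting the bimodal population of healthy
and glaucomatous fields.  After each presentation at stimulus level ``s``
the pmf is multiplied by the likelihood of the observed response under a
cumulative-Gaussian frequency-of-seeing curve with fixed slope
(sigma = 1.25 dB)::

    P(seen | threshold t) = gamma + (1 - gamma - lambda) * Phi((t - s) / sigma)

(guess rate gamma and lapse rate lambda default to 0).  The next stimulus
is placed at the posterior mean (snapped to the grid), and the location
terminates dynamically once the posterior standard deviation falls to
1.5 dB or below (or a presentation cap is hit).  The final estimate is the
posterior mean, not grid-snapped.

In the staged growth pattern, the healthy mode of a yet-untested
location's prior is shifted by the mean deviation from normative observed
at its already-completed lattice neighbours (:func:`seed_from_neighbors`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .grid import GridLocation

__all__ = [
    "PriorSpec",
    "ZestConfig",
    "ZestState",
    "make_prior",
    "p_seen",
    "update",
    "next_stimulus",
    "is_terminated",
    "posterior_sd",
    "estimate",
    "seed_from_neighbors",
    "run_to_termination",
]


@dataclass(frozen=True)
class PriorSpec:
    """Bimodal prior: healthy mode at the normative mean, abnormal mode low.

    The exact mixture constants are configuration, not dogma: defaults are
    a 20% abnormal component centred at 5 dB with an 8 dB spread, and a
    healthy component with a 2 dB spread around the location's normative
    sensitivity.
    """

    healthy_mean: float = 23.0
    healthy_sd: float = 2.0
    abnormal_mean: float = 5.0
    abnormal_sd: float = 8.0
    abnormal_weight: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.abnormal_weight <= 1.0:
            raise ValueError("abnormal_weight must be in [0, 1]")
        if self.healthy_sd <= 0 or self.abnormal_sd <= 0:
            raise ValueError("prior standard deviations must be positive")


@dataclass(frozen=True)
class ZestConfig:
    db_domain: tuple[float, ...] = tuple(float(v) for v in range(35))
    likelihood_slope_sigma: float = 1.25
    termination_sd: float = 1.5
    max_presentations: int = 20
    min_presentations: int = 1
    guess_rate: float = 0.0
    lapse_rate: float = 0.0
    prior: PriorSpec = PriorSpec()

    def __post_init__(self) -> None:
        dom = np.asarray(self.db_domain, dtype=float)
        if dom.ndim != 1 or len(dom) < 2 or np.any(np.diff(dom) <= 0):
            raise ValueError("db_domain must be strictly increasing with >= 2 values")
        if self.likelihood_slope_sigma <= 0:
            raise ValueError("likelihood slope must be positive")
        if self.termination_sd <= 0:
            raise ValueError("termination_sd must be positive")
        if not 0 <= self.min_presentations <= self.max_presentations:
            raise ValueError("presentation bounds inconsistent")

    @property
    def domain(self) -> np.ndarray:
        return np.asarray(self.db_domain, dtype=float)


@dataclass
class ZestState:
    """Posterior over the dB domain for one location."""

    pmf: np.ndarray
    n_presentations: int = 0
    terminated: bool = False
    location: GridLocation | None = None

    def copy(self) -> "ZestState":
        return ZestState(self.pmf.copy(), self.n_presentations,
                         self.terminated, self.location)


def make_prior(spec: PriorSpec, config: ZestConfig) -> np.ndarray:
    """Normalized bimodal prior pmf on the dB domain."""
    dom = config.domain
    w = spec.abnormal_weight
    pdf = ((1.0 - w) * stats.norm.pdf(dom, spec.healthy_mean, spec.healthy_sd)
           + w * stats.norm.pdf(dom, spec.abnormal_mean, spec.abnormal_sd))
    total = pdf.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("prior has zero mass on the dB domain")
    return pdf / total


def p_seen(stimulus_db, threshold_db, slope: float,
           guess_rate: float = 0.0, lapse_rate: float = 0.0):
    """Probability of detection: frequency-of-seeing curve.

    Cumulative Gaussian in threshold-minus-stimulus: 0.5 at threshold,
    approaching 1 for stimuli brighter (lower dB) than threshold.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    core = stats.norm.cdf((np.asarray(threshold_db, dtype=float) - stimulus_db) / slope)
    out = guess_rate + (1.0 - guess_rate - lapse_rate) * core
    return float(out) if np.ndim(out) == 0 else out


def new_state(config: ZestConfig, prior: PriorSpec | None = None,
              location: GridLocation | None = None) -> ZestState:
    return ZestState(make_prior(prior or config.prior, config), location=location)


def update(state: ZestState, stimulus_db: float, seen: bool,
           config: ZestConfig) -> ZestState:
    """Bayes update of the posterior after one presentation (in place)."""
    if state.terminated:
        raise RuntimeError("cannot update a terminated location")
    like = p_seen(stimulus_db, config.domain, config.likelihood_slope_sigma,
                  config.guess_rate, config.lapse_rate)
    if not seen:
        like = 1.0 - like
    post = state.pmf * like
    total = post.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("posterior has zero mass (inconsistent responses?)")
    state.pmf = post / total
    state.n_presentations += 1
    if is_terminated(state, config):
        state.terminated = True
    return state


def posterior_mean(state: ZestState, config: ZestConfig) -> float:
    return float(np.dot(config.domain, state.pmf))


def posterior_sd(state: ZestState, config: ZestConfig) -> float:
    dom = config.domain
    m = np.dot(dom, state.pmf)
    var = float(np.dot((dom - m) ** 2, state.pmf))
    return math.sqrt(max(var, 0.0))


def next_stimulus(state: ZestState, config: ZestConfig) -> float:
    """Posterior mean snapped to the nearest domain value; ties go brighter.

    "Brighter" is the lower dB value (less attenuation).
    """
    if state.terminated:
        raise RuntimeError("cannot place a stimulus at a terminated location")
    dom = config.domain
    m = posterior_mean(state, config)
    hi = int(np.searchsorted(dom, m))
    if hi == 0:
        return float(dom[0])
    if hi >= len(dom):
        return float(dom[-1])
    lo = hi - 1
    d_lo, d_hi = m - dom[lo], dom[hi] - m
    return float(dom[lo]) if d_lo <= d_hi else float(dom[hi])


def is_terminated(state: ZestState, config: ZestConfig) -> bool:
    """Dynamic termination: posterior SD <= bound (inclusive) or cap hit."""
    if state.n_presentations >= config.max_presentations:
        return True
    if state.n_presentations < config.min_presentations:
        return False
    return posterior_sd(state, config) <= config.termination_sd


def estimate(state: ZestState, config: ZestConfig) -> float:
    """Final sensitivity estimate: posterior mean clamped to the domain."""
    m = posterior_mean(state, config)
    dom = config.domain
    return float(min(max(m, dom[0]), dom[-1]))


def seed_from_neighbors(location: GridLocation,
                        completed_estimates: Mapping[tuple[float, float], float],
                        normative: Mapping[tuple[float, float], float],
                        spec: PriorSpec,
                        neighbor_step: float = 6.0) -> PriorSpec:
    """Shift the healthy prior mode by neighbours' deviation from normative.

    The shift is the mean of (estimate - normative) over completed
    locations within one lattice step; with no completed neighbour the
    spec is returned untouched.
    """
    devs = []
    for xy, est in completed_estimates.items():
        dx, dy = abs(xy[0] - location.x), abs(xy[1] - location.y)
        if max(dx, dy) <= neighbor_step and (dx, dy) != (0.0, 0.0):
            devs.append(est - normative[xy])
    if not devs:
        return spec
    return replace(spec, healthy_mean=spec.healthy_mean + float(np.mean(devs)))


def run_to_termination(respond: Callable[[float], bool], config: ZestConfig,
                       prior: PriorSpec | None = None,
                       location: GridLocation | None = None,
                       ) -> tuple[ZestState, list[float]]:
    """Drive one location to termination against a response callable.

    ``respond(stimulus_db) -> seen`` supplies the observer.  Returns the
    final state and the sequence of stimulus levels presented.  This is
    the single-location fast path used for calibration and recovery
    studies; interleaved testing lives in :mod:`gazeperim.session`.
    """
    state = new_state(config, prior, location)
    stimuli: list[float] = []
    while not state.terminated:
        s = next_stimulus(state, config)
        stimuli.append(s)
        update(state, s, bool(respond(s)), config)
    return state, stimuli
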