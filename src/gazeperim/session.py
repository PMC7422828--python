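"""Full-test orchestration: gaze-contingent, growth-patterned ZEST testing.

A session interleaves, trial by trial:

* **Test trials** at a location drawn uniformly at random from the active
  set (the current growth-pattern stage plus the blind-spot points, which
  are tested throughout).  The target is placed at the location's
  visual-field offset from the *current* fixation point, the simulated
  observer responds, the gaze stream is classified, and the location's
  ZEST posterior is updated.  A stage opens only when every location of
  the previous stage has terminated, and newly opened locations have
  their priors seeded from completed neighbours.
* **Catch trials** (Bernoulli per trial, default 7%, averaging ~21 per
  session): half blank (false-positive probes), half maximal-luminance
  suprathreshold (false-negative probes), at test-trial locations, never
  touching any ZEST state.
* **Refixation trials** whenever fixation is unstable at trial onset or
  the pending target cannot be validly placed (off-screen, prohibited
  zone, or outside the trackbox).  The refixation event recentres gaze at
  a point from which the pending target is placeable; a location that
  stays unplaceable after the retry budget is flagged unmeasured and the
  session continues.

Sessions are bit-reproducible under their seed.  ``response_mode="direct"``
bypasses gaze synthesis/classification (the observer's detection decision
is used directly) for fast calibration and recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from . import zest as _zest
from .classifier import EccentricityModel, GazeStream, classify, fixation_stable, \
    params_for_eccentricity
from .geometry import Placement, ScreenModel, ViewerState, angles_to_px, \
    field_offset_to_px, screen_angular_extent
from .grid import ROLE_BLIND_SPOT, ROLE_TEST, GridLocation, TestGrid, growth_pattern
from .observer import HillModel, SimulatedObserver, gaze_stream, normative_mean, respond
from .zest import PriorSpec, ZestConfig, ZestState

__all__ = [
    "SessionConfig",
    "TrialRecord",
    "TestResult",
    "run_session",
    "schedule_catch_trial",
    "estimate_error_rates",
]

TRIAL_TEST = "test"
TRIAL_CATCH_BLANK = "catch_blank"
TRIAL_CATCH_SUPRA = "catch_supra"
TRIAL_REFIXATION = "refixation"

OUTCOME_HIT = "hit"
OUTCOME_MISS = "miss"
OUTCOME_SKIPPED = "skipped"

#: default prior for blind-spot locations: sensitivity expected near 0
BLIND_SPOT_PRIOR = PriorSpec(healthy_mean=0.0, healthy_sd=3.0,
                             abnormal_mean=0.0, abnormal_sd=3.0,
                             abnormal_weight=1.0)


@dataclass(frozen=True)
class SessionConfig:
    catch_probability: float = 0.07
    max_placement_retries: int = 3
    fixation_window: int = 10
    dispersion_limit_deg: float = 1.0
    response_mode: str = "gaze"       # "gaze" or "direct"
    trial_slack_s: float = 0.5        # stream length beyond the deadline
    max_trials: int = 3000
    refixation_noise_deg: float = 0.5
    blind_spot_prior: PriorSpec = BLIND_SPOT_PRIOR

    def __post_init__(self) -> None:
        if not 0.0 <= self.catch_probability <= 0.5:
            raise ValueError("catch_probability must be in [0, 0.5]")
        if self.response_mode not in ("gaze", "direct"):
            raise ValueError("response_mode must be 'gaze' or 'direct'")


@dataclass(frozen=True)
class TrialRecord:
    index: int
    type: str
    location: tuple[float, float] | None
    stimulus_db: float | None
    placement_px: tuple[float, float] | None
    outcome: str
    viewing_distance_cm: float


@dataclass
class TestResult:
    """Everything one session produced."""

    grid: TestGrid
    estimates: np.ndarray            # aligned with grid.locations, dB
    posterior_sds: np.ndarray        # final posterior SD per location, dB
    n_presentations: np.ndarray
    terminated: np.ndarray           # bool per location
    unmeasured: np.ndarray           # bool per location
    trials: list[TrialRecord]
    n_trials_by_type: dict[str, int]
    fp_rate_est: float | None
    fn_rate_est: float | None
    seed: int
    states: dict[tuple[float, float], ZestState] = field(default_factory=dict)

    @property
    def n_refixations(self) -> int:
        return self.n_trials_by_type.get(TRIAL_REFIXATION, 0)

    def estimate_at(self, x: float, y: float) -> float:
        for i, loc in enumerate(self.grid):
            if loc.x == x and loc.y == y:
                return float(self.estimates[i])
        raise KeyError(f"no location at ({x}, {y})")


def schedule_catch_trial(rng: np.random.Generator,
                         config: SessionConfig) -> str | None:
    """Per-trial catch decision: None, blank, or suprathreshold (50/50)."""
    if rng.random() >= config.catch_probability:
        return None
    return TRIAL_CATCH_BLANK if rng.random() < 0.5 else TRIAL_CATCH_SUPRA


def estimate_error_rates(trials: Iterable[TrialRecord],
                         ) -> tuple[float | None, float | None]:
    """(fp, fn) from catch trials; None (undefined) on a zero denominator."""
    blanks = supras = blank_hits = supra_misses = 0
    for t in trials:
        if t.type == TRIAL_CATCH_BLANK:
            blanks += 1
            blank_hits += t.outcome == OUTCOME_HIT
        elif t.type == TRIAL_CATCH_SUPRA:
            supras += 1
            supra_misses += t.outcome == OUTCOME_MISS
    fp = blank_hits / blanks if blanks else None
    fn = supra_misses / supras if supras else None
    return fp, fn


def _refixation_point(offset_deg: tuple[float, float], viewer: ViewerState,
                      screen: ScreenModel, rng: np.random.Generator,
                      jitter_deg: float = 0.0) -> tuple[float, float]:
    """A fixation point from which ``offset_deg`` should be placeable.

    Solves, per axis, for the fixation angle nearest straight-ahead that
    keeps both fixation and target comfortably on-screen; optional jitter
    lets retries escape prohibited zones.
    """
    ew, eh = screen_angular_extent(screen, viewer.viewing_distance_cm)
    margin = 1.0

    def solve(off: float, half_extent: float) -> float:
        # the target must stay on-screen AND inside the trackable cone
        lo = max(-half_extent + margin - off, -half_extent + margin)
        hi = min(half_extent - margin - off, half_extent - margin)
        if lo > hi:  # no feasible fixation; aim at centre and let it fail
            return 0.0
        return min(max(0.0, lo), hi)

    half_x = min(ew / 2.0, viewer.trackbox_deg[0])
    half_y = min(eh / 2.0, viewer.trackbox_deg[1])
    ax = solve(offset_deg[0], half_x) + (rng.normal(0.0, jitter_deg) if jitter_deg else 0.0)
    ay = solve(offset_deg[1], half_y) + (rng.normal(0.0, jitter_deg) if jitter_deg else 0.0)
    px, py = angles_to_px((ax, ay), viewer.viewing_distance_cm, screen)
    px = min(max(px, 0.0), screen.width_px)
    py = min(max(py, 0.0), screen.height_px)
    return (px, py)


def _pretrial_fixation_stream(viewer_behavior, rng: np.random.Generator,
                              window: int) -> GazeStream:
    n = window
    t = np.arange(n) / viewer_behavior.sample_rate_hz
    jitter = viewer_behavior.fixation_jitter_sd_deg
    return GazeStream(
        t,
        rng.normal(0.0, jitter, n),
        rng.normal(0.0, jitter, n),
        rng.random(n) >= viewer_behavior.dropout_prob,
    )


def run_session(observer: SimulatedObserver, grid: TestGrid,
                seed: int = 0, *,
                zest_config: ZestConfig = ZestConfig(),
                ecc_model: EccentricityModel = EccentricityModel(),
                screen: ScreenModel = ScreenModel(),
                session: SessionConfig = SessionConfig(),
                normative_hill: HillModel = HillModel(),
                initial_distance_cm: float = 60.0,
                trackbox_deg: tuple[float, float] = (27.0, 15.0),
                ) -> TestResult:
    """Run one complete simulated (or direct-response) test.

    The normative hill supplies per-location prior means and the reference
    values against which neighbour deviations are computed when seeding
    later growth-pattern stages.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    viewer = ViewerState(initial_distance_cm, screen.center_px, trackbox_deg)
    behavior = observer.behavior
    db_max = zest_config.domain[-1]

    stages = growth_pattern(grid)
    normative = {loc.key: normative_mean(normative_hill, loc.x, loc.y, db_max)
                 for loc in grid if loc.role == ROLE_TEST}
    loc_by_key = {loc.key: loc for loc in grid}

    states: dict[tuple[float, float], ZestState] = {}
    unmeasured: set[tuple[float, float]] = set()
    completed: dict[tuple[float, float], float] = {}

    def activate(locs: Iterable[GridLocation]) -> None:
        for loc in locs:
            if loc.role == ROLE_BLIND_SPOT:
                prior = session.blind_spot_prior
            else:
                prior = replace(zest_config.prior, healthy_mean=normative[loc.key])
                prior = _zest.seed_from_neighbors(loc, completed, normative, prior)
            states[loc.key] = _zest.new_state(zest_config, prior, loc)

    activate(grid.blind_spot_locations)
    stage_idx = 0
    activate(stages[stage_idx])

    trials: list[TrialRecord] = []
    counts = {TRIAL_TEST: 0, TRIAL_CATCH_BLANK: 0, TRIAL_CATCH_SUPRA: 0,
              TRIAL_REFIXATION: 0}

    def record(type_: str, loc_key, stim, px, outcome) -> None:
        trials.append(TrialRecord(len(trials), type_, loc_key, stim, px,
                                  outcome, viewer.viewing_distance_cm))
        counts[type_] += 1

    def stage_done() -> bool:
        return all(states[l.key].terminated or l.key in unmeasured
                   for l in stages[stage_idx])

    def note_completed() -> None:
        for key, st in states.items():
            if st.terminated and key not in completed \
                    and loc_by_key[key].role == ROLE_TEST:
                completed[key] = _zest.estimate(st, zest_config)

    while len(trials) < session.max_trials:
        note_completed()
        while stage_done() and stage_idx + 1 < len(stages):
            stage_idx += 1
            activate(stages[stage_idx])
        active = [k for k, st in states.items()
                  if not st.terminated and k not in unmeasured]
        if not active:
            break

        catch_type = schedule_catch_trial(rng, session)
        if catch_type is not None:
            test_keys = [k for k in states
                         if loc_by_key[k].role == ROLE_TEST and k not in unmeasured]
            loc = loc_by_key[test_keys[rng.integers(len(test_keys))]]
        else:
            loc = loc_by_key[active[rng.integers(len(active))]]

        # gate on fixation stability (only meaningful when gaze is simulated)
        if session.response_mode == "gaze":
            pre = _pretrial_fixation_stream(behavior, rng, session.fixation_window)
            if not fixation_stable(pre, session.fixation_window,
                                   session.dispersion_limit_deg):
                _recenter(viewer, screen, session, rng)
                record(TRIAL_REFIXATION, None, None, None, OUTCOME_SKIPPED)
                continue

        offset = loc.key
        placement = field_offset_to_px(offset, viewer, screen)
        retries = 0
        while not placement.valid and retries < session.max_placement_retries:
            # jitter the refixation cue only to escape prohibited zones;
            # for edge/trackbox failures the solved point is already optimal
            jitter = 2.0 if placement.reason == "prohibited_zone" else 0.0
            target = _refixation_point(offset, viewer, screen, rng,
                                       jitter_deg=jitter)
            viewer.fixation_px = _with_noise(target, session.refixation_noise_deg,
                                             viewer, screen, rng)
            record(TRIAL_REFIXATION, None, None, None, OUTCOME_SKIPPED)
            placement = field_offset_to_px(offset, viewer, screen)
            retries += 1
        if not placement.valid:
            if catch_type is None:
                unmeasured.add(loc.key)
            record(catch_type or TRIAL_TEST, loc.key, None, None, OUTCOME_SKIPPED)
            continue

        if catch_type == TRIAL_CATCH_BLANK:
            stimulus = None
        elif catch_type == TRIAL_CATCH_SUPRA:
            stimulus = 0.0  # maximal luminance = zero attenuation
        else:
            stimulus = _zest.next_stimulus(states[loc.key], zest_config)

        seen = respond(observer, loc, stimulus, rng)
        if session.response_mode == "direct":
            hit = seen
        else:
            params = params_for_eccentricity(offset, ecc_model)
            stream = gaze_stream(observer, seen, offset,
                                 params.deadline_s + session.trial_slack_s,
                                 rng, viewer.trackbox_deg)
            hit = classify(stream, offset, params).hit

        record(catch_type or TRIAL_TEST, loc.key, stimulus, placement.px,
               OUTCOME_HIT if hit else OUTCOME_MISS)
        if catch_type is None:
            _zest.update(states[loc.key], stimulus, hit, zest_config)

        if hit:
            viewer.fixation_px = placement.px
        _drift_distance(viewer, behavior, rng)
    note_completed()

    estimates = np.empty(len(grid))
    post_sds = np.empty(len(grid))
    n_pres = np.zeros(len(grid), dtype=int)
    terminated = np.zeros(len(grid), dtype=bool)
    unmeasured_arr = np.zeros(len(grid), dtype=bool)
    for i, loc in enumerate(grid):
        st = states.get(loc.key)
        if st is None or loc.key in unmeasured:
            estimates[i] = np.nan
            post_sds[i] = np.nan
            unmeasured_arr[i] = True
            continue
        estimates[i] = _zest.estimate(st, zest_config)
        post_sds[i] = _zest.posterior_sd(st, zest_config)
        n_pres[i] = st.n_presentations
        terminated[i] = st.terminated

    fp_est, fn_est = estimate_error_rates(trials)
    return TestResult(grid, estimates, post_sds, n_pres, terminated,
                      unmeasured_arr, trials, counts, fp_est, fn_est, seed,
                      states)


def _with_noise(px: tuple[float, float], noise_deg: float, viewer: ViewerState,
                screen: ScreenModel, rng: np.random.Generator) -> tuple[float, float]:
    """Fixation compliance noise: the eye lands near, not on, the cue."""
    if noise_deg <= 0:
        return px
    ppd = screen.px_per_cm_x * viewer.viewing_distance_cm * np.tan(np.radians(1.0))
    x = px[0] + rng.normal(0.0, noise_deg) * ppd
    y = px[1] + rng.normal(0.0, noise_deg) * ppd
    return (min(max(x, 0.0), screen.width_px), min(max(y, 0.0), screen.height_px))


def _recenter(viewer: ViewerState, screen: ScreenModel, session: SessionConfig,
              rng: np.random.Generator) -> None:
    viewer.fixation_px = _with_noise(screen.center_px, session.refixation_noise_deg,
                                     viewer, screen, rng)


def _drift_distance(viewer: ViewerState, behavior, rng: np.random.Generator,
                    lo: float = 50.0, hi: float = 70.0) -> None:
    if behavior.distance_drift_sd_cm <= 0:
        return
    d = viewer.viewing_distance_cm + rng.normal(0.0, behavior.distance_drift_sd_cm)
    viewer.viewing_distance_cm = float(min(max(d, lo), hi))
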