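import numpy as np
import pytest

from gazeperim.geometry import ScreenModel
from gazeperim.grid import ROLE_TEST, build_grid
from gazeperim.observer import HillModel, ObserverBehavior, sample_observer
from gazeperim.session import (
    SessionConfig,
    TrialRecord,
    estimate_error_rates,
    run_session,
    schedule_catch_trial,
)

DIRECT = SessionConfig(response_mode="direct")


def flat_session(right_grid, flat_hill, flat_observer, seed=42, **kwargs):
    return run_session(flat_observer, right_grid, seed,
                       normative_hill=flat_hill, **kwargs)


class TestFullSession:
    def test_flat_field_recovery(self, right_grid, flat_hill, flat_observer):
        res = flat_session(right_grid, flat_hill, flat_observer)
        test_mask = np.array([l.role == ROLE_TEST for l in right_grid])
        measured = test_mask & ~res.unmeasured
        assert measured.sum() >= 40
        assert np.all(np.abs(res.estimates[measured] - 20.0) < 3.0)
        assert np.mean(np.abs(res.estimates[measured] - 20.0)) < 1.5

    def test_blind_spots_fall_well_below_their_neighbors(self, right_grid, flat_hill,
                                                         flat_observer):
        res = flat_session(right_grid, flat_hill, flat_observer)
        for bs in right_grid.blind_spot_locations:
            est = res.estimate_at(bs.x, bs.y)
            neighbor_vals = [
                res.estimate_at(l.x, l.y) for l in right_grid.test_locations
                if max(abs(l.x - bs.x), abs(l.y - bs.y)) <= 6.0
                and not np.isnan(res.estimate_at(l.x, l.y))
            ]
            assert est < min(neighbor_vals) - 5.0

    def test_same_seed_reproduces_the_session_exactly(self, right_grid, flat_hill,
                                                      flat_observer):
        a = flat_session(right_grid, flat_hill, flat_observer, seed=9)
        b = flat_session(right_grid, flat_hill, flat_observer, seed=9)
        np.testing.assert_array_equal(a.estimates, b.estimates)
        assert a.trials == b.trials
        c = flat_session(right_grid, flat_hill, flat_observer, seed=10)
        assert a.trials != c.trials

    def test_termination_bound_holds_at_every_noncapped_location(
            self, right_grid, flat_hill, flat_observer):
        res = flat_session(right_grid, flat_hill, flat_observer)
        capped = res.n_presentations >= 20
        done = res.terminated & ~capped & ~res.unmeasured
        assert done.any()
        assert np.nanmax(res.posterior_sds[done]) <= 1.5

    def test_catch_trials_never_touch_threshold_states(self, right_grid, flat_hill,
                                                       flat_observer):
        res = flat_session(right_grid, flat_hill, flat_observer,
                           session=SessionConfig(catch_probability=0.3))
        presented = sum(1 for t in res.trials
                        if t.type == "test" and t.outcome in ("hit", "miss"))
        assert presented == int(res.n_presentations.sum())
        n_catch = sum(1 for t in res.trials if t.type.startswith("catch"))
        assert n_catch > 0

    def test_growth_pattern_order_is_respected(self, right_grid, flat_hill,
                                               flat_observer):
        res = flat_session(right_grid, flat_hill, flat_observer)
        group_of = {l.key: l.group for l in right_grid}
        last_seen_stage = 0
        first_idx: dict[int, int] = {}
        for t in res.trials:
            if t.type != "test" or t.location is None:
                continue
            g = group_of[t.location]
            if g == 0:
                continue  # blind spot: tested throughout
            first_idx.setdefault(g, t.index)
        stages = sorted(first_idx)
        assert stages == list(range(1, len(stages) + 1))
        assert all(first_idx[a] < first_idx[b]
                   for a, b in zip(stages, stages[1:]))

    def test_direct_mode_skips_gaze_but_matches_contract(self, right_grid, flat_hill,
                                                         flat_observer):
        res = flat_session(right_grid, flat_hill, flat_observer, session=DIRECT)
        assert res.terminated.sum() + res.unmeasured.sum() >= 46
        assert res.n_trials_by_type["refixation"] >= 0

    def test_unplaceable_location_is_flagged_not_fatal(self, right_grid, flat_hill,
                                                       flat_observer):
        # trackbox so narrow that |x| >= 21 can never be placed validly
        res = flat_session(right_grid, flat_hill, flat_observer, session=DIRECT,
                           trackbox_deg=(10.0, 10.0))
        far = [i for i, l in enumerate(right_grid) if abs(l.x) >= 21.0]
        assert res.unmeasured[far].all()
        assert np.isnan(res.estimates[far]).all()
        others = np.ones(len(right_grid), dtype=bool)
        others[far] = False
        assert res.terminated[others].sum() > 30  # the session carried on


class TestCatchTrials:
    def test_zero_probability_schedules_none(self, rng):
        cfg = SessionConfig(catch_probability=0.0)
        assert all(schedule_catch_trial(rng, cfg) is None for _ in range(1000))

    def test_blank_supra_split_is_even(self, rng):
        cfg = SessionConfig(catch_probability=0.07)
        kinds = [schedule_catch_trial(rng, cfg) for _ in range(20000)]
        n_blank = sum(k == "catch_blank" for k in kinds)
        n_supra = sum(k == "catch_supra" for k in kinds)
        total = n_blank + n_supra
        assert total == pytest.approx(20000 * 0.07, abs=4 * np.sqrt(20000 * 0.07 * 0.93))
        assert n_blank / total == pytest.approx(0.5, abs=4 * np.sqrt(0.25 / total))

    def test_catch_rate_among_stimulus_trials_matches_default(self, right_grid):
        """~7% of stimulus presentations are catch trials (binomial bounds)."""
        hill = HillModel()
        n_catch = n_stim = 0
        for s in range(6):
            obs = sample_observer(hill, right_grid, ObserverBehavior(), seed=s)
            res = run_session(obs, right_grid, 300 + s, normative_hill=hill)
            c = res.n_trials_by_type
            n_catch += c["catch_blank"] + c["catch_supra"]
            n_stim += c["catch_blank"] + c["catch_supra"] + c["test"]
        p = n_catch / n_stim
        se = np.sqrt(0.07 * 0.93 / n_stim)
        assert p == pytest.approx(0.07, abs=4 * se)

    def test_invalid_catch_probability_rejected(self):
        with pytest.raises(ValueError):
            SessionConfig(catch_probability=0.9)


class TestErrorRates:
    @staticmethod
    def rec(i, type_, outcome):
        return TrialRecord(i, type_, (9.0, 9.0), None, None, outcome, 60.0)

    def test_clean_blanks_give_zero_fp(self):
        trials = [self.rec(i, "catch_blank", "miss") for i in range(10)]
        assert estimate_error_rates(trials) == (0.0, None)

    def test_one_missed_supra_in_ten(self):
        trials = [self.rec(i, "catch_supra", "hit") for i in range(9)]
        trials.append(self.rec(9, "catch_supra", "miss"))
        fp, fn = estimate_error_rates(trials)
        assert fp is None and fn == pytest.approx(0.1)

    def test_no_catch_trials_is_undefined_not_zero(self):
        trials = [self.rec(0, "test", "hit")]
        assert estimate_error_rates(trials) == (None, None)
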