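import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazeperim.stats import (
    bca_bootstrap_ci,
    bland_altman,
    cor95,
    cor_difference_test,
    mean_sensitivity,
    min_detectable_difference,
    normative_table,
    pointwise_comparison,
)


class TestMeanSensitivity:
    def test_constant_field(self, right_grid):
        assert mean_sensitivity(np.full(46, 20.0), right_grid) == 20.0

    def test_blind_spots_have_no_influence(self, right_grid):
        lo = np.full(46, 20.0)
        hi = lo.copy()
        for i, l in enumerate(right_grid):
            if l.role == "blind_spot":
                lo[i], hi[i] = 0.0, 34.0
        assert mean_sensitivity(lo, right_grid) == mean_sensitivity(hi, right_grid)

    def test_closed_form_mean(self, right_grid):
        vals = np.zeros(46)
        test_idx = [i for i, l in enumerate(right_grid) if l.role == "test"]
        vals[test_idx] = np.arange(44) / 43.0 * 34.0
        assert mean_sensitivity(vals, right_grid) == pytest.approx(17.0)


class TestBlandAltman:
    def test_identical_runs(self):
        rep = bland_altman(np.arange(10.0), np.arange(10.0))
        assert rep.mean_difference == 0.0 and rep.cor95 == 0.0
        assert rep.limits_of_agreement == (0.0, 0.0)

    def test_plus_minus_one_differences(self):
        rep = bland_altman(np.array([10.0, 10.0]), np.array([11.0, 9.0]))
        assert rep.mean_difference == 0.0
        assert rep.cor95 == pytest.approx(1.96 * np.sqrt(2.0), abs=1e-12)

    def test_constant_shift_moves_mean_not_cor(self, rng):
        r1 = rng.normal(20, 2, 30)
        r2 = r1 + rng.normal(0, 1, 30)
        a = bland_altman(r1, r2)
        b = bland_altman(r1, r2 + 5.0)
        assert b.mean_difference == pytest.approx(a.mean_difference + 5.0)
        assert b.cor95 == pytest.approx(a.cor95)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 64))
    def test_matches_explicit_loop_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        r1, r2 = rng.normal(20, 3, (2, n))
        rep = bland_altman(r1, r2)
        # oracle: explicit loop arithmetic, no numpy reductions
        diffs = [b - a for a, b in zip(r1, r2)]
        mu = sum(diffs) / n
        var = sum((d - mu) ** 2 for d in diffs) / (n - 1)
        assert rep.mean_difference == pytest.approx(mu, abs=1e-12)
        assert rep.cor95 == pytest.approx(1.96 * var ** 0.5, abs=1e-12)


class TestBcaBootstrap:
    def test_constant_data_gives_zero_width(self):
        assert bca_bootstrap_ci(np.mean, np.full(20, 7.0), n_boot=200, seed=0) == (7.0, 7.0)

    def test_seed_determinism_and_permutation_invariance(self, rng):
        d = rng.normal(0, 1, 100)
        a = bca_bootstrap_ci(np.mean, d, n_boot=1000, seed=3)
        b = bca_bootstrap_ci(np.mean, d, n_boot=1000, seed=3)
        c = bca_bootstrap_ci(np.mean, rng.permutation(d), n_boot=1000, seed=3)
        assert a == b == c

    def test_interval_brackets_the_point_estimate(self, rng):
        d = rng.normal(5, 2, 80)
        lo, hi = bca_bootstrap_ci(np.mean, d, n_boot=1000, seed=1)
        assert lo < np.mean(d) < hi


class TestCorDifference:
    def test_identical_devices_give_p_one(self, rng):
        runs = rng.normal(20, 1, (30, 2))
        delta, p = cor_difference_test(runs, runs.copy(), n_boot=500, seed=0)
        assert delta == 0.0
        assert p == 1.0

    def test_p_is_always_in_unit_interval(self, rng):
        a = rng.normal(0, 3, (20, 2))
        b = rng.normal(0, 1, (20, 2))
        _, p = cor_difference_test(a, b, n_boot=200, seed=0)
        assert 0.0 < p <= 1.0

    def test_detects_a_threefold_noise_difference(self):
        hits = 0
        for i in range(20):
            r = np.random.default_rng(1000 + i)
            a = 20.0 + r.normal(0, 3, (64, 2))
            b = 20.0 + r.normal(0, 1, (64, 2))
            delta, p = cor_difference_test(a, b, n_boot=1000, seed=i)
            assert delta > 0
            hits += p < 0.05
        assert hits >= 19

    def test_too_few_observers_rejected(self, rng):
        with pytest.raises(ValueError):
            cor_difference_test(rng.normal(size=(1, 2)), rng.normal(size=(1, 2)))


class TestPointwise:
    def test_identical_data_flags_nothing(self, right_grid, rng):
        a = rng.normal(20, 2, (30, 46))
        out = pointwise_comparison(a, a.copy(), right_grid)
        assert (out.verdict == "ns").all()

    def test_single_shifted_location_is_isolated(self, right_grid, rng):
        a = rng.normal(20, 0.1, (30, 46))
        b = a + rng.normal(0, 0.1, (30, 46))
        shift_idx = right_grid.index_of(right_grid.location_at(9.0, 9.0))
        a = a.copy()
        a[:, shift_idx] += 10.0
        out = pointwise_comparison(a, b, right_grid)
        flagged = out[out.verdict != "ns"]
        assert list(flagged.index) == [shift_idx]
        assert flagged.verdict.iloc[0] == "a_higher"

    def test_bonferroni_uses_the_44_test_locations(self, right_grid, rng):
        # a raw p between alpha/44 and alpha/46 must not change the verdict
        # count relative to an explicit alpha/44 threshold
        a = rng.normal(20, 1, (40, 46))
        b = rng.normal(20, 1, (40, 46))
        out = pointwise_comparison(a, b, right_grid, alpha=0.01)
        from scipy.stats import ttest_rel
        _, p = ttest_rel(a, b, axis=0)
        test_mask = np.array([l.role == "test" for l in right_grid])
        expected = int(((p < 0.01 / 44) & test_mask).sum())
        assert int((out.verdict != "ns").sum()) == expected


class TestNormativeTable:
    def test_constant_cohort_collapses_percentiles(self, right_grid):
        vals = np.full((10, 46), 21.0)
        tab = normative_table(vals, right_grid)
        assert len(tab) == 46
        assert (tab.mean_db == 21.0).all()
        assert (tab["p2.5_db"] == 21.0).all() and (tab["p97.5_db"] == 21.0).all()

    def test_hand_computed_linear_percentiles(self, right_grid):
        col = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        vals = np.tile(col[:, None], (1, 46))
        tab = normative_table(vals, right_grid)
        # linear interpolation: p2.5 = 1 + 0.025*4*1 = 1.1; p97.5 = 4.9
        assert tab["p2.5_db"].iloc[0] == pytest.approx(1.1)
        assert tab["p97.5_db"].iloc[0] == pytest.approx(4.9)

    def test_left_eye_values_are_reported_in_right_eye_format(self, left_grid):
        vals = np.zeros((3, 46))
        tab = normative_table(vals, left_grid)
        blind = tab[tab.role == "blind_spot"]
        assert set(blind.x_deg) == {15.0}


class TestMinDetectableDifference:
    def test_reproduces_the_cohort_power_analysis(self):
        # n=64, sd of paired MS differences 1.548 dB, alpha 0.05, power 0.80
        assert min_detectable_difference(64, 1.548) == pytest.approx(0.55, abs=0.005)

    def test_zero_sd_means_zero_difference(self):
        assert min_detectable_difference(10, 0.0) == 0.0

    def test_strictly_decreasing_in_n(self):
        vals = [min_detectable_difference(n, 1.5) for n in (4, 8, 16, 32, 64, 128)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            min_detectable_difference(1, 1.0)
        with pytest.raises(ValueError):
            min_detectable_difference(10, 1.0, alpha=1.5)
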