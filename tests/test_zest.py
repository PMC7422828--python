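import math

import numpy as np
import pytest
from scipy import stats as sps

from gazeperim.grid import GridLocation
from gazeperim.zest import (
    PriorSpec,
    ZestConfig,
    ZestState,
    estimate,
    is_terminated,
    make_prior,
    new_state,
    next_stimulus,
    p_seen,
    posterior_sd,
    run_to_termination,
    seed_from_neighbors,
    update,
)

CFG = ZestConfig()


def two_point_state(domain=(10.0, 20.0), pmf=(0.5, 0.5), n=0):
    cfg = ZestConfig(db_domain=domain)
    return ZestState(np.asarray(pmf, dtype=float), n_presentations=n), cfg


class TestPrior:
    def test_unimodal_when_no_abnormal_weight(self):
        spec = PriorSpec(healthy_mean=25.0, abnormal_weight=0.0)
        pmf = make_prior(spec, CFG)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert CFG.domain[np.argmax(pmf)] == 25.0

    def test_pure_abnormal_mode(self):
        spec = PriorSpec(abnormal_mean=5.0, abnormal_weight=1.0)
        pmf = make_prior(spec, CFG)
        assert CFG.domain[np.argmax(pmf)] == 5.0

    def test_all_mass_off_domain_rejected(self):
        spec = PriorSpec(healthy_mean=1e6, healthy_sd=1e-3, abnormal_weight=0.0)
        with pytest.raises(ValueError):
            make_prior(spec, CFG)


class TestFrequencyOfSeeing:
    def test_half_at_threshold(self):
        assert p_seen(20.0, 20.0, 1.25) == pytest.approx(0.5)

    def test_four_sigma_brighter_is_almost_certain(self):
        # stimulus 5 dB below (brighter than) threshold with sigma 1.25
        assert p_seen(15.0, 20.0, 1.25) == pytest.approx(sps.norm.cdf(4.0), abs=1e-12)
        assert p_seen(15.0, 20.0, 1.25) == pytest.approx(0.99997, abs=1e-5)

    def test_symmetry_about_threshold(self):
        for delta in (0.5, 1.0, 3.0):
            assert p_seen(20.0 - delta, 20.0, 1.25) + p_seen(20.0 + delta, 20.0, 1.25) \
                == pytest.approx(1.0, abs=1e-12)

    def test_guess_and_lapse_bound_the_curve(self):
        assert p_seen(34.0, 0.0, 1.25, guess_rate=0.03) == pytest.approx(0.03, abs=1e-6)
        assert p_seen(0.0, 34.0, 1.25, lapse_rate=0.05) == pytest.approx(0.95, abs=1e-6)


class TestUpdate:
    def test_two_point_prior_seen_response(self):
        state, cfg = two_point_state()
        update(state, 15.0, True, cfg)
        phi4 = sps.norm.cdf(4.0)
        expected = phi4 / (phi4 + sps.norm.cdf(-4.0))
        assert state.pmf[1] == pytest.approx(expected, abs=1e-12)

    def test_two_point_prior_unseen_response(self):
        state, cfg = two_point_state()
        update(state, 15.0, False, cfg)
        phi4 = sps.norm.cdf(4.0)
        assert state.pmf[0] == pytest.approx(phi4 / (phi4 + sps.norm.cdf(-4.0)),
                                             abs=1e-12)

    def test_alternating_responses_keep_symmetry(self):
        # presentation floor keeps the state updatable for all four trials
        cfg = ZestConfig(min_presentations=10, max_presentations=10)
        n = len(cfg.domain)
        state = ZestState(np.full(n, 1.0 / n))
        for seen in (True, False, True, False):
            update(state, 17.0, seen, cfg)
        # symmetric about 17: pmf[17+k] == pmf[17-k]
        for k in range(1, 18):
            assert state.pmf[17 + k] == pytest.approx(state.pmf[17 - k], abs=1e-12)

    def test_update_counts_and_termination_flag(self):
        state = new_state(CFG)
        update(state, 20.0, True, CFG)
        assert state.n_presentations == 1
        with pytest.raises(RuntimeError):
            update(ZestState(np.array([1.0, 0.0]), terminated=True), 1, True,
                   ZestConfig(db_domain=(0.0, 1.0)))


class TestPlacementAndTermination:
    def test_symmetric_pmf_places_at_center(self):
        cfg = ZestConfig()
        pmf = np.zeros(35)
        pmf[[15, 17, 19]] = [0.25, 0.5, 0.25]
        assert next_stimulus(ZestState(pmf), cfg) == 17.0

    def test_point_mass_places_on_itself(self):
        cfg = ZestConfig()
        pmf = np.zeros(35)
        pmf[3] = 1.0
        assert next_stimulus(ZestState(pmf), cfg) == 3.0

    def test_halfway_mean_rounds_down_to_the_brighter_level(self):
        state, cfg = two_point_state(domain=(16.0, 17.0))  # mean 16.5
        assert next_stimulus(state, cfg) == 16.0

    def test_point_mass_is_terminated(self):
        pmf = np.zeros(35)
        pmf[10] = 1.0
        assert is_terminated(ZestState(pmf, n_presentations=1), CFG)

    def test_uniform_prior_is_not_terminated(self):
        state = ZestState(np.full(35, 1 / 35), n_presentations=1)
        assert posterior_sd(state, CFG) == pytest.approx(math.sqrt((35**2 - 1) / 12),
                                                         abs=1e-9)
        assert not is_terminated(state, CFG)

    def test_termination_is_inclusive_at_the_bound(self):
        # two equal masses 3 dB apart have SD exactly 1.5
        state, cfg = two_point_state(domain=(18.0, 21.0), n=1)
        assert posterior_sd(state, cfg) == pytest.approx(1.5, abs=1e-12)
        assert is_terminated(state, cfg)

    def test_minimum_presentations_floor(self):
        pmf = np.zeros(35)
        pmf[10] = 1.0
        assert not is_terminated(ZestState(pmf, n_presentations=0), CFG)

    def test_estimate_is_posterior_mean_clamped(self):
        pmf = np.zeros(35)
        pmf[22] = 1.0
        assert estimate(ZestState(pmf), CFG) == 22.0
        state, cfg = two_point_state()
        assert estimate(state, cfg) == 15.0
        lo = ZestState(np.array([1.0, 0.0]))
        assert 0.0 <= estimate(lo, ZestConfig(db_domain=(0.0, 1.0))) <= 1.0


class TestNeighborSeeding:
    LOC = GridLocation(9.0, 9.0)

    def test_normative_neighbors_leave_prior_unchanged(self):
        spec = PriorSpec(healthy_mean=22.0)
        out = seed_from_neighbors(self.LOC, {(3.0, 9.0): 20.0}, {(3.0, 9.0): 20.0}, spec)
        assert out == spec

    def test_depressed_neighbors_lower_the_healthy_mode(self):
        spec = PriorSpec(healthy_mean=22.0)
        completed = {(3.0, 9.0): 16.0, (9.0, 3.0): 16.0}
        normative = {(3.0, 9.0): 20.0, (9.0, 3.0): 20.0}
        out = seed_from_neighbors(self.LOC, completed, normative, spec)
        assert out.healthy_mean == pytest.approx(18.0)

    def test_distant_completions_are_ignored(self):
        spec = PriorSpec(healthy_mean=22.0)
        out = seed_from_neighbors(self.LOC, {(-21.0, -9.0): 2.0}, {(-21.0, -9.0): 20.0},
                                  spec)
        assert out == spec


class TestOracleEquivalence:
    """Sequential updates must equal the brute-force product posterior."""

    def brute_force(self, prior, domain, trials, sigma):
        post = np.asarray(prior, dtype=float).copy()
        for s, seen in trials:
            like = sps.norm.cdf((np.asarray(domain) - s) / sigma)
            post *= like if seen else (1.0 - like)
        return post / post.sum()

    def test_engine_matches_brute_force_on_random_sequences(self, rng):
        domain = (0.0, 8.0, 16.0, 24.0, 32.0)
        cfg = ZestConfig(db_domain=domain, max_presentations=100,
                         min_presentations=100)
        for _ in range(50):
            prior = rng.dirichlet(np.ones(5))
            state = ZestState(prior.copy())
            trials = []
            for _ in range(rng.integers(1, 7)):
                s = float(rng.choice(domain))
                seen = bool(rng.random() < 0.5)
                trials.append((s, seen))
                try:
                    update(state, s, seen, cfg)
                except ValueError:
                    break  # numerically impossible sequence; brute force agrees
            expected = self.brute_force(prior, domain, trials[:state.n_presentations],
                                        cfg.likelihood_slope_sigma)
            np.testing.assert_allclose(state.pmf, expected, atol=1e-12)


def test_posterior_sd_contracts_for_consistent_observer(rng):
    """Mean posterior SD decreases with presentations (Monte Carlo)."""
    cfg = ZestConfig(max_presentations=8, termination_sd=1e-9,
                     min_presentations=8)
    sds = []
    for rep in range(100):
        state = new_state(cfg)
        true_t = 20.0
        trace = [posterior_sd(state, cfg)]
        while not state.terminated:
            s = next_stimulus(state, cfg)
            seen = rng.random() < p_seen(s, true_t, cfg.likelihood_slope_sigma)
            update(state, s, seen, cfg)
            trace.append(posterior_sd(state, cfg))
        sds.append(trace)
    mean_trace = np.mean(sds, axis=0)
    assert np.all(np.diff(mean_trace) < 0.25)  # monotone in expectation (slack for MC)
    assert mean_trace[-1] < mean_trace[0] / 2


def test_run_to_termination_recovers_a_deterministic_threshold():
    # step observer: sees everything brighter (lower dB) than 18
    state, stimuli = run_to_termination(lambda s: s < 18.0, CFG,
                                        PriorSpec(healthy_mean=20.0))
    assert state.terminated
    assert estimate(state, CFG) == pytest.approx(17.5, abs=1.5)
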