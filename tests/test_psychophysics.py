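"""Psi staircase vs an independent brute-force oracle, MLE refit, designs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fogspeed.observer import ObserverParams, respond_2ifc
from fogspeed.psychophysics import (
    PsychometricModel,
    TrialRecord,
    build_design,
    build_production_design,
    default_grids,
    expected_entropies,
    fit_psychometric_mle,
    psi_estimate,
    psi_init,
    psi_select_stimulus,
    psi_update,
    run_staircase,
)

# ---------------------------------------------------------------------------
# independent brute-force oracle: naive Python loops, math-module functions
# ---------------------------------------------------------------------------


def _phi(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def _p_faster(v: float, pse: float, sigma: float, lapse: float) -> float:
    return lapse / 2.0 + (1.0 - lapse) * _phi((math.log(v) - math.log(pse)) / sigma)


def brute_expected_entropies(pse_grid, sigma_grid, candidates, posterior, lapse):
    out = []
    for v in candidates:
        s1 = s0 = 0.0
        cells = []
        for i, pse in enumerate(pse_grid):
            for j, sig in enumerate(sigma_grid):
                p = _p_faster(v, pse, sig, lapse)
                a = posterior[i, j] * p
                b = posterior[i, j] * (1.0 - p)
                s1 += a
                s0 += b
                cells.append((a, b))
        h1 = h0 = 0.0
        for a, b in cells:
            if s1 > 0 and a > 0:
                q = a / s1
                h1 -= q * math.log(q)
            if s0 > 0 and b > 0:
                q = b / s0
                h0 -= q * math.log(q)
        out.append(s1 * h1 + s0 * h0)
    return np.array(out)


def brute_posterior_update(pse_grid, sigma_grid, posterior, v, response, lapse):
    post = posterior.copy()
    for i, pse in enumerate(pse_grid):
        for j, sig in enumerate(sigma_grid):
            p = _p_faster(v, pse, sig, lapse)
            post[i, j] *= p if response else (1.0 - p)
    return post / post.sum()


def _trial(v, response, idx=0, cond="fog"):
    return TrialRecord(
        reference_speed=60.0,
        test_speed=v,
        condition=cond,
        order_ref_first=True,
        response_test_faster=response,
        trial_index=idx,
    )


class TestPsiInit:
    def test_single_cell_grid(self):
        state = psi_init([60.0], [0.2], [40.0, 60.0])
        assert state.posterior.shape == (1, 1)
        assert state.posterior[0, 0] == 1.0

    def test_uniform_prior(self):
        state = psi_init([50, 60, 70], [0.1, 0.3], [40, 60, 80])
        assert np.allclose(state.posterior, 1.0 / 6.0)

    def test_supplied_prior_normalised(self):
        prior = np.array([[2.0, 1.0], [1.0, 0.0]])
        state = psi_init([50, 60], [0.1, 0.3], [40, 60], prior=prior)
        assert state.posterior.sum() == pytest.approx(1.0, abs=1e-12)
        assert state.posterior[0, 0] == pytest.approx(0.5)

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            psi_init([], [0.2], [60.0])
        with pytest.raises(ValueError):
            psi_init([60.0, -1.0], [0.2], [60.0])


class TestOracleEquivalence:
    """Vectorised psi mechanics vs naive loops on grids up to 5x5x9."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_select_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pse_grid = np.geomspace(40, 90, 5)
        sigma_grid = np.geomspace(0.08, 0.6, 5)
        candidates = np.geomspace(30, 120, 9)
        prior = rng.dirichlet(np.ones(25)).reshape(5, 5)
        state = psi_init(pse_grid, sigma_grid, candidates, prior=prior, lapse=0.02)
        eh_fast = expected_entropies(state)
        eh_brute = brute_expected_entropies(pse_grid, sigma_grid, candidates, prior, 0.02)
        assert np.allclose(eh_fast, eh_brute, atol=1e-12)
        chosen = psi_select_stimulus(state)
        assert chosen == candidates[int(np.argmin(eh_brute))]

    def test_sequential_updates_match_brute_force(self):
        rng = np.random.default_rng(11)
        pse_grid = np.geomspace(45, 80, 3)
        sigma_grid = np.geomspace(0.1, 0.4, 3)
        candidates = np.geomspace(35, 100, 5)
        state = psi_init(pse_grid, sigma_grid, candidates, lapse=0.02)
        brute = state.posterior.copy()
        for k in range(12):
            v = float(rng.choice(candidates))
            resp = bool(rng.random() < 0.5)
            psi_update(state, _trial(v, resp, k))
            brute = brute_posterior_update(pse_grid, sigma_grid, brute, v, resp, 0.02)
            assert np.allclose(state.posterior, brute, atol=1e-12)
            assert state.posterior.sum() == pytest.approx(1.0, abs=1e-10)

    def test_consistent_low_speed_faster_responses_pull_pse_down(self):
        state = psi_init(*default_grids(60.0))
        low = float(state.candidate_stimuli[5])  # well below the reference
        before = psi_estimate(state)[0] if state.trial_log else math.exp(
            np.dot(state.posterior.sum(1), np.log(state.pse_grid))
        )
        for k in range(10):
            psi_update(state, _trial(low, True, k))
        after, _ = psi_estimate(state)
        assert after < before
        assert after < low * 1.1


class TestSelection:
    def test_single_cell_returns_lowest_candidate(self):
        state = psi_init([60.0], [0.2], [40.0, 60.0, 80.0])
        # all candidates equally (un)informative: tie broken toward low speed
        assert psi_select_stimulus(state) == 40.0

    def test_peaked_posterior_selects_rising_part(self):
        # sharply peaked (but not degenerate: an exact point mass has zero
        # entropy for every candidate) around pse 60, sigma 0.2
        pse_grid, sigma_grid, candidates = default_grids(60.0)
        lp = np.log(pse_grid)[:, None]
        ls = np.log(sigma_grid)[None, :]
        prior = np.exp(
            -((lp - math.log(60.0)) ** 2) / (2 * 0.05**2)
            - ((ls - math.log(0.2)) ** 2) / (2 * 0.1**2)
        )
        state = psi_init(pse_grid, sigma_grid, candidates, prior=prior)
        chosen = psi_select_stimulus(state)
        assert 30.0 < chosen < 120.0  # inside the rising region, not an extreme

    def test_symmetric_two_peak_posterior_selects_midpoint(self):
        # peaks at 50 and 72 are log-symmetric about 60; the most
        # discriminating stimulus is the midpoint candidate
        pse_grid = np.array([50.0, 60.0, 72.0])
        sigma_grid = np.array([0.2])
        candidates = np.array([50.0, 60.0, 72.0])
        prior = np.array([[0.5], [0.0], [0.5]])
        state = psi_init(pse_grid, sigma_grid, candidates, prior=prior)
        assert psi_select_stimulus(state) == 60.0


class TestUpdate:
    def test_flat_likelihood_leaves_posterior_unchanged(self):
        # lapse 1 makes every response probability 1/2 at every grid point
        state = psi_init([50, 60, 70], [0.1, 0.3], [40, 60, 80], lapse=1.0)
        before = state.posterior.copy()
        psi_update(state, _trial(60.0, True))
        assert np.allclose(state.posterior, before, atol=1e-15)

    def test_double_update_equals_squared_likelihood(self):
        grids = default_grids(60.0)
        s1 = psi_init(*grids)
        v = float(s1.candidate_stimuli[10])
        psi_update(s1, _trial(v, True, 0))
        psi_update(s1, _trial(v, True, 1))
        s2 = psi_init(*grids)
        lik = s2.likelihood_for_speed(v)
        expected = s2.posterior * lik**2
        expected /= expected.sum()
        assert np.allclose(s1.posterior, expected, atol=1e-12)

    def test_trial_log_grows(self):
        state = psi_init(*default_grids(60.0))
        psi_update(state, _trial(55.0, False))
        assert len(state.trial_log) == 1


class TestEstimate:
    def test_point_mass_posterior(self):
        prior = np.zeros((3, 2))
        prior[1, 1] = 1.0
        state = psi_init([40, 55, 70], [0.1, 0.3], [40, 60], prior=prior)
        state.trial_log.append(_trial(55.0, True))
        pse, jnd = psi_estimate(state)
        assert pse == pytest.approx(55.0)
        assert jnd == pytest.approx(0.3)

    def test_log_domain_mean(self):
        # uniform over pse {40, 90}: exp((ln40 + ln90)/2) = 60
        state = psi_init([40.0, 90.0], [0.2], [40, 60, 90])
        state.trial_log.append(_trial(60.0, True))
        pse, _ = psi_estimate(state)
        assert pse == pytest.approx(60.0, rel=1e-12)

    def test_warns_before_any_update(self):
        state = psi_init([40.0, 90.0], [0.2], [40, 60, 90])
        with pytest.warns(UserWarning):
            psi_estimate(state)


class TestPosteriorNormalisation:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 40), st.booleans()), min_size=1, max_size=60))
    def test_posterior_sums_to_one_after_any_update_sequence(self, moves):
        state = psi_init(*default_grids(60.0))
        for k, (ci, resp) in enumerate(moves):
            v = float(state.candidate_stimuli[ci])
            psi_update(state, _trial(v, resp, k))
            assert state.posterior.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(state.posterior >= 0)


class TestStaircaseRecovery:
    def test_recovers_biased_observer_pse(self):
        # smoke-scale recovery; the full 200-replicate sweep runs in the
        # acceptance suite
        true_pse = 47.7
        obs = ObserverParams(gains={"fog": 60.0 / true_pse}, noise_sigma=0.15)
        errs = []
        for rep in range(30):
            rng = np.random.default_rng(100 + rep)
            st_ = run_staircase(
                lambda v, r: respond_2ifc(obs, 60.0, v, "fog", r),
                60.0, 80, rng, "fog",
            )
            pse, _ = psi_estimate(st_)
            errs.append(abs(pse - true_pse) / true_pse)
        assert float(np.median(errs)) <= 0.05


class TestMLEFit:
    @staticmethod
    def _simulate_log(pse, sigma, lapse, n, seed):
        rng = np.random.default_rng(seed)
        speeds = np.geomspace(pse / 2.5, pse * 2.5, 11)
        trials = []
        for k in range(n):
            v = float(rng.choice(speeds))
            p = PsychometricModel(pse=pse, sigma=sigma, lapse=lapse).prob_test_faster(v)
            trials.append(_trial(v, bool(rng.random() < p), k))
        return trials

    def test_matches_dense_grid_search(self):
        trials = self._simulate_log(60.0, 0.25, 0.02, 40, seed=5)
        fit = fit_psychometric_mle(trials, lapse=0.02)
        v = np.array([t.test_speed for t in trials])
        y = np.array([t.response_test_faster for t in trials])
        pses = np.geomspace(v.min() / 4, v.max() * 4, 1200)
        sigmas = np.geomspace(0.01, 2.0, 600)
        from scipy.special import erf as _erf

        z = (np.log(v)[None, None, :] - np.log(pses)[:, None, None]) / (
            sigmas[None, :, None] * math.sqrt(2)
        )
        p = 0.01 + 0.98 * 0.5 * (1 + _erf(z))
        nll = -np.sum(np.where(y, np.log(p), np.log(1 - p)), axis=2)
        bi, bj = np.unravel_index(np.argmin(nll), nll.shape)
        assert fit.pse == pytest.approx(pses[bi], rel=0.01)
        assert fit.sigma == pytest.approx(sigmas[bj], rel=0.015)

    def test_parameter_recovery_large_sample(self):
        trials = self._simulate_log(60.0, 0.25, 0.02, 500, seed=11)
        fit = fit_psychometric_mle(trials, lapse=0.02)
        assert fit.pse == pytest.approx(60.0, rel=0.05)
        assert fit.sigma == pytest.approx(0.25, rel=0.2)
        assert not fit.boundary

    def test_uninformative_log_flagged_not_crashed(self):
        # responses split 50/50 at a single speed: unidentifiable
        trials = [_trial(60.0, k % 2 == 0, k) for k in range(20)]
        fit = fit_psychometric_mle(trials, lapse=0.02)
        assert fit.boundary

    def test_perfect_separation_flagged(self):
        trials = [_trial(40.0, False, 0), _trial(90.0, True, 1)] * 10
        fit = fit_psychometric_mle(trials, lapse=0.02)
        assert fit.boundary  # sigma driven to its lower bound


class TestDesignBuilder:
    def test_experiment1_totals(self):
        design, seq = build_design(
            ["clear", "fog_moderate", "fog_severe", "uniform_moderate", "uniform_severe"],
            [40.0, 60.0, 90.0], 80, seed=1,
        )
        assert design.total_trials == 1200
        assert len(seq) == 1200

    def test_experiment3_totals(self):
        design, seq = build_design(["clear", "fog", "antifog"], [60.0], 80, seed=2)
        assert design.total_trials == 240
        assert len(seq) == 240

    def test_single_trial_design(self):
        design, seq = build_design(["clear"], [60.0], 1, seed=0)
        assert design.total_trials == 1
        assert seq == [("clear", 60.0)]

    def test_each_staircase_appears_exactly_once_per_trial(self):
        _, seq = build_design(["a", "b"], [40.0, 60.0], 7, seed=3)
        from collections import Counter

        counts = Counter(seq)
        assert all(c == 7 for c in counts.values())
        assert len(counts) == 4

    def test_interleaving_is_seeded(self):
        _, s1 = build_design(["a", "b"], [40.0], 5, seed=9)
        _, s2 = build_design(["a", "b"], [40.0], 5, seed=9)
        _, s3 = build_design(["a", "b"], [40.0], 5, seed=10)
        assert s1 == s2
        assert s1 != s3

    def test_production_session_count(self):
        seq = build_production_design(
            ["clear", "fog_moderate", "fog_severe", "uniform_moderate", "uniform_severe"],
            [60.0], 5, seed=0,
        )
        assert len(seq) == 25

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            build_design([], [60.0], 5, seed=0)
        with pytest.raises(ValueError):
            build_design(["a"], [60.0], 0, seed=0)
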