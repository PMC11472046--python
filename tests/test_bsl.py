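"""Synthetic-likelihood rate inference: proposals, simulator, sampler."""

import numpy as np
import pytest
from scipy.linalg import expm

import hpdyn
from hpdyn.bsl import (
    BslConfig,
    ObservedTransitions,
    _simulate_summaries,
    hdi_interval,
    infer_rate_constants,
    matrix_log_rates,
    propose_rates,
    rate_pairs,
    rates_to_Q,
    synthetic_loglik,
)

EPE1_T = np.array([[0.992, 0.008], [0.21, 0.79]])


class _FixedRng:
    """Deterministic stand-in for a Generator in proposal unit tests."""

    def __init__(self, t, move, idx=0):
        self.t, self.move, self.idx = t, move, idx

    def standard_t(self, df):
        return self.t

    def integers(self, n):
        return self.move if n == 3 else self.idx


class TestProposals:
    def test_zero_draw_leaves_rates_unchanged(self):
        cur = np.array([0.3, 2.0])
        for move in range(3):
            prop = propose_rates(cur, BslConfig(), _FixedRng(t=0.0, move=move))
            assert np.array_equal(prop, cur)

    def test_paired_move_multiplies_opposing_rates(self):
        # 3-state system: the pair (0, 1) scales k_01 and k_10 only
        pairs = rate_pairs(3)
        cur = np.linspace(1.0, 6.0, 6)
        t = 1.7
        prop = propose_rates(cur, BslConfig(), _FixedRng(t=t, move=2, idx=0))
        f = np.exp(0.01 * t)
        for n, (i, j) in enumerate(pairs):
            if (i, j) in [(0, 1), (1, 0)]:
                assert prop[n] == pytest.approx(cur[n] * f, rel=1e-12)
            else:
                assert prop[n] == cur[n]

    def test_global_move_scale_divided_by_state_count_squared(self):
        cur = np.array([1.0, 1.0])
        t = 2.0
        prop = propose_rates(cur, BslConfig(), _FixedRng(t=t, move=1))
        assert np.allclose(prop, np.exp(0.02 * t / 4))

    def test_log_ratio_symmetric_about_zero(self):
        rng = np.random.default_rng(0)
        cur = np.array([0.5, 3.0])
        ratios = np.empty(20_000)
        for i in range(len(ratios)):
            prop = propose_rates(cur, BslConfig(), rng)
            ratios[i] = np.log(prop / cur).sum()
        se = ratios.std() / np.sqrt(len(ratios))
        assert abs(ratios.mean()) < 3 * se

    def test_proposals_stay_positive(self):
        rng = np.random.default_rng(1)
        cur = np.array([1e-6, 1e3])
        for _ in range(500):
            cur = propose_rates(cur, BslConfig(), rng)
            assert np.all(cur > 0)


class TestTransitionSimulator:
    def test_zero_rates_keep_all_molecules_in_place(self):
        cfg = BslConfig(M=5000)
        s = hpdyn.simulate_transition_summary(
            np.zeros(2), np.array([0.7, 0.3]), cfg, np.random.default_rng(0)
        ).reshape(2, 2)
        assert s[0, 1] == 0 and s[1, 0] == 0
        assert s.sum() == 5000

    def test_two_state_frame_fractions_match_matrix_exponential(self):
        # closed-form 2-state master equation: P(frame) = expm(Q * 0.04)
        rates = np.array([1.0, 2.0])
        pi = np.array([2 / 3, 1 / 3])
        cfg = BslConfig(M=100_000)
        sims = _simulate_summaries(rates, pi, cfg, np.random.default_rng(1), 50, 0.04)
        counts = sims.mean(axis=0).reshape(2, 2)
        P = expm(rates_to_Q(rates, 2) * 0.04)
        for i in range(2):
            frac = counts[i] / counts[i].sum()
            n_i = counts[i].sum() * 50
            se = np.sqrt(P[i] * (1 - P[i]) / n_i)
            assert np.all(np.abs(frac - P[i]) < 3 * np.maximum(se, 1e-7))

    def test_finer_discretization_same_expected_summary(self):
        rates = np.array([3.0, 5.0])
        pi = np.array([0.6, 0.4])
        means = []
        for n_fine in (100, 200):
            cfg = BslConfig(M=50_000, n_fine=n_fine)
            sims = _simulate_summaries(rates, pi, cfg, np.random.default_rng(2), 400, 0.04)
            means.append(sims.mean(axis=0))
        # discretization error O(delta_t) is far below MC error here
        se = np.sqrt(2.0) * np.sqrt(np.maximum(means[0], 1.0)) / np.sqrt(400)
        assert np.all(np.abs(means[0] - means[1]) < 4 * se + 1.0)

    def test_stepwise_and_exact_agree_in_distribution(self):
        rates = matrix_log_rates(EPE1_T, 0.04)
        pi = hpdyn.stationary_distribution(EPE1_T)
        cfg = BslConfig(M=10_000)
        exact = _simulate_summaries(rates, pi, cfg, np.random.default_rng(3), 2000, 0.04, "exact")
        stepw = _simulate_summaries(rates, pi, cfg, np.random.default_rng(4), 2000, 0.04, "stepwise")
        for a, b in ((exact.mean(0), stepw.mean(0)), (exact.std(0), stepw.std(0))):
            assert np.all(np.abs(a - b) < 0.15 * np.maximum(a, 5.0))

    def test_rate_exceeding_fine_step_validity_rejected(self):
        cfg = BslConfig()
        with pytest.raises(ValueError, match="exit probability"):
            hpdyn.simulate_transition_summary(
                np.array([3000.0, 1.0]), np.array([0.5, 0.5]), cfg,
                np.random.default_rng(0),
            )


class TestSyntheticLikelihood:
    def test_same_seed_bit_identical(self):
        obs = ObservedTransitions(T_frame=EPE1_T)
        rates = matrix_log_rates(EPE1_T, 0.04)
        cfg = BslConfig(n_sim=200)
        v1 = synthetic_loglik(obs, rates, cfg, np.random.default_rng(5))
        v2 = synthetic_loglik(obs, rates, cfg, np.random.default_rng(5))
        assert v1 == v2

    def test_density_maximal_at_simulated_mean(self):
        from scipy.stats import multivariate_normal

        rng = np.random.default_rng(6)
        sims = _simulate_summaries(
            matrix_log_rates(EPE1_T, 0.04), hpdyn.stationary_distribution(EPE1_T),
            BslConfig(n_sim=500), rng, 500, 0.04,
        )
        mu, cov = sims.mean(0), np.cov(sims, rowvar=False) + 1e-6 * np.eye(4)
        at_mean = multivariate_normal.logpdf(mu, mu, cov)
        for row in sims[:50]:
            assert multivariate_normal.logpdf(row, mu, cov) <= at_mean + 1e-9

    def test_true_rates_beat_inflated_rates(self):
        obs = ObservedTransitions(T_frame=EPE1_T)
        truth = matrix_log_rates(EPE1_T, 0.04)
        cfg = BslConfig(n_sim=500)
        ll_true = synthetic_loglik(obs, truth, cfg, np.random.default_rng(7))
        ll_off = synthetic_loglik(obs, truth * 10, cfg, np.random.default_rng(7))
        assert ll_true > ll_off


class TestSampler:
    def test_single_state_is_noop(self):
        post = infer_rate_constants(ObservedTransitions(T_frame=[[1.0]]), BslConfig())
        assert post.pairs == [] and post.rates.size == 0

    def test_mcmc_targets_known_log_space_density(self):
        # detailed-balance check: with log-density log N(log k; mu, s^2) and
        # the Jeffreys-prior/Jacobian cancellation, the chain samples a
        # lognormal; compare the empirical log-rate moments to (mu, s)
        mu, s = np.log(0.3), 0.4
        rng = np.random.default_rng(8)
        cfg = BslConfig(scale_single=0.5, scale_global=0.5, scale_paired=0.25)
        cur = np.array([0.3, 0.3])

        def ll(r):
            return float(np.sum(-0.5 * ((np.log(r) - mu) / s) ** 2))

        ll_cur = ll(cur)
        kept = []
        for it in range(40_000):
            prop = propose_rates(cur, cfg, rng)
            ll_prop = ll(prop)
            if np.log(rng.random()) < ll_prop - ll_cur:
                cur, ll_cur = prop, ll_prop
            if it >= 5000 and it % 5 == 0:
                kept.append(np.log(cur[0]))
        kept = np.asarray(kept)
        n_eff = len(kept) / 50  # generous autocorrelation allowance
        assert abs(kept.mean() - mu) < 4 * s / np.sqrt(n_eff)
        assert abs(kept.std() - s) < 4 * s / np.sqrt(n_eff)

    def test_epe1_like_posterior_within_hdi_and_positive(self):
        obs = ObservedTransitions(T_frame=EPE1_T, dt_exp=0.04)
        cfg = BslConfig(n_sim=400, chain_length=4000, M=5000, seed=11)
        post = infer_rate_constants(obs, cfg)
        truth = matrix_log_rates(EPE1_T, 0.04)
        assert np.all(post.rates > 0)
        for n in range(2):
            lo, hi = post.hdi95[n]
            assert lo <= post.rates[n] <= hi
            assert lo <= truth[n] * 1.15 and hi >= truth[n] * 0.85

    def test_hdi_covers_truth_for_weakly_identified_system(self):
        # per-frame probability near 1e-3: only ~10 expected transition
        # events at M = 1e4, so the posterior is wide and skewed; the HDI
        # must still cover the matrix-log rate
        T = np.array([[0.9985, 0.0015], [0.05, 0.95]])
        obs = ObservedTransitions(T_frame=T, dt_exp=0.04)
        post = infer_rate_constants(obs, BslConfig(n_sim=400, chain_length=6000, seed=12))
        truth = matrix_log_rates(T, 0.04)
        lo, hi = post.hdi95[0]
        assert lo <= truth[0] <= hi

    def test_hdi_width_shrinks_with_more_molecules(self):
        obs = ObservedTransitions(T_frame=EPE1_T, dt_exp=0.04)
        widths = []
        for M in (1000, 16_000):
            cfg = BslConfig(n_sim=300, chain_length=4000, M=M, seed=13)
            post = infer_rate_constants(obs, cfg)
            widths.append(post.hdi95[0, 1] - post.hdi95[0, 0])
        assert widths[1] < widths[0]


def test_hdi_interval_is_shortest_covering_interval():
    x = np.concatenate([np.zeros(90), np.full(10, 100.0)])
    lo, hi = hdi_interval(x, prob=0.9)
    assert (lo, hi) == (0.0, 0.0)
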