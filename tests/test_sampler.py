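"""Metropolis-within-Gibbs machinery: steps, adaptation, indicator flips."""

import numpy as np
import pytest
from scipy import stats

import omrfdiff._kernels as K
from omrfdiff.model import GroupModel, OrdinalDataset, log_pseudolikelihood
from omrfdiff.priors import (BernoulliPrior, BetaBernoulliPrior, PriorConfig,
                             log_cauchy)
from omrfdiff.sampler import (SamplerConfig, adapt_proposal_sd,
                              run_estimation, run_selection,
                              rw_metropolis_step,
                              update_indicator_and_parameter)

from conftest import random_dataset, random_model


def empty_data(p=3, ncat=3):
    return OrdinalDataset(np.empty((0, p), dtype=int), [ncat] * p)


class TestRwMetropolisStep:
    def test_uphill_always_accepted(self, rng):
        # target increases with x, propose from a state with tiny sd so the
        # acceptance ratio >= 1 whenever the proposal goes uphill
        for _ in range(50):
            x = np.array([0.0])
            new, acc = rw_metropolis_step(x, lambda v: 100 * float(v), 0.1, rng)
            if float(new[0]) > 0:
                assert acc

    def test_standard_normal_target_moments(self):
        rng = np.random.default_rng(7)
        x = np.array([0.0])
        samples = np.empty(50_000)
        logt = lambda v: -0.5 * float(v) ** 2
        for t in range(samples.size):
            x, _ = rw_metropolis_step(x, logt, 2.4, rng)
            samples[t] = x[0]
        assert abs(samples.mean()) < 0.05
        assert abs(samples.var() - 1.0) < 0.1

    def test_fixed_downhill_acceptance_rate(self):
        # a move with log-target drop of log 2 is accepted ~half the time
        rng = np.random.default_rng(3)
        n_acc = 0
        trials = 20_000
        for _ in range(trials):
            if np.log(rng.random()) < -np.log(2):
                n_acc += 1
        freq = n_acc / trials
        se = np.sqrt(0.25 / trials)
        assert abs(freq - 0.5) < 4 * se

    def test_nonfinite_proposal_rejected(self, rng):
        def logt(v):
            return -np.inf if abs(float(v)) > 0 else 0.0

        x = np.array([0.0])
        new, acc = rw_metropolis_step(x, logt, 1.0, rng)
        assert not acc and new[0] == 0.0


class TestAdaptProposalSd:
    def test_fixed_point_at_target_rate(self):
        cfg = SamplerConfig(target_accept=0.44)
        sd = 1.0
        # accept/reject finely interleaved at the target rate
        for step in range(1, 2001):
            acc = (step * 44) // 100 > ((step - 1) * 44) // 100
            sd = adapt_proposal_sd(sd, acc, step, cfg)
        assert 0.5 < sd < 2.0  # drift stays bounded around the fixed point

    def test_clipped_to_bounds(self):
        cfg = SamplerConfig(proposal_sd_min=0.1, proposal_sd_max=2.0)
        sd = 1.0
        for step in range(1, 200):
            sd = adapt_proposal_sd(sd, True, step, cfg)
        assert sd <= 2.0
        for step in range(1, 200):
            sd = adapt_proposal_sd(sd, False, step, cfg)
        assert sd >= 0.1

    def test_terminal_acceptance_near_target(self):
        # adapting on a standard normal target lands in a sane window
        rng = np.random.default_rng(11)
        cfg = SamplerConfig()
        sd, x = 1.0, np.array([0.0])
        logt = lambda v: -0.5 * float(v) ** 2
        accepts = []
        for step in range(1, 5001):
            x, acc = rw_metropolis_step(x, logt, sd, rng)
            sd = adapt_proposal_sd(sd, acc, step, cfg)
            accepts.append(acc)
        assert 0.3 < np.mean(accepts[-2000:]) < 0.6


class TestColumnKernel:
    @pytest.mark.parametrize("seed", range(3))
    def test_col_ll_matches_reference(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng, p=3)
        data = random_dataset(rng, model, n=40)
        X = data.responses
        R = X.astype(float) @ model.interactions
        total = sum(
            K.col_ll(X, R, i, model.thresholds[i],
                     int(model.n_categories[i]) - 1)
            for i in range(3))
        assert total == pytest.approx(log_pseudolikelihood(model, data),
                                      rel=1e-10)


class TestUpdateIndicatorAndParameter:
    def test_prior_only_inclusion_rate(self):
        # with no data the pairwise flip must recover Bernoulli(0.5)
        rng = np.random.default_rng(5)
        log_pl = lambda d: 0.0
        gamma, delta = 0, np.zeros(1)
        inc = 0
        T = 40_000
        for _ in range(T):
            gamma, delta, _ = update_indicator_and_parameter(
                gamma, delta, log_pl, 1.0, 1.0, 0.0, rng)
            inc += gamma
        pip = inc / T
        assert abs(pip - 0.5) < 3 * np.sqrt(0.25 / T) * 4  # allow autocorr

    def test_excluded_parameter_is_exact_zero(self, rng):
        gamma, delta = 1, np.array([0.7])
        for _ in range(200):
            gamma, delta, _ = update_indicator_and_parameter(
                gamma, delta, lambda d: 0.0, 1.0, 1.0, 0.0, rng)
            if gamma == 0:
                assert np.all(delta == 0.0)


class TestRunSelection:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        model = random_model(rng, p=3, ncat=[3, 3, 3])
        d1 = random_dataset(rng, model, n=60)
        d2 = random_dataset(rng, model, n=60)
        cfg = SamplerConfig(main_iterations=300, burnin_iterations=100, seed=9)
        a = run_selection(d1, d2, PriorConfig(), cfg)
        b = run_selection(d1, d2, PriorConfig(), cfg)
        np.testing.assert_array_equal(a.interaction_diffs, b.interaction_diffs)
        np.testing.assert_array_equal(a.interaction_indicators,
                                      b.interaction_indicators)
        np.testing.assert_array_equal(a.overall_thresholds,
                                      b.overall_thresholds)

    def test_zero_consistency_every_draw(self):
        rng = np.random.default_rng(2)
        model = random_model(rng, p=3, ncat=[2, 3, 2])
        d1 = random_dataset(rng, model, n=80)
        d2 = random_dataset(rng, model, n=80)
        cfg = SamplerConfig(main_iterations=800, burnin_iterations=400, seed=4)
        draws = run_selection(d1, d2, PriorConfig(), cfg)
        excl = draws.interaction_diffs[draws.interaction_indicators == 0]
        assert excl.size > 0
        assert np.all(excl == 0.0)
        var_of = np.array([i for i, _ in draws.threshold_index])
        ind = draws.threshold_indicators[:, var_of]
        exclt = draws.threshold_diffs[ind == 0]
        assert np.all(exclt == 0.0)

    def test_prior_only_bernoulli_marginals(self):
        cfg = SamplerConfig(main_iterations=6000, burnin_iterations=500,
                            seed=12)
        draws = run_selection(empty_data(), empty_data(), PriorConfig(), cfg)
        assert np.all(np.abs(draws.interaction_pips() - 0.5) < 0.05)
        assert np.all(np.abs(draws.threshold_pips() - 0.5) < 0.05)

    def test_prior_only_slab_is_cauchy(self):
        cfg = SamplerConfig(main_iterations=30_000, burnin_iterations=500,
                            seed=21)
        draws = run_selection(empty_data(p=2), empty_data(p=2),
                              PriorConfig(), cfg)
        inc = draws.interaction_diffs[draws.interaction_indicators == 1]
        thin = inc[::20]
        res = stats.kstest(thin, stats.cauchy(scale=1.0).cdf)
        assert res.pvalue > 0.01

    def test_free_mode_disables_threshold_testing(self):
        rng = np.random.default_rng(3)
        model = random_model(rng, p=3, ncat=[3, 3, 3])
        d1 = random_dataset(rng, model, n=50)
        d2 = random_dataset(rng, model, n=50)
        cfg = SamplerConfig(main_iterations=200, burnin_iterations=100, seed=0)
        draws = run_selection(d1, d2, PriorConfig(), cfg,
                              alignment_mode="Free")
        assert draws.threshold_indicators is None
        assert draws.group1_thresholds is not None
        assert draws.interaction_indicators is not None


class TestRunEstimation:
    def test_deterministic_and_records_all(self):
        rng = np.random.default_rng(8)
        model = random_model(rng, p=3, ncat=[3, 2, 3])
        d1 = random_dataset(rng, model, n=50)
        d2 = random_dataset(rng, model, n=40)
        cfg = SamplerConfig(main_iterations=250, burnin_iterations=100, seed=1)
        a = run_estimation(d1, d2, PriorConfig(), cfg)
        b = run_estimation(d1, d2, PriorConfig(), cfg)
        assert a.n_draws == 250
        assert a.interaction_indicators is None
        np.testing.assert_array_equal(a.overall_interactions,
                                      b.overall_interactions)

    def test_null_data_diffs_near_zero(self):
        # identical groups generated under no difference: the posterior for
        # every difference parameter should cover zero
        rng = np.random.default_rng(13)
        model = random_model(rng, p=3, ncat=[2, 2, 2])
        X = np.stack([rng.integers(0, 2, 600) for _ in range(3)], axis=1)
        d1 = OrdinalDataset(X[:300], [2, 2, 2])
        d2 = OrdinalDataset(X[300:], [2, 2, 2])
        cfg = SamplerConfig(main_iterations=2500, burnin_iterations=1000,
                            seed=6)
        draws = run_estimation(d1, d2, PriorConfig(), cfg)
        z = draws.interaction_diffs.mean(0) / draws.interaction_diffs.std(0)
        assert np.all(np.abs(z) < 3)
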