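"""Truth generation, OMRF sampling, marginal safeguard, harness plumbing."""

import numpy as np
import pytest

from omrfdiff.model import GroupModel, OrdinalDataset, enumerate_joint_pmf
from omrfdiff.priors import PriorConfig
from omrfdiff.sampler import SamplerConfig
from omrfdiff.simulate import (TruthConfig, apply_marginal_safeguard,
                               generate_truth, recenter_thresholds,
                               run_simulation_cell, sample_dataset)
from omrfdiff.two_group import derive_group_model

from conftest import random_model


class TestSampleDataset:
    def test_null_model_uniform_frequencies(self, rng):
        m = GroupModel(thresholds=[[0.0, 0.0]] * 2,
                       interactions=np.zeros((2, 2)))
        d = sample_dataset(m, 10_000, rng=rng)
        se = np.sqrt((1 / 3) * (2 / 3) / 10_000)
        for i in range(2):
            freqs = np.bincount(d.responses[:, i], minlength=3) / 10_000
            assert np.all(np.abs(freqs - 1 / 3) < 3.5 * se)

    def test_exact_matches_enumeration(self, rng):
        m = random_model(rng, p=3, ncat=[2, 2, 2])
        d = sample_dataset(m, 50_000, rng=rng)
        table = enumerate_joint_pmf(m)
        emp = np.zeros(len(table.states))
        codes = d.responses @ np.array([4, 2, 1])
        tcodes = table.states @ np.array([4, 2, 1])
        for k, c in enumerate(tcodes):
            emp[k] = np.mean(codes == c)
        tv = 0.5 * np.abs(emp - table.probabilities).sum()
        assert tv < 0.02

    def test_gibbs_agrees_with_exact_moments(self, rng):
        m = random_model(rng, p=3, ncat=[2, 2, 2])
        de = sample_dataset(m, 8000, method="exact", rng=rng)
        dg = sample_dataset(m, 8000, method="gibbs", rng=rng,
                            gibbs_sweeps=200)
        for i in range(3):
            for j in range(i + 1, 3):
                me = np.mean(de.responses[:, i] * de.responses[:, j])
                mg = np.mean(dg.responses[:, i] * dg.responses[:, j])
                se = np.sqrt(2 * 0.25 / 8000)
                assert abs(me - mg) < 4 * se

    def test_respects_category_bounds(self, rng):
        m = random_model(rng, p=3, ncat=[4, 2, 3])
        d = sample_dataset(m, 500, method="gibbs", rng=rng, gibbs_sweeps=50)
        assert d.responses.min() >= 0
        assert np.all(d.responses.max(axis=0) < d.n_categories)

    def test_guard_violation_suggests_gibbs(self, rng):
        p = 12
        m = GroupModel(thresholds=[[0.0, 0.0, 0.0]] * p,
                       interactions=np.zeros((p, p)))
        with pytest.raises(Exception, match="gibbs"):
            sample_dataset(m, 10, method="exact", rng=rng)


class TestGenerateTruth:
    def test_full_density_all_nonzero(self, rng):
        cfg = TruthConfig(p=5, n_categories=3, density=1.0, prop_diff=0.0)
        t = generate_truth(cfg, rng)
        iu = np.triu_indices(5, 1)
        assert np.all(t.overall.interactions[iu] != 0)

    def test_zero_prop_diff_identical_groups(self, rng):
        cfg = TruthConfig(p=4, n_categories=3, density=0.5, prop_diff=0.0)
        t = generate_truth(cfg, rng)
        assert np.all(t.diffs.interaction_diffs == 0)
        g1, g2 = derive_group_model(t, 1), derive_group_model(t, 2)
        np.testing.assert_array_equal(g1.interactions, g2.interactions)

    def test_retention_rate(self, rng):
        cfg = TruthConfig(p=10, n_categories=2, density=0.15, prop_diff=0.0,
                          recenter=False)
        retained = []
        for _ in range(300):
            t = generate_truth(cfg, rng)
            iu = np.triu_indices(10, 1)
            retained.append(np.mean(t.overall.interactions[iu] != 0))
        rate = np.mean(retained)
        se = np.sqrt(0.15 * 0.85 / (300 * 45))
        assert abs(rate - 0.15) < 3.5 * se

    def test_difference_count_and_magnitudes(self, rng):
        cfg = TruthConfig(p=6, n_categories=2, density=1.0, prop_diff=0.4,
                          diff_low=0.2, diff_high=0.6)
        t = generate_truth(cfg, rng)
        iu = np.triu_indices(6, 1)
        d = t.diffs.interaction_diffs[iu]
        nz = d[d != 0]
        assert nz.size == round(0.4 * 15)
        assert np.all((np.abs(nz) >= 0.2) & (np.abs(nz) <= 0.6))

    def test_sign_balance(self, rng):
        cfg = TruthConfig(p=6, n_categories=2, density=1.0, prop_diff=1.0)
        signs = []
        for _ in range(200):
            t = generate_truth(cfg, rng)
            iu = np.triu_indices(6, 1)
            signs.extend(np.sign(t.diffs.interaction_diffs[iu]))
        pos = np.mean(np.array(signs) > 0)
        se = np.sqrt(0.25 / len(signs))
        assert abs(pos - 0.5) < 3.5 * se

    def test_threshold_diffs_are_zero(self, rng):
        cfg = TruthConfig(p=4, n_categories=4, density=1.0, prop_diff=0.5)
        t = generate_truth(cfg, rng)
        for d in t.diffs.threshold_diffs:
            assert np.all(d == 0)


class TestRecenterThresholds:
    def test_marginals_match_target(self, rng):
        dense = random_model(rng, p=3, ncat=[3, 3, 3])
        targets = [enumerate_joint_pmf(dense).marginal(i) for i in range(3)]
        sparse = GroupModel(thresholds=[t.copy() for t in dense.thresholds],
                            interactions=np.zeros((3, 3)))
        fixed = recenter_thresholds(sparse, targets, tol=0.005)
        table = enumerate_joint_pmf(fixed)
        for i in range(3):
            assert np.abs(table.marginal(i) - targets[i]).max() < 0.05


class TestMarginalSafeguard:
    def _gen(self, thresholds):
        def gen(rng):
            m = GroupModel(thresholds=thresholds,
                           interactions=np.zeros((2, 2)))
            cfgm = TruthConfig(p=2, n_categories=2)
            from omrfdiff.two_group import DifferenceModel, TwoGroupModel
            truth = TwoGroupModel(m, DifferenceModel(
                threshold_diffs=[np.zeros(1)] * 2,
                interaction_diffs=np.zeros((2, 2))))
            d = sample_dataset(m, 100, rng=rng)
            d2 = sample_dataset(m, 100, rng=rng)
            return truth, d, d2
        return gen

    def test_benign_data_unchanged(self, rng):
        cfg = TruthConfig(p=2, n_categories=2, min_second_category_count=10)
        truth, d1, d2, k = apply_marginal_safeguard(
            self._gen([[0.0], [0.0]]), cfg, rng)
        assert k == 0

    def test_degenerate_variable_triggers_resample(self, rng):
        # extreme threshold forces a near-constant variable
        cfg = TruthConfig(p=2, n_categories=2, min_second_category_count=10)
        with pytest.raises(RuntimeError):
            apply_marginal_safeguard(self._gen([[-12.0], [0.0]]), cfg, rng,
                                     max_resamples=5)

    def test_mean_resample_count_low_under_defaults(self, rng):
        cfg = TruthConfig(p=4, n_categories=3, density=0.3, prop_diff=0.2,
                          recenter=False)

        def gen(r):
            truth = generate_truth(cfg, r)
            d1 = sample_dataset(derive_group_model(truth, 1), 300, rng=r)
            d2 = sample_dataset(derive_group_model(truth, 2), 300, rng=r)
            return truth, d1, d2

        counts = [apply_marginal_safeguard(gen, cfg, rng)[3]
                  for _ in range(60)]
        assert np.mean(counts) < 1


class TestRunSimulationCell:
    def test_bookkeeping_and_determinism(self):
        cfg = TruthConfig(p=4, n_categories=2, density=1.0, prop_diff=0.5)
        scfg = SamplerConfig(main_iterations=150, burnin_iterations=100)
        t1 = run_simulation_cell(cfg, 80, PriorConfig(), scfg,
                                 replicates=2, seed=3)
        t2 = run_simulation_cell(cfg, 80, PriorConfig(), scfg,
                                 replicates=2, seed=3)
        assert len(t1) == 2 * 6
        assert t1.equals(t2)
        assert set(t1.columns) == {"replicate", "var_i", "var_j",
                                   "true_delta", "true_diff", "pip"}

    def test_separation_between_true_and_null_edges(self):
        cfg = TruthConfig(p=4, n_categories=2, density=1.0, prop_diff=0.5,
                          diff_low=0.5, diff_high=0.9)
        scfg = SamplerConfig(main_iterations=1200, burnin_iterations=800)
        tab = run_simulation_cell(cfg, 600, PriorConfig(), scfg,
                                  replicates=4, seed=17)
        mean_true = tab.loc[tab.true_diff == 1, "pip"].mean()
        mean_null = tab.loc[tab.true_diff == 0, "pip"].mean()
        assert mean_true > mean_null
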