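import numpy as np
import pytest
from scipy import stats

from otusynth.copula import fit_copula, sample_synthetic
from otusynth.fixtures import degrade_to_noise
from otusynth.io import OtuTable
from otusynth.qc import (
    ColumnStats,
    RetentionRule,
    SvcParams,
    adversarial_report,
    column_similarity,
    ks_battery,
    retain_hard_synthetic,
    screen_features_chi2,
    tune_polynomial_svc,
)


def _brute_chi2(X, y):
    """Per-feature chi-squared statistic from the 2 x classes totals table."""
    out = []
    classes = np.unique(y)
    for j in range(X.shape[1]):
        observed = np.array([X[y == c, j].sum() for c in classes])
        class_totals = np.array([(y == c).sum() for c in classes])
        expected = X[:, j].sum() * class_totals / len(y)
        out.append(np.sum((observed - expected) ** 2 / expected))
    return np.array(out)


class TestChi2Screen:
    def test_saturating_k_returns_all(self):
        X = np.abs(np.random.default_rng(0).normal(size=(10, 4)))
        y = np.array([0] * 5 + [1] * 5)
        np.testing.assert_array_equal(screen_features_chi2(X, y, 10), np.arange(4))

    def test_matches_brute_force_ranking(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(5.0, size=(40, 12)).astype(float)
        y = np.array([0] * 20 + [1] * 20)
        X[y == 1, 7] += 30  # one clearly class-linked feature
        sel = screen_features_chi2(X, y, 1)
        assert sel.tolist() == [int(np.argmax(_brute_chi2(X, y)))] == [7]
        top4 = screen_features_chi2(X, y, 4)
        brute4 = np.sort(np.argsort(_brute_chi2(X, y))[::-1][:4])
        np.testing.assert_array_equal(top4, brute4)

    def test_default_k_on_wide_table_selects_500(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(2.0, size=(30, 620)).astype(float)
        y = np.array([0] * 15 + [1] * 15)
        assert len(screen_features_chi2(X, y, 500)) == 500

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            screen_features_chi2(np.array([[-1.0, 2.0]]), [0], 1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two label classes"):
            screen_features_chi2(np.ones((4, 2)), [1, 1, 1, 1], 1)


class TestSvcTuning:
    def test_single_trial_returns_sampled_pair_in_range(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = np.array([0, 1] * 10)
        params, score = tune_polynomial_svc(X, y, n_trials=1, seed=4)
        assert 0.01 <= params.C <= 1000
        assert 0.0001 <= params.gamma <= 100
        assert 0 <= score <= 1

    def test_best_beats_every_trial_on_separable_toy(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(-3, 1, (15, 2)), rng.normal(3, 1, (15, 2))])
        y = np.array([0] * 15 + [1] * 15)
        _, best = tune_polynomial_svc(X, y, n_trials=10, seed=0)
        _, single = tune_polynomial_svc(X, y, n_trials=1, seed=0)
        assert best >= single  # trial 1 is part of the same seeded stream

    def test_params_outside_box_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SvcParams(C=5000, gamma=1)


class TestAdversarial:
    def test_identical_data_near_chance(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(4.0, size=(60, 30)).astype(float)
        # a random half labelled "synthetic": indistinguishable by design
        rep = adversarial_report(X[:30], X[30:], seed=0)
        assert abs(rep.best_accuracy - 0.5) <= 0.15
        assert rep.passed

    def test_shifted_noise_is_flagged(self, crc_biopsy_group):
        accs = []
        for seed in range(5):
            table, _ = crc_biopsy_group
            bad = degrade_to_noise(table, seed=seed)
            shifted = bad.counts + 10 * table.counts.std(axis=0)
            rep = adversarial_report(table.counts, shifted, seed=seed)
            accs.append(rep.best_accuracy)
        assert np.mean(accs) >= 0.9

    def test_metrics_bounded(self, crc_biopsy_group):
        table, _ = crc_biopsy_group
        model = fit_copula(table)
        batch = sample_synthetic(model, table.n_samples, seed=0)
        rep = adversarial_report(table, batch.table, seed=0)
        for metrics in rep.per_classifier.values():
            for v in metrics.values():
                assert 0 <= v <= 1

    def test_noise_monotone_in_magnitude(self, crc_biopsy_group):
        """More added noise never decreases mean adversarial accuracy."""
        table, _ = crc_biopsy_group
        model = fit_copula(table)
        levels = [0.0, 3.0, 10.0]
        means = []
        for level in levels:
            accs = []
            for seed in range(3):
                batch = sample_synthetic(model, table.n_samples, seed=seed)
                shifted = batch.table.counts + level * table.counts.std(axis=0)
                accs.append(adversarial_report(table.counts, shifted, seed=seed).best_accuracy)
            means.append(np.mean(accs))
        assert means[0] <= means[1] + 0.05 and means[1] <= means[2] + 0.05


class TestKsBattery:
    def test_identical_tables_no_rejections(self, crc_biopsy_group):
        table, _ = crc_biopsy_group
        res = ks_battery(table, table)
        assert all(r.statistic == 0 and r.p_adjusted == 1 and not r.reject for r in res)

    def test_disjoint_supports_statistic_one(self):
        real = OtuTable(["r1", "r2", "r3"], ["a"], np.array([[1.0], [2.0], [3.0]]))
        synth = OtuTable(["s1", "s2", "s3"], ["a"], np.array([[10.0], [11.0], [12.0]]))
        res = ks_battery(real, synth)
        assert res[0].statistic == 1.0

    def test_statistic_matches_brute_force_ecdf(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            r = rng.integers(0, 6, size=10).astype(float)
            s = rng.integers(0, 6, size=10).astype(float)
            real = OtuTable([f"r{i}" for i in range(10)], ["f"], r[:, None])
            synth = OtuTable([f"s{i}" for i in range(10)], ["f"], s[:, None])
            stat = ks_battery(real, synth)[0].statistic
            pooled = np.unique(np.concatenate([r, s]))
            brute = max(
                abs((r <= t).mean() - (s <= t).mean()) for t in pooled
            )
            assert stat == pytest.approx(brute, abs=1e-12)

    def test_bonferroni_definition_and_monotonicity(self):
        rng = np.random.default_rng(0)
        n = 12
        for p_feats in (5, 20):
            X = rng.poisson(3.0, size=(2 * n, p_feats)).astype(float)
            real = OtuTable([f"r{i}" for i in range(n)], [f"f{j}" for j in range(p_feats)], X[:n])
            synth = OtuTable([f"s{i}" for i in range(n)], [f"f{j}" for j in range(p_feats)], X[n:])
            res = ks_battery(real, synth)
            for r in res:
                assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * p_feats))
                assert r.reject == (r.p_adjusted < 0.05)

    def test_mismatched_features_rejected(self, crc_biopsy_group):
        table, _ = crc_biopsy_group
        other = OtuTable(table.sample_ids, [f + "_x" for f in table.feature_ids], table.counts)
        with pytest.raises(ValueError, match="feature axes"):
            ks_battery(table, other)


class TestColumnSimilarity:
    def test_identity_stats(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(5.0, size=(20, 6)).astype(float)
        cs = column_similarity(X, X)
        assert cs.mean_difference == 0 and cs.std_difference == 0 and cs.mse == 0
        assert cs.spearman_correlation == pytest.approx(1.0)

    def test_constant_shift(self):
        rng = np.random.default_rng(1)
        X = rng.normal(10, 2, size=(25, 4))
        cs = column_similarity(X, X + 3.5)
        assert cs.mean_difference == pytest.approx(3.5)
        assert cs.std_difference == pytest.approx(0.0, abs=1e-9)

    def test_reversed_pairing_spearman_minus_one(self):
        x = np.arange(1.0, 13.0)[:, None]
        cs = column_similarity(x, x[::-1])
        assert cs.spearman_correlation == pytest.approx(-1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            column_similarity(np.ones((3, 2)), np.ones((4, 2)))


class TestRetention:
    def test_confident_scores_drop_everything(self):
        scores = np.full(10, 0.99)
        idx, _ = retain_hard_synthetic(np.zeros((10, 2)), scores, RetentionRule(0.2))
        assert len(idx) == 0

    def test_maximal_difficulty_keeps_everything(self):
        scores = np.full(10, 0.5)
        idx, _ = retain_hard_synthetic(np.zeros((10, 2)), scores, RetentionRule(0.2))
        assert len(idx) == 10

    def test_matches_brute_force_set_logic(self):
        rng = np.random.default_rng(5)
        scores = rng.random(20)
        rule = RetentionRule(margin_threshold=0.1, include_misclassified=True)
        idx, _ = retain_hard_synthetic(np.zeros((20, 3)), scores, rule)
        brute = {
            i for i, s in enumerate(scores) if s < 0.5 or abs(s - 0.5) < 0.1
        }
        assert set(idx.tolist()) == brute

    def test_score_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="scores"):
            retain_hard_synthetic(np.zeros((5, 2)), [0.5, 0.5])
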