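"""Evaluation metrics: MAE/MSE, Frechet distance in embedding space,
confusion diagnostics, AUROC against a brute-force pairwise oracle, and the
blinded-set exporter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgrecon.metrics import (
    ConfusionCounts,
    FeatureStats,
    RandomProjectionEmbedder,
    auroc,
    confusion_metrics,
    export_blinded_set,
    feature_stats,
    fid,
    lead_report,
    mae,
    mean_per_lead_embedder,
    mse,
    youden_threshold,
)


class TestPointwiseErrors:
    def test_zero_for_equal_inputs(self):
        x = np.random.default_rng(0).standard_normal((100, 12))
        assert mae(x, x) == 0.0 and mse(x, x) == 0.0

    @pytest.mark.parametrize("r,g,expected_mae,expected_mse", [
        ([0.0, 1.0], [1.0, 1.0], 0.5, 0.5),
        ([0.0, 2.0], [0.0, 0.0], 1.0, 2.0),
    ])
    def test_hand_examples(self, r, g, expected_mae, expected_mse):
        assert mae(np.array(r), np.array(g)) == expected_mae
        assert mse(np.array(r), np.array(g)) == expected_mse

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_jensen_mse_at_least_mae_squared(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.standard_normal((20, 3))
        g = rng.standard_normal((20, 3))
        assert mse(r, g) >= mae(r, g) ** 2 - 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae(np.zeros(3), np.zeros(4))


class TestFeatureStats:
    def test_identical_signals_zero_covariance(self):
        sig = np.ones((12, 10))
        stats = feature_stats([sig] * 5, mean_per_lead_embedder)
        np.testing.assert_array_equal(stats.cov, 0.0)

    def test_analytic_mean_for_known_constants(self):
        sigs = [np.full((12, 4), c) for c in (0.0, 2.0)]
        stats = feature_stats(sigs, mean_per_lead_embedder)
        np.testing.assert_allclose(stats.mean, 1.0)
        np.testing.assert_allclose(np.diag(stats.cov), 2.0)  # unbiased var

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        sigs = [rng.standard_normal((12, 8)) for _ in range(6)]
        a = feature_stats(sigs, mean_per_lead_embedder)
        b = feature_stats(list(reversed(sigs)), mean_per_lead_embedder)
        np.testing.assert_allclose(a.mean, b.mean)
        np.testing.assert_allclose(a.cov, b.cov, atol=1e-12)

    def test_single_signal_rejected(self):
        with pytest.raises(ValueError):
            feature_stats([np.zeros((12, 4))], mean_per_lead_embedder)


class TestFid:
    def test_identical_stats_give_zero(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((5, 5))
        stats = FeatureStats(mean=rng.standard_normal(5), cov=A @ A.T, n=10)
        assert fid(stats, stats) < 1e-8

    def test_one_dimensional_closed_form(self):
        a = FeatureStats(mean=np.array([0.0]), cov=np.array([[1.0]]), n=10)
        b = FeatureStats(mean=np.array([1.0]), cov=np.array([[1.0]]), n=10)
        assert fid(a, b) == pytest.approx(1.0)

    def test_diagonal_gaussian_samples_match_analytic(self):
        rng = np.random.default_rng(1)
        mu_a, mu_b = np.array([0.0, 1.0]), np.array([2.0, -1.0])
        sd_a, sd_b = np.array([1.0, 0.5]), np.array([1.5, 1.0])
        xa = mu_a + sd_a * rng.standard_normal((10 ** 5, 2))
        xb = mu_b + sd_b * rng.standard_normal((10 ** 5, 2))
        sa = FeatureStats(np.mean(xa, 0), np.cov(xa, rowvar=False), len(xa))
        sb = FeatureStats(np.mean(xb, 0), np.cov(xb, rowvar=False), len(xb))
        analytic = (np.sum((mu_a - mu_b) ** 2)
                    + np.sum(sd_a ** 2 + sd_b ** 2 - 2 * sd_a * sd_b))
        assert abs(fid(sa, sb) - analytic) / analytic < 0.02

    def test_self_distance_zero_over_random_psd_trials(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            A = rng.standard_normal((4, 4))
            stats = FeatureStats(mean=rng.standard_normal(4),
                                 cov=A @ A.T + 1e-6 * np.eye(4), n=10)
            assert fid(stats, stats) < 1e-8

    def test_symmetric_for_commuting_covariances(self):
        a = FeatureStats(np.zeros(3), np.diag([1.0, 2.0, 3.0]), 10)
        b = FeatureStats(np.ones(3), np.diag([2.0, 1.0, 0.5]), 10)
        assert fid(a, b) == pytest.approx(fid(b, a), rel=1e-10)

    def test_dimension_mismatch_rejected(self):
        a = FeatureStats(np.zeros(2), np.eye(2), 5)
        b = FeatureStats(np.zeros(3), np.eye(3), 5)
        with pytest.raises(ValueError):
            fid(a, b)


class TestLeadReport:
    def test_perfect_reconstruction_all_zeros(self, clean_records, mask3):
        report = lead_report(clean_records, clean_records, mask3,
                             RandomProjectionEmbedder(seed=0))
        assert report.overall_mse == 0.0 and report.overall_mae == 0.0
        assert report.fid_value < 1e-8
        assert (report.rows["mse"] == 0.0).all()

    def test_nine_rows_for_three_retained_leads(self, clean_records, mask3):
        report = lead_report(clean_records, clean_records, mask3,
                             RandomProjectionEmbedder(seed=0))
        assert len(report.rows) == 9
        assert "II" not in set(report.rows["lead_name"])

    def test_overall_is_pooled_per_element_aggregate(self, clean_records,
                                                     noisy_records, mask3):
        from ecgrecon.preprocess import impute_nans
        recon = [impute_nans(r) for r in noisy_records[:6]]
        report = lead_report(clean_records, recon, mask3,
                             RandomProjectionEmbedder(seed=0))
        pooled_r = np.concatenate([r.signal for r in clean_records], axis=1)
        pooled_g = np.concatenate([r.signal for r in recon], axis=1)
        idx = mask3.dropped_indices
        expected = np.mean((pooled_r[idx] - pooled_g[idx]) ** 2)
        assert report.overall_mse == pytest.approx(expected, abs=1e-12)

    def test_all_leads_mode_gives_twelve_rows(self, clean_records, mask3):
        report = lead_report(clean_records, clean_records, mask3,
                             RandomProjectionEmbedder(seed=0), leads="all")
        assert len(report.rows) == 12


class TestConfusionMetrics:
    def test_reported_counts_reproduce_printed_percentages(self):
        m = confusion_metrics(ConfusionCounts(tp=26, tn=13, fp=16, fn=0))
        assert round(m["accuracy"] * 100, 1) == 70.9
        assert round(m["sensitivity"] * 100, 1) == 100.0
        assert round(m["specificity"] * 100, 1) == 44.8
        assert round(m["precision"] * 100, 1) == 61.9
        assert round(m["f1"] * 100, 1) == 76.5

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(1, 1, 0, 0))
        assert all(v == 1.0 for v in m.values())

    def test_degenerate_cases(self):
        m = confusion_metrics(ConfusionCounts(tp=0, tn=1, fp=0, fn=1))
        assert m["sensitivity"] == 0.0 and m["specificity"] == 1.0
        assert np.isnan(m["precision"])  # tp + fp == 0: undefined, not faked

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(0, 0, 0, 0))


def _auroc_bruteforce(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1])) == 1.0

    def test_all_ties_give_half(self):
        assert auroc(np.ones(10), np.r_[np.ones(5), np.zeros(5)]) == 0.5

    def test_exact_agreement_with_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            labels = rng.integers(0, 2, size=20)
            if labels.sum() in (0, 20):
                labels[0] = 1 - labels[0]
            scores = np.round(rng.standard_normal(20), 1)  # force ties
            assert auroc(scores, labels) == pytest.approx(
                _auroc_bruteforce(scores, labels), abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=30)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        scores = rng.standard_normal(30)
        base = auroc(scores, labels)
        assert auroc(3 * scores + 2, labels) == pytest.approx(base)
        assert auroc(np.exp(scores), labels) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc(np.arange(4.0), np.ones(4))


def test_youden_threshold_on_separable_scores():
    scores = np.array([0.1, 0.2, 0.8, 0.9])
    labels = np.array([0, 0, 1, 1])
    thr, sens, spec = youden_threshold(scores, labels)
    assert sens == 1.0 and spec == 1.0
    assert 0.2 < thr <= 0.8


class TestBlindedExport:
    def test_balanced_set_of_fifty(self, clean_records, noisy_records):
        real = (clean_records * 5)[:25]
        gen = (noisy_records * 3)[:25]
        exported, key = export_blinded_set(real, gen, 25, seed=7)
        assert len(exported) == 50
        assert (key["origin"] == "real").sum() == 25

    def test_key_joins_back_without_mismatch(self, noisy_records):
        real, gen = noisy_records[:6], noisy_records[6:]
        exported, key = export_blinded_set(real, gen, 3, seed=1)
        by_anon = {r.record_id: r for r in exported}
        originals = {r.record_id: r for r in real + gen}
        for row in key.itertuples():
            np.testing.assert_array_equal(
                by_anon[row.anon_id].signal,
                originals[row.source_record_id].signal)

    def test_same_seed_same_order(self, clean_records, noisy_records):
        a, _ = export_blinded_set(clean_records, noisy_records[:6], 3, seed=9)
        b, _ = export_blinded_set(clean_records, noisy_records[:6], 3, seed=9)
        assert [pd.util.hash_array(r.signal.ravel()).sum() for r in a] == \
               [pd.util.hash_array(r.signal.ravel()).sum() for r in b]

    def test_insufficient_records_rejected(self, clean_records):
        with pytest.raises(ValueError):
            export_blinded_set(clean_records, clean_records, 100, seed=0)
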