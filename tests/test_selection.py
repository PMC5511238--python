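"""Feature selection, the SVM cross-validation loops and the metric panel."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlradiomics import (
    confusion_metrics,
    fscore_rank,
    loocv_predict,
    roc_auc,
    select_top,
    time_split_predict,
    ttest_filter,
)


def brute_force_auc(scores, labels):
    """Pairwise concordance with half-credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestTtestFilter:
    def test_identical_feature_not_kept(self):
        y = np.array([0, 0, 1, 1])
        X = np.column_stack([[1.0, 1, 1, 1], [0.1, 0.2, 5.1, 5.2]])
        with pytest.warns(UserWarning):
            kept, p = ttest_filter(X, y, alpha=0.05)
        assert 0 not in kept
        assert np.isnan(p[0])

    def test_separating_feature_kept(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 10)
        X = (y + rng.normal(0, 0.01, 20))[:, None]
        kept, p = ttest_filter(X, y, alpha=0.05)
        assert kept.tolist() == [0]
        assert p[0] < 1e-10

    def test_alpha_one_keeps_all_defined_features(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 5)
        X = rng.normal(size=(10, 8))
        kept, _ = ttest_filter(X, y, alpha=1.0)
        assert kept.tolist() == list(range(8))

    def test_nesting_in_alpha(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 15)
        X = rng.normal(size=(30, 50)) + y[:, None] * rng.uniform(0, 1, 50)
        kept_small, _ = ttest_filter(X, y, alpha=0.01)
        kept_big, _ = ttest_filter(X, y, alpha=0.2)
        assert set(kept_small) <= set(kept_big)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ttest_filter(np.zeros((4, 2)), np.zeros(4, dtype=int))


class TestFscore:
    def test_hand_computed_example(self):
        # x+ = {1,2,3}, x- = {7,8,9}: grand mean 5 -> numerator 18, denom 2
        X = np.array([1.0, 2, 3, 7, 8, 9])[:, None]
        y = np.array([1, 1, 1, 0, 0, 0])
        assert fscore_rank(X, y)[0] == pytest.approx(9.0)

    def test_equal_class_means_score_zero(self):
        X = np.array([1.0, -1, 2, -2])[:, None]
        y = np.array([0, 0, 1, 1])
        assert fscore_rank(X, y)[0] == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 8)
        X = rng.normal(size=(16, 4)) + y[:, None]
        np.testing.assert_allclose(fscore_rank(X * 37.5, y), fscore_rank(X, y))


class TestSelectTop:
    def test_largest_scores_selected(self):
        assert select_top(np.array([3.0, 1, 2]), 2).tolist() == [0, 2]

    def test_tie_breaks_to_lower_index(self):
        assert select_top(np.array([2.0, 2, 1]), 1).tolist() == [0]

    def test_m_capped_with_warning(self):
        with pytest.warns(UserWarning):
            idx = select_top(np.array([1.0, 2.0]), 5)
        assert idx.tolist() == [0, 1]


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0]))
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _ = roc_auc(np.ones(6), np.array([0, 1, 0, 1, 0, 1]))
        assert auc == 0.5

    def test_enumerated_example(self):
        auc, _ = roc_auc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
        assert auc == pytest.approx(0.75)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(4, 20))
            y = np.r_[0, 1, rng.integers(0, 2, n - 2)]
            s = np.round(rng.normal(size=n), 1)  # rounding forces ties
            auc, _ = roc_auc(s, y)
            assert auc == pytest.approx(brute_force_auc(s, y), abs=1e-12)

    def test_negation_complements_auc(self):
        rng = np.random.default_rng(5)
        y = np.r_[0, 1, rng.integers(0, 2, 10)]
        s = rng.normal(size=12)  # continuous, no ties
        assert roc_auc(s, y)[0] + roc_auc(-s, y)[0] == pytest.approx(1.0)

    def test_curve_endpoints(self):
        _, pts = roc_auc(np.array([0.2, 0.7, 0.5]), np.array([0, 1, 1]))
        assert pts[0].tolist() == [0.0, 0.0]
        assert pts[-1].tolist() == [1.0, 1.0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        y = np.repeat([1, 0], 5)
        assert confusion_metrics(y, y) == (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def test_hand_computed_table(self):
        # TP=3, FP=1, TN=4, FN=2
        pred = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        true = np.array([1, 1, 1, 0, 1, 1, 0, 0, 0, 0])
        acc, sens, spec, ppv, npv, mcc = confusion_metrics(pred, true)
        assert acc == pytest.approx(0.7)
        assert sens == pytest.approx(0.6)
        assert spec == pytest.approx(0.8)
        assert ppv == pytest.approx(0.75)
        assert npv == pytest.approx(2 / 3)
        assert mcc == pytest.approx(10 / np.sqrt(600))

    def test_inverted_prediction_gives_negative_one(self):
        y = np.repeat([1, 0], 4)
        assert confusion_metrics(1 - y, y)[-1] == -1.0

    def test_degenerate_prediction_warns(self):
        with pytest.warns(UserWarning):
            out = confusion_metrics(np.zeros(4, dtype=int), np.array([0, 0, 1, 1]))
        assert out[3] == 0.0  # PPV undefined -> 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.zeros(3, dtype=int), np.zeros(4, dtype=int))


class TestLoocv:
    def test_perfect_feature(self):
        rng = np.random.default_rng(6)
        y = np.repeat([0, 1], 10)
        X = np.column_stack([y.astype(float), rng.normal(size=20)])
        rep = loocv_predict(X, y, alpha=0.05, m=1, svm_c=1.0)
        assert rep.auc == 1.0
        assert rep.acc == 1.0
        assert rep.mcc == 1.0

    def test_noise_features_near_chance(self):
        rng = np.random.default_rng(7)
        y = np.repeat([0, 1], 20)
        X = rng.normal(size=(40, 30))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = loocv_predict(X, y, alpha=0.05, m=5)
        assert 0.3 <= rep.auc <= 0.7

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            loocv_predict(np.zeros((3, 2)), np.array([0, 1, 1]))

    def test_fold_isolation(self):
        """Re-running one fold by hand reproduces its recorded score."""
        from dlradiomics.selection import _fit_and_score

        rng = np.random.default_rng(8)
        y = np.repeat([0, 1], 6)
        X = rng.normal(size=(12, 10)) + 0.5 * y[:, None]
        rep = loocv_predict(X, y, alpha=1.0, m=4)
        i = 5
        tr = np.arange(12) != i
        manual = _fit_and_score(X[tr], y[tr], X[i : i + 1], 1.0, 4, 1.0)[0]
        assert manual == rep.scores[i]


class TestTimeSplit:
    def test_split_sizes_and_perfect_feature(self):
        y = np.tile([0, 1], 10)
        X = y.astype(float)[:, None]
        t = np.arange(20)
        rep = time_split_predict(X, y, t, cutoff=10, alpha=1.0, m=1)
        assert len(rep.scores) == 10
        assert rep.auc == 1.0

    def test_cutoff_beyond_all_times_rejected(self):
        y = np.tile([0, 1], 4)
        with pytest.raises(ValueError):
            time_split_predict(y[:, None].astype(float), y, np.arange(8), cutoff=100)
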