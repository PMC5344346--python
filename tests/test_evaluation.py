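import math

import numpy as np
import pytest

from ictalwave.evaluation import (
    ClassifierConfig,
    confusion_metrics,
    cv_splits,
    kfold_cv,
    leave_one_subject_out_cv,
    train_classify,
)
from ictalwave.io import NON_SEIZURE, SEIZURE, EEGSegment


class TestConfusionMetrics:
    def test_rates_from_counts(self):
        m = confusion_metrics(tp=97, fn=3, tn=200, fp=0)
        assert m.sensitivity == pytest.approx(0.97)
        assert m.specificity == 1.0
        assert m.ppv == 1.0
        assert m.npv == pytest.approx(0.9852, abs=1e-4)
        assert m.accuracy == pytest.approx(297 / 300)

    def test_symmetric_counts_give_half(self):
        m = confusion_metrics(25, 25, 25, 25)
        assert (m.accuracy, m.sensitivity, m.specificity, m.ppv, m.npv) == (0.5,) * 5

    def test_zero_denominator_reported_missing(self):
        m = confusion_metrics(tp=5, fp=0, tn=0, fn=2)
        assert math.isnan(m.specificity)
        assert m.sensitivity == pytest.approx(5 / 7)
        assert m.ppv == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 1, 0)

    def test_accuracy_decomposes_by_prevalence(self, rng):
        for _ in range(200):
            tp, fp, tn, fn = rng.integers(1, 100, size=4)
            m = confusion_metrics(int(tp), int(fp), int(tn), int(fn))
            p, n = tp + fn, tn + fp
            expected = m.sensitivity * p / (p + n) + m.specificity * n / (p + n)
            assert m.accuracy == pytest.approx(expected, rel=1e-12)


class TestTrainClassify:
    def test_separable_blobs_classified(self, rng):
        X1 = rng.normal(3.0, 1.0, size=(100, 2))
        X0 = rng.normal(-3.0, 1.0, size=(100, 2))
        X = np.vstack([X1, X0])
        y = np.array([1] * 100 + [0] * 100)
        Xt = np.vstack([rng.normal(3.0, 1.0, (50, 2)), rng.normal(-3.0, 1.0, (50, 2))])
        yt = np.array([1] * 50 + [0] * 50)
        pred = train_classify(X, y, Xt)
        assert np.mean(pred == yt) >= 0.95

    def test_single_identical_point(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        y = np.array([1, 0])
        assert train_classify(X, y, X[[0]], ClassifierConfig(standardize=False))[0] == 1

    def test_label_independent_features_near_chance(self, rng):
        X = rng.standard_normal((200, 5))
        y = np.array([0, 1] * 100)
        Xt = rng.standard_normal((400, 5))
        yt = np.array([0, 1] * 200)
        acc = np.mean(train_classify(X, y, Xt) == yt)
        assert abs(acc - 0.5) < 2.576 * math.sqrt(0.25 / 400)

    def test_one_class_training_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_classify(np.zeros((3, 2)), [1, 1, 1], np.zeros((1, 2)))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            train_classify(np.zeros((4, 2)), [0, 1, 0, 1], np.zeros((1, 3)))


class TestCVSplits:
    def test_loso_one_fold_per_subject(self):
        y = np.array([0, 1] * 6)
        groups = np.repeat(["a", "b", "c"], 4)
        folds = cv_splits(y, groups, "loso")
        assert len(folds) == 3
        for train, test in folds:
            assert set(train) & set(test) == set()
            assert len(set(groups[test])) == 1
            assert set(groups[train]) == set("abc") - set(groups[test])

    def test_loso_skips_one_class_training_folds(self):
        # subject c holds every positive: removing any other subject is fine,
        # but the fold testing on c would train on negatives only
        y = np.array([0, 0, 0, 0, 1, 1])
        groups = np.array(["a", "a", "b", "b", "c", "c"])
        with pytest.warns(UserWarning, match="one-class"):
            folds = cv_splits(y, groups, "loso")
        assert len(folds) == 2

    def test_stratified_kfold_on_imbalanced_classes(self):
        y = np.array([1] * 100 + [0] * 200)
        folds = cv_splits(y, None, "kfold:10", seed=0)
        assert len(folds) == 10
        for _, test in folds:
            assert np.sum(y[test] == 1) == 10
            assert np.sum(y[test] == 0) == 20

    def test_kfold_equals_n_is_leave_one_out(self):
        y = np.array([0, 1] * 5)
        folds = cv_splits(y, None, "kfold:10", seed=1)
        assert sorted(len(test) for _, test in folds) == [1] * 10

    def test_same_seed_same_folds(self):
        y = np.array([0, 1] * 20)
        a = cv_splits(y, None, "kfold:4", seed=9)
        b = cv_splits(y, None, "kfold:4", seed=9)
        for (tr1, te1), (tr2, te2) in zip(a, b):
            assert np.array_equal(te1, te2)

    def test_small_class_degrades_with_warning(self):
        y = np.array([1, 1] + [0] * 18)
        with pytest.warns(UserWarning, match="unstratified"):
            folds = cv_splits(y, None, "kfold:5", seed=0)
        assert len(folds) == 5

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            cv_splits(np.array([0, 1]), None, "bootstrap")


def _labeled_segments(rng, n_subjects=3, per_class=8, separation=3.0):
    segments = []
    for s in range(n_subjects):
        for _ in range(per_class):
            segments.append(EEGSegment(
                f"s{s}", "c", rng.normal(separation, 1.0, 32), 64.0, SEIZURE))
            segments.append(EEGSegment(
                f"s{s}", "c", rng.normal(-separation, 1.0, 32), 64.0, NON_SEIZURE))
    return segments


def _mean_feature(segment):
    return [float(np.mean(segment.samples))]


class TestSegmentCV:
    def test_loso_counts_conserved(self, rng):
        segments = _labeled_segments(rng)
        m = leave_one_subject_out_cv(segments, _mean_feature)
        assert m.total == len(segments)
        assert m.accuracy > 0.95

    def test_kfold_counts_conserved(self, rng):
        segments = _labeled_segments(rng)
        m = kfold_cv(segments, k=4, featurizer=_mean_feature, seed=0)
        assert m.total == len(segments)
        assert m.accuracy > 0.95

    def test_metrics_invariant_to_segment_order(self, rng):
        segments = _labeled_segments(rng)
        m1 = leave_one_subject_out_cv(segments, _mean_feature)
        m2 = leave_one_subject_out_cv(segments[::-1], _mean_feature)
        assert m1 == m2
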