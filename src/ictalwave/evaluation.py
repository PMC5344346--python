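"""Classifier contract, cross-validation schemes and confusion metrics.

The classifier is an RBF-kernel SVM preceded by feature standardization
fitted on the training fold only. Two CV schemes are provided:
leave-one-subject-out (one fold per subject, no subject in both train and
test) and seeded stratified k-fold. Folds are pooled into a single
confusion matrix, from which accuracy, sensitivity, specificity, PPV and
NPV are derived; seizure is the positive class throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass(frozen=True)
class ClassifierConfig:
    """RBF-SVM hyperparameters (unstated in most EEG studies, so explicit)."""

    C: float = 1.0
    gamma: float | str = "scale"  # dimension/variance-scaled kernel width
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not (self.gamma in ("scale", "auto") or (
            isinstance(self.gamma, (int, float)) and self.gamma > 0
        )):
            raise ValueError("gamma must be positive or 'scale'/'auto'")


@dataclass(frozen=True)
class ConfusionMetrics:
    """Pooled confusion counts and the five derived rates.

    Rates with a zero denominator are reported as NaN.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den else math.nan

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMetrics":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        if y_true.shape != y_pred.shape:
            raise ValueError("prediction/label shape mismatch")
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Build :class:`ConfusionMetrics` from raw counts."""
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def make_classifier(config: ClassifierConfig = ClassifierConfig()) -> Pipeline:
    """Standardizer + RBF-SVM pipeline (scaler parameters learned on fit)."""
    steps = []
    if config.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svc", SVC(C=config.C, gamma=config.gamma, kernel="rbf")))
    return Pipeline(steps)


def train_classify(
    train_vectors: np.ndarray,
    train_labels: np.ndarray,
    test_vectors: np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
) -> np.ndarray:
    """Fit the SVM on the training fold and predict binary test labels."""
    train_vectors = np.atleast_2d(np.asarray(train_vectors, dtype=float))
    test_vectors = np.atleast_2d(np.asarray(test_vectors, dtype=float))
    train_labels = np.asarray(train_labels).astype(int)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("training data must contain both classes")
    if train_vectors.shape[1] != test_vectors.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: train {train_vectors.shape[1]}, "
            f"test {test_vectors.shape[1]}"
        )
    clf = make_classifier(config)
    clf.fit(train_vectors, train_labels)
    return clf.predict(test_vectors)


def cv_splits(
    y: np.ndarray,
    groups: np.ndarray | None,
    scheme: str = "loso",
    seed: int | None = 0,
):
    """Yield (train_idx, test_idx) folds for 'loso' or 'kfold:K'.

    LOSO folds whose training part lacks a class are skipped with a
    warning; an error is raised if every fold is skipped. Stratified k-fold
    degrades to a plain shuffled k-fold (with a warning) when a class has
    fewer members than k.
    """
    y = np.asarray(y)
    folds = []
    if scheme == "loso":
        if groups is None:
            raise ValueError("leave-one-subject-out requires groups")
        groups = np.asarray(groups)
        subjects = sorted(set(groups.tolist()))
        if len(subjects) < 2:
            raise ValueError("leave-one-subject-out requires >= 2 subjects")
        for subject in subjects:
            test = np.flatnonzero(groups == subject)
            train = np.flatnonzero(groups != subject)
            if len(np.unique(y[train])) < 2:
                warnings.warn(
                    f"skipping fold for subject {subject!r}: one-class training set"
                )
                continue
            folds.append((train, test))
        if not folds:
            raise ValueError("all leave-one-subject-out folds were skipped")
    elif scheme.startswith("kfold"):
        k = int(scheme.split(":", 1)[1]) if ":" in scheme else 10
        if k < 2 or len(y) < k:
            raise ValueError(f"need 2 <= k <= n, got k={k}, n={len(y)}")
        counts = np.bincount(y.astype(int))
        if counts.min() < k:
            warnings.warn(
                f"class with {counts.min()} members < k={k}; "
                "using unstratified shuffled folds"
            )
            splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
            folds = list(splitter.split(y))
        else:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            folds = list(splitter.split(np.zeros_like(y), y))
    else:
        raise ValueError(f"unknown CV scheme {scheme!r} (use 'loso' or 'kfold:K')")
    return folds


def cross_validate_features(
    F: np.ndarray,
    y: np.ndarray,
    folds,
    config: ClassifierConfig = ClassifierConfig(),
) -> ConfusionMetrics:
    """Pooled confusion metrics of the SVM over precomputed folds."""
    y = np.asarray(y).astype(int)
    true_all: list[np.ndarray] = []
    pred_all: list[np.ndarray] = []
    for train, test in folds:
        pred = train_classify(F[train], y[train], F[test], config)
        true_all.append(y[test])
        pred_all.append(pred)
    return ConfusionMetrics.from_predictions(
        np.concatenate(true_all), np.concatenate(pred_all)
    )


def _featurize(segments, featurizer) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    from .io import segments_to_arrays

    X, y, groups = segments_to_arrays(segments)
    F = np.stack([np.asarray(featurizer(s), dtype=float).ravel() for s in segments])
    return F, y, groups


def leave_one_subject_out_cv(
    segments, featurizer, config: ClassifierConfig = ClassifierConfig()
) -> ConfusionMetrics:
    """One fold per subject; predictions pooled into one confusion matrix."""
    F, y, groups = _featurize(segments, featurizer)
    return cross_validate_features(F, y, cv_splits(y, groups, "loso"), config)


def kfold_cv(
    segments,
    k: int = 10,
    featurizer=None,
    config: ClassifierConfig = ClassifierConfig(),
    seed: int = 0,
) -> ConfusionMetrics:
    """Seeded stratified k-fold CV pooled into one confusion matrix."""
    if featurizer is None:
        raise ValueError("featurizer is required")
    F, y, _ = _featurize(segments, featurizer)
    return cross_validate_features(F, y, cv_splits(y, None, f"kfold:{k}", seed), config)
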