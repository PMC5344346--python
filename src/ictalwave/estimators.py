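"""scikit-learn estimators: DWT featurizer and the two search blocks.

`WaveletFeatureExtractor` is a Transformer mapping raw fixed-length EEG
windows (rows of X) to per-band coefficient statistics. `WaveletLevelSearch`
and `BandFeatureSearch` are meta-estimators in the mould of GridSearchCV:
the first scans every (mother wavelet, decomposition level) pair with all
bands and all nine features; the second exhaustively scans every non-empty
(band subset, feature subset) pair for one fixed wavelet and level. Both
score candidates by cross-validated pooled accuracy and expose the full
result table alongside the winner.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import wavelets as wv
from .evaluation import (
    ClassifierConfig,
    ConfusionMetrics,
    cross_validate_features,
    cv_splits,
    make_classifier,
)
from .features import FEATURE_NAMES, band_features, validate_feature_names


class WaveletFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transform raw EEG windows into per-band DWT coefficient statistics.

    Parameters
    ----------
    wavelet : catalog member name (e.g. ``"coif3"``).
    level : decomposition level j; bands 1..j are details from the highest
        octave down, band j+1 is the final approximation.
    bands : band indices to keep (default: all j+1).
    features : feature names to keep, in canonical order (default: all 9).
    sampling_rate : Hz of the input windows.
    freq_lo : lower edge of the analysed range (the high-pass cutoff); the
        band-to-frequency map spans (freq_lo, sampling_rate / 2).
    """

    def __init__(
        self,
        wavelet: str = "haar",
        level: int = 1,
        bands=None,
        features=None,
        sampling_rate: float = 256.0,
        freq_lo: float = 0.5,
    ):
        self.wavelet = wavelet
        self.level = level
        self.bands = bands
        self.features = features
        self.sampling_rate = sampling_rate
        self.freq_lo = freq_lo

    def fit(self, X, y=None):
        X = check_array(X)
        spec = wv.spec_for(self.wavelet)
        lmax = wv.max_decomposition_level(X.shape[1], spec.filter_length)
        if not 1 <= self.level <= lmax:
            raise ValueError(
                f"level {self.level} outside 1..{lmax} for {self.wavelet} "
                f"on {X.shape[1]}-sample windows"
            )
        self.spec_ = spec
        self.bands_ = (
            tuple(range(1, self.level + 2))
            if self.bands is None
            else tuple(sorted(set(self.bands)))
        )
        if not self.bands_ or min(self.bands_) < 1 or max(self.bands_) > self.level + 1:
            raise ValueError(
                f"bands must be a non-empty subset of 1..{self.level + 1}"
            )
        self.features_ = validate_feature_names(
            FEATURE_NAMES if self.features is None else self.features
        )
        self.n_features_in_ = X.shape[1]
        self.band_frequencies_ = wv.band_frequencies(
            self.freq_lo, self.sampling_rate / 2.0, self.level
        )
        self.layout_ = tuple(
            (b, f) for b in self.bands_ for f in self.features_
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "layout_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} samples per window, got {X.shape[1]}"
            )
        out = np.empty((X.shape[0], len(self.layout_)))
        for i, row in enumerate(X):
            dec = wv.decompose(
                row, self.spec_, self.level, self.sampling_rate, self.freq_lo
            )
            col = 0
            for b in self.bands_:
                feats = band_features(dec.band(b).coefficients, self.features_)
                for f in self.features_:
                    out[i, col] = feats[f]
                    col += 1
        return out

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "layout_")
        return np.array([f"b{b}_{f}" for b, f in self.layout_], dtype=object)


def _metrics_row(wavelet: str, family: str, level: int, m: ConfusionMetrics) -> dict:
    row = {"wavelet": wavelet, "family": family, "level": level}
    row.update(m.as_dict())
    return row


class WaveletLevelSearch(BaseEstimator):
    """Scan (mother wavelet, level) pairs by cross-validated accuracy.

    Every candidate is scored with feature vectors built from ALL bands and
    all nine features. ``best_per_family_`` applies either the plain argmax
    rule or the threshold rule (lowest level reaching ``threshold``, then
    smallest vanishing moments).

    Attributes
    ----------
    entries_ : DataFrame with one row per (wavelet, level) and the pooled
        confusion counts and rates.
    max_levels_ : wavelet -> maximum level at this window length.
    best_per_wavelet_ : wavelet -> (level, accuracy).
    best_per_family_ : family -> (wavelet, level, accuracy).
    best_wavelet_, best_level_, best_accuracy_ : overall winner.
    """

    def __init__(
        self,
        wavelets=None,
        levels=None,
        cv: str = "loso",
        C: float = 1.0,
        gamma="scale",
        standardize: bool = True,
        sampling_rate: float = 256.0,
        freq_lo: float = 0.5,
        rule: str = "max",
        threshold: float = 0.95,
        random_state: int | None = 0,
    ):
        self.wavelets = wavelets
        self.levels = levels
        self.cv = cv
        self.C = C
        self.gamma = gamma
        self.standardize = standardize
        self.sampling_rate = sampling_rate
        self.freq_lo = freq_lo
        self.rule = rule
        self.threshold = threshold
        self.random_state = random_state

    def _config(self) -> ClassifierConfig:
        return ClassifierConfig(self.C, self.gamma, self.standardize)

    def _levels_for(self, lmax: int):
        if self.levels is None:
            return range(1, lmax + 1)
        lo, hi = (1, self.levels) if np.isscalar(self.levels) else self.levels
        return range(max(1, lo), min(hi, lmax) + 1)

    def fit(self, X, y, groups=None):
        X = check_array(X)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("need both classes present")
        names = list(self.wavelets) if self.wavelets else [
            s.member for s in wv.catalog()
        ]
        if not names:
            raise ValueError("wavelet candidate list is empty")
        folds = cv_splits(y, groups, self.cv, self.random_state)
        config = self._config()
        rows = []
        self.max_levels_ = {}
        for name in names:
            spec = wv.spec_for(name)
            lmax = wv.max_decomposition_level(X.shape[1], spec.filter_length)
            self.max_levels_[name] = lmax
            for level in self._levels_for(lmax):
                F = WaveletFeatureExtractor(
                    name, level, None, None, self.sampling_rate, self.freq_lo
                ).fit(X).transform(X)
                metrics = cross_validate_features(F, y, folds, config)
                rows.append(_metrics_row(name, spec.family, level, metrics))
        self.entries_ = pd.DataFrame(rows)
        self.best_per_wavelet_ = {}
        for name in names:
            sub = self.entries_[self.entries_.wavelet == name]
            best = sub.sort_values(["accuracy", "level"], ascending=[False, True]).iloc[0]
            self.best_per_wavelet_[name] = (int(best.level), float(best.accuracy))
        self.best_per_family_ = (
            pick_family_best_threshold(self.entries_, self.threshold)
            if self.rule == "threshold"
            else pick_family_best_max(self.entries_)
        )
        top = min(self.entries_.itertuples(), key=_tie_key_max)
        self.best_wavelet_ = str(top.wavelet)
        self.best_level_ = int(top.level)
        self.best_accuracy_ = float(top.accuracy)
        return self


def _tie_key_max(row) -> tuple:
    spec = wv.spec_for(row.wavelet)
    return (-row.accuracy, row.level, spec.filter_length, row.wavelet)


def pick_family_best_max(entries: pd.DataFrame) -> dict[str, tuple[str, int, float]]:
    """Per family: highest accuracy; ties -> lower level, shorter filter, name."""
    if len(entries) == 0:
        raise ValueError("no entries to pick from")
    out = {}
    for family, sub in entries.groupby("family"):
        best = min(sub.itertuples(), key=_tie_key_max)
        out[str(family)] = (str(best.wavelet), int(best.level), float(best.accuracy))
    return out


def pick_family_best_threshold(
    entries: pd.DataFrame, threshold: float = 0.95
) -> dict[str, tuple[str, int, float]]:
    """Per family: lowest level reaching ``threshold`` accuracy, then the
    member with the smallest vanishing moments; falls back to the argmax
    rule (with a warning) when no entry reaches the threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    out = {}
    for family, sub in entries.groupby("family"):
        ok = sub[sub.accuracy >= threshold]
        if len(ok) == 0:
            warnings.warn(
                f"family {family!r}: no entry reaches accuracy {threshold}; "
                "falling back to the argmax rule"
            )
            best = min(sub.itertuples(), key=_tie_key_max)
        else:
            best = min(
                ok.itertuples(),
                key=lambda r: (
                    r.level,
                    wv.spec_for(r.wavelet).vanishing_moments,
                    r.wavelet,
                ),
            )
        out[str(family)] = (str(best.wavelet), int(best.level), float(best.accuracy))
    return out


class BandFeatureSearch(BaseEstimator):
    """Exhaustive (band subset, feature subset) search for one wavelet+level.

    The full feature matrix over the candidate bands and features is
    computed once; each of the (2^B - 1)(2^M - 1) subset pairs is then a
    column slice scored on the SAME cross-validation folds. The winner is
    the highest pooled accuracy, ties broken by smaller dimension, then
    lexicographic subsets. After the search the winning pipeline is refitted
    on all data, so the estimator predicts like a plain classifier.

    Attributes
    ----------
    results_ : DataFrame, one row per combination (bands, features,
        dimension, confusion counts and rates).
    best_bands_, best_features_, best_metrics_ : the winning combination.
    dimensionality_reduction_ : percent reduction versus the full
        (level + 1) x 9 vector.
    """

    def __init__(
        self,
        wavelet: str = "haar",
        level: int = 1,
        candidate_bands=None,
        candidate_features=None,
        cv: str = "loso",
        C: float = 1.0,
        gamma="scale",
        standardize: bool = True,
        sampling_rate: float = 256.0,
        freq_lo: float = 0.5,
        random_state: int | None = 0,
    ):
        self.wavelet = wavelet
        self.level = level
        self.candidate_bands = candidate_bands
        self.candidate_features = candidate_features
        self.cv = cv
        self.C = C
        self.gamma = gamma
        self.standardize = standardize
        self.sampling_rate = sampling_rate
        self.freq_lo = freq_lo
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        X = check_array(X)
        y = np.asarray(y).astype(int)
        cand_bands = (
            tuple(range(1, self.level + 2))
            if self.candidate_bands is None
            else tuple(sorted(set(self.candidate_bands)))
        )
        cand_feats = validate_feature_names(
            FEATURE_NAMES if self.candidate_features is None else self.candidate_features
        )
        if not cand_bands:
            raise ValueError("candidate band set must be non-empty")
        extractor = WaveletFeatureExtractor(
            self.wavelet, self.level, cand_bands, cand_feats,
            self.sampling_rate, self.freq_lo,
        ).fit(X)
        F_full = extractor.transform(X)
        columns = {bf: i for i, bf in enumerate(extractor.layout_)}
        folds = cv_splits(y, groups, self.cv, self.random_state)
        config = ClassifierConfig(self.C, self.gamma, self.standardize)

        feat_order = {f: i for i, f in enumerate(FEATURE_NAMES)}
        rows = []
        for nb in range(1, len(cand_bands) + 1):
            for bands in itertools.combinations(cand_bands, nb):
                for nf in range(1, len(cand_feats) + 1):
                    for feats in itertools.combinations(cand_feats, nf):
                        cols = [columns[(b, f)] for b in bands for f in feats]
                        metrics = cross_validate_features(
                            F_full[:, cols], y, folds, config
                        )
                        row = {
                            "bands": bands,
                            "features": feats,
                            "dimension": len(cols),
                        }
                        row.update(metrics.as_dict())
                        rows.append(row)
        self.results_ = pd.DataFrame(rows)

        def key(r):
            return (
                -r.accuracy,
                r.dimension,
                r.bands,
                tuple(feat_order[f] for f in r.features),
            )

        best = min(self.results_.itertuples(), key=key)
        self.best_bands_ = tuple(best.bands)
        self.best_features_ = tuple(best.features)
        self.best_metrics_ = ConfusionMetrics(best.TP, best.FP, best.TN, best.FN)
        self.dimensionality_reduction_ = dimensionality_reduction(
            self.level, len(self.best_bands_), len(self.best_features_)
        )
        self.best_extractor_ = WaveletFeatureExtractor(
            self.wavelet, self.level, self.best_bands_, self.best_features_,
            self.sampling_rate, self.freq_lo,
        ).fit(X)
        self.best_classifier_ = make_classifier(config).fit(
            self.best_extractor_.transform(X), y
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "best_classifier_")
        return self.best_classifier_.predict(self.best_extractor_.transform(X))

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y).astype(int)))


def count_combinations(level: int, n_features: int) -> int:
    """Number of non-empty (band subset, feature subset) pairs at level j:
    (2^(j+1) - 1) (2^m - 1)."""
    if level < 1 or n_features < 1:
        raise ValueError("level and n_features must be >= 1")
    return (2 ** (level + 1) - 1) * (2**n_features - 1)


def dimensionality_reduction(
    level: int, n_bands_selected: int, n_features_selected: int, m: int = 9
) -> float:
    """Percent reduction of the feature-vector dimension, to 2 decimals.

    The reference dimension is the full (level + 1) bands x m features
    vector used during wavelet-level selection.
    """
    if not 1 <= n_bands_selected <= level + 1:
        raise ValueError("n_bands_selected must lie in 1..level+1")
    if not 1 <= n_features_selected <= m:
        raise ValueError("n_features_selected must lie in 1..m")
    full = (level + 1) * m
    return round(100.0 * (1.0 - n_bands_selected * n_features_selected / full), 2)
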