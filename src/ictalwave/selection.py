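"""The two search blocks as plain functions over labeled segments.

These are thin wrappers around :class:`~ictalwave.estimators.WaveletLevelSearch`
and :class:`~ictalwave.estimators.BandFeatureSearch` for callers holding
:class:`~ictalwave.io.EEGSegment` lists rather than arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .estimators import (
    BandFeatureSearch,
    WaveletLevelSearch,
    count_combinations,
    dimensionality_reduction,
)
from .estimators import (
    pick_family_best_max as _pick_max,
)
from .estimators import (
    pick_family_best_threshold as _pick_threshold,
)
from .evaluation import ClassifierConfig, ConfusionMetrics
from .io import segments_to_arrays

__all__ = [
    "WaveletLevelResult",
    "BandFeatureResult",
    "wavelet_level_search",
    "band_feature_search",
    "pick_family_best_max",
    "pick_family_best_threshold",
    "count_combinations",
    "dimensionality_reduction",
]


@dataclass
class WaveletLevelResult:
    entries: pd.DataFrame  # one row per (wavelet, level) with pooled metrics
    best_per_wavelet: dict[str, tuple[int, float]]
    best_per_family: dict[str, tuple[str, int, float]]
    max_levels: dict[str, int]


@dataclass
class BandFeatureResult:
    wavelet: str
    level: int
    entries: pd.DataFrame  # one row per (band subset, feature subset)
    best_bands: tuple[int, ...]
    best_features: tuple[str, ...]
    best_metrics: ConfusionMetrics
    dimensionality_reduction: float


def wavelet_level_search(
    segments,
    wavelets=None,
    cv_scheme: str = "loso",
    classifier_config: ClassifierConfig = ClassifierConfig(),
    levels=None,
    rule: str = "max",
    threshold: float = 0.95,
    seed: int = 0,
    freq_lo: float = 0.5,
) -> WaveletLevelResult:
    """Score every candidate (wavelet, level) pair by cross-validated accuracy."""
    X, y, groups = segments_to_arrays(segments)
    search = WaveletLevelSearch(
        wavelets=wavelets,
        levels=levels,
        cv=cv_scheme,
        C=classifier_config.C,
        gamma=classifier_config.gamma,
        standardize=classifier_config.standardize,
        sampling_rate=segments[0].sampling_rate,
        freq_lo=freq_lo,
        rule=rule,
        threshold=threshold,
        random_state=seed,
    ).fit(X, y, groups)
    return WaveletLevelResult(
        entries=search.entries_,
        best_per_wavelet=search.best_per_wavelet_,
        best_per_family=search.best_per_family_,
        max_levels=search.max_levels_,
    )


def pick_family_best_max(result: WaveletLevelResult) -> dict[str, tuple[str, int, float]]:
    """Per-family argmax accuracy; ties -> lower level, shorter filter, name."""
    return _pick_max(result.entries)


def pick_family_best_threshold(
    result: WaveletLevelResult, threshold: float = 0.95
) -> dict[str, tuple[str, int, float]]:
    """Per-family lowest level above the accuracy threshold, then smallest
    vanishing moments; argmax fallback when nothing reaches the threshold."""
    return _pick_threshold(result.entries, threshold)


def band_feature_search(
    segments,
    wavelet: str,
    level: int,
    cv_scheme: str = "loso",
    classifier_config: ClassifierConfig = ClassifierConfig(),
    candidate_bands=None,
    candidate_features=None,
    seed: int = 0,
    freq_lo: float = 0.5,
) -> BandFeatureResult:
    """Exhaustively score every non-empty (band subset, feature subset) pair."""
    X, y, groups = segments_to_arrays(segments)
    search = BandFeatureSearch(
        wavelet=wavelet,
        level=level,
        candidate_bands=candidate_bands,
        candidate_features=candidate_features,
        cv=cv_scheme,
        C=classifier_config.C,
        gamma=classifier_config.gamma,
        standardize=classifier_config.standardize,
        sampling_rate=segments[0].sampling_rate,
        freq_lo=freq_lo,
        random_state=seed,
    ).fit(X, y, groups)
    return BandFeatureResult(
        wavelet=wavelet,
        level=level,
        entries=search.results_,
        best_bands=search.best_bands_,
        best_features=search.best_features_,
        best_metrics=search.best_metrics_,
        dimensionality_reduction=search.dimensionality_reduction_,
    )
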