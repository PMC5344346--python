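"""Per-band coefficient statistics and feature-vector assembly.

Nine order-free statistics are computed on each band's wavelet
coefficients: Max, Min, Mean, STD (sample, n-1 denominator), skewness and
kurtosis (population-moment, kurtosis not excess-corrected so a normal band
scores 3), Energy (sum of squares), nSTD = STD / (Max - Min), and
nEnergy = Energy / n where n is the band's coefficient count. Feature
vectors are laid out bands-major: all chosen features of the lowest-index
band first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .wavelets import BandDecomposition

#: Canonical feature order; subsets always preserve this order.
FEATURE_NAMES: tuple[str, ...] = (
    "Max",
    "Min",
    "Mean",
    "STD",
    "skewness",
    "kurtosis",
    "Energy",
    "nSTD",
    "nEnergy",
)


def validate_feature_names(names) -> tuple[str, ...]:
    """Check a feature subset and return it in canonical order."""
    names = tuple(names)
    if not names:
        raise ValueError("feature subset must be non-empty")
    unknown = [n for n in names if n not in FEATURE_NAMES]
    if unknown:
        raise ValueError(f"unknown feature name(s): {unknown}")
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names")
    return tuple(n for n in FEATURE_NAMES if n in names)


def band_features(coefficients: np.ndarray, names=FEATURE_NAMES) -> dict[str, float]:
    """Compute the named statistics of one coefficient series.

    Degenerate bands never raise: constant or single-coefficient bands
    report 0 for STD-derived features, skewness and kurtosis, so exhaustive
    searches run to completion on any input.
    """
    names = validate_feature_names(names)
    c = np.asarray(coefficients, dtype=float).ravel()
    if c.size == 0:
        raise ValueError("empty coefficient vector")
    cmax = float(c.max())
    cmin = float(c.min())
    energy = float(c @ c)
    degenerate = c.size < 2 or cmax == cmin
    std = 0.0 if degenerate else float(np.std(c, ddof=1))

    def _moment(func) -> float:
        # moments of near-constant bands can underflow to 0/0; report the
        # degenerate convention (0) instead of NaN so searches never abort
        if degenerate:
            return 0.0
        value = float(func(c))
        return value if math.isfinite(value) else 0.0

    values = {
        "Max": cmax,
        "Min": cmin,
        "Mean": float(c.mean()),
        "STD": std,
        "skewness": _moment(lambda v: stats.skew(v, bias=True)),
        "kurtosis": _moment(lambda v: stats.kurtosis(v, fisher=False, bias=True)),
        "Energy": energy,
        "nSTD": 0.0 if degenerate else std / (cmax - cmin),
        "nEnergy": energy / c.size,
    }
    return {n: values[n] for n in names}


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    layout: tuple[tuple[int, str], ...]  # (band_index, feature_name) per position

    def __post_init__(self) -> None:
        if len(self.values) != len(self.layout):
            raise ValueError("values and layout lengths differ")

    def __len__(self) -> int:
        return len(self.values)


def assemble_feature_vector(
    decomposition: BandDecomposition,
    band_subset=None,
    names=FEATURE_NAMES,
) -> FeatureVector:
    """Feature vector over chosen bands x features, bands-major layout."""
    names = validate_feature_names(names)
    available = [b.index for b in decomposition.bands]
    if band_subset is None:
        band_subset = available
    band_subset = sorted(set(band_subset))
    if not band_subset:
        raise ValueError("band subset must be non-empty")
    unknown = [b for b in band_subset if b not in available]
    if unknown:
        raise ValueError(f"unknown band index(es): {unknown}; have {available}")
    values: list[float] = []
    layout: list[tuple[int, str]] = []
    for b in band_subset:
        feats = band_features(decomposition.band(b).coefficients, names)
        for n in names:
            values.append(feats[n])
            layout.append((b, n))
    return FeatureVector(np.array(values), tuple(layout))
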