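"""Wavelet catalog, decomposition-level rule, multilevel DWT and band mapping.

The catalog covers the 54 mother wavelets commonly benchmarked for EEG
seizure detection: 15 biorthogonal, 5 coiflets, 10 Daubechies, 15 reverse
biorthogonal, 7 symlets, the discrete Meyer filter and Haar. Decomposition
is the standard Mallat cascade (PyWavelets ``wavedec``) with symmetric
boundary extension; each detail/approximation series is mapped to the
frequency interval it occupies in the original signal.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pywt

from ._dmey import DMEY_LENGTH, dmey_wavelet

__all__ = [
    "WaveletSpec",
    "Band",
    "BandDecomposition",
    "catalog",
    "get_wavelet",
    "max_decomposition_level",
    "band_frequencies",
    "decompose",
    "rhythm_overlap",
    "RHYTHMS",
]

#: Conventional human EEG rhythms (Hz). gamma is open-ended above 31 Hz.
RHYTHMS: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 15.0),
    "beta": (16.0, 31.0),
    "gamma": (31.0, math.inf),
}

_CATALOG_MEMBERS: dict[str, tuple[str, ...]] = {
    "bior": (
        "bior1.1", "bior1.3", "bior1.5", "bior2.2", "bior2.4", "bior2.6",
        "bior2.8", "bior3.1", "bior3.3", "bior3.5", "bior3.7", "bior3.9",
        "bior4.4", "bior5.5", "bior6.8",
    ),
    "coif": ("coif1", "coif2", "coif3", "coif4", "coif5"),
    "db": (
        "db1", "db2", "db3", "db4", "db5", "db6", "db7", "db8", "db9", "db10",
    ),
    "rbio": (
        "rbio1.1", "rbio1.3", "rbio1.5", "rbio2.2", "rbio2.4", "rbio2.6",
        "rbio2.8", "rbio3.1", "rbio3.3", "rbio3.5", "rbio3.7", "rbio3.9",
        "rbio4.4", "rbio5.5", "rbio6.8",
    ),
    "sym": ("sym2", "sym3", "sym4", "sym5", "sym6", "sym7", "sym8"),
    "dmey": ("dmey",),
    "haar": ("haar",),
}


@dataclass(frozen=True)
class WaveletSpec:
    """One catalog entry: a mother wavelet and its filter properties."""

    family: str
    member: str
    filter_length: int
    vanishing_moments: int

    def __post_init__(self) -> None:
        if self.filter_length < 2:
            raise ValueError("filter_length must be >= 2")


def _vanishing_moments(family: str, member: str) -> int:
    # Used only as an intra-family simplicity ordering, so the member order
    # (first integer of the name; coifN annihilates 2N moments; dmey is a
    # single-member family where the value never matters) is sufficient.
    if family == "haar":
        return 1
    if family == "dmey":
        return 0
    first = int(re.search(r"(\d+)", member).group(1))
    return 2 * first if family == "coif" else first


def get_wavelet(name: str) -> pywt.Wavelet:
    """PyWavelets object for a catalog member (dmey uses the 102-tap filter)."""
    if name == "dmey":
        return dmey_wavelet()
    return pywt.Wavelet(name)


def catalog() -> list[WaveletSpec]:
    """The 54-member mother-wavelet catalog."""
    specs = []
    for family, members in _CATALOG_MEMBERS.items():
        for member in members:
            length = DMEY_LENGTH if member == "dmey" else pywt.Wavelet(member).dec_len
            specs.append(
                WaveletSpec(family, member, length, _vanishing_moments(family, member))
            )
    return specs


def spec_for(name: str) -> WaveletSpec:
    """Catalog entry for a member name."""
    for s in catalog():
        if s.member == name:
            return s
    raise KeyError(f"unknown catalog wavelet: {name!r}")


def max_decomposition_level(n_samples: int, filter_length: int) -> int:
    """Maximum useful dyadic decomposition level, floor(log2(N / (F - 1))).

    N is the segment length, F the wavelet filter length. This is the
    standard convention under which e.g. a 5120-sample segment supports 12
    Haar levels but only 5 discrete-Meyer levels.
    """
    if filter_length < 2:
        raise ValueError("filter_length must be >= 2")
    if n_samples < filter_length:
        raise ValueError(
            f"signal of {n_samples} samples shorter than filter ({filter_length})"
        )
    return max(1, int(math.floor(math.log2(n_samples / (filter_length - 1)))))


def band_frequencies(a: float, b: float, level: int) -> list[tuple[float, float]]:
    """Frequency interval of every band of a level-j dyadic decomposition.

    Returned in band-index order: detail bands 1..j from the highest octave
    downward, then the final approximation band. Detail band n spans
    (a + (b-a)/2^n, a + (b-a)/2^(n-1)); the approximation spans
    (a, a + (b-a)/2^j). The intervals tile (a, b) exactly.
    """
    if not 0 <= a < b:
        raise ValueError("need 0 <= a < b")
    if level < 1:
        raise ValueError("level must be >= 1")
    width = b - a
    out = [(a + width / 2**n, a + width / 2 ** (n - 1)) for n in range(1, level + 1)]
    out.append((a, a + width / 2**level))
    return out


@dataclass(frozen=True)
class Band:
    """One coefficient series of a decomposition and its frequency interval."""

    index: int
    kind: str  # "detail" | "approximation"
    coefficients: np.ndarray = field(repr=False)
    freq_lo: float
    freq_hi: float

    def __post_init__(self) -> None:
        if self.freq_lo >= self.freq_hi:
            raise ValueError("freq_lo must be < freq_hi")

    @property
    def interval(self) -> tuple[float, float]:
        return (self.freq_lo, self.freq_hi)


@dataclass(frozen=True)
class BandDecomposition:
    wavelet: WaveletSpec
    level: int
    bands: tuple[Band, ...]
    source_range: tuple[float, float]

    def band(self, index: int) -> Band:
        for b in self.bands:
            if b.index == index:
                return b
        raise KeyError(f"no band with index {index}")


def decompose(
    samples: np.ndarray,
    wavelet: str | WaveletSpec,
    level: int,
    sampling_rate: float,
    freq_lo: float = 0.5,
    mode: str = "symmetric",
) -> BandDecomposition:
    """Multilevel DWT of one segment, bands indexed 1 (highest octave) .. j+1.

    The source frequency range runs from the high-pass cutoff ``freq_lo`` to
    the Nyquist frequency, so e.g. 256 Hz data maps to (0.5, 128) Hz.
    """
    spec = wavelet if isinstance(wavelet, WaveletSpec) else spec_for(wavelet)
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("samples must be one-dimensional")
    lmax = max_decomposition_level(x.size, spec.filter_length)
    if not 1 <= level <= lmax:
        raise ValueError(
            f"level {level} outside 1..{lmax} for {spec.member} on {x.size} samples"
        )
    nyquist = sampling_rate / 2.0
    coeffs = pywt.wavedec(x, get_wavelet(spec.member), mode=mode, level=level)
    freqs = band_frequencies(freq_lo, nyquist, level)
    bands = []
    for i in range(1, level + 1):  # detail at level i is coeffs[-i]
        lo, hi = freqs[i - 1]
        bands.append(Band(i, "detail", coeffs[-i], lo, hi))
    lo, hi = freqs[level]
    bands.append(Band(level + 1, "approximation", coeffs[0], lo, hi))
    return BandDecomposition(spec, level, tuple(bands), (freq_lo, nyquist))


def reconstruct(decomposition: BandDecomposition, mode: str = "symmetric") -> np.ndarray:
    """Invert :func:`decompose` (up to the usual even-length padding)."""
    j = decomposition.level
    coeffs = [decomposition.band(j + 1).coefficients]
    coeffs += [decomposition.band(i).coefficients for i in range(j, 0, -1)]
    return pywt.waverec(coeffs, get_wavelet(decomposition.wavelet.member), mode=mode)


def rhythm_overlap(band: Band | tuple[float, float]) -> list[str]:
    """Names of the EEG rhythms whose range intersects the band's interval."""
    lo, hi = band.interval if isinstance(band, Band) else band
    return [name for name, (rlo, rhi) in RHYTHMS.items() if lo < rhi and hi > rlo]
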