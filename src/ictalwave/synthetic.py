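"""Synthetic multi-subject EEG generator with planted rhythm-band effects.

Non-seizure windows are 1/f^beta Gaussian noise shaped in the frequency
domain. Seizure windows share the same background construction and add
random-phase band-limited components whose per-bin amplitude is ``gain``
times the background spectral envelope inside each effect band, so the
expected seizure/background power ratio there is 1 + gain^2. A per-subject
log-normal factor scales the effect amplitudes, mimicking the
between-subject variability that makes leave-one-subject-out CV harder
than pooled k-fold. Seizure morphology is deliberately reduced to
band-limited power elevation (no spike-wave shape): enough to make every
coefficient statistic discriminative and every pipeline stage testable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io import NON_SEIZURE, SEIZURE, EEGSegment, write_edf


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults emulate a small multi-subject cohort: 6 subjects contributing
    20 seizure and 20 non-seizure 20 s windows each at 256 Hz, pink-noise
    background (beta = 1), and one theta-band (4-7 Hz) seizure effect with
    amplitude gain 3.
    """

    n_subjects: int = 6
    segments_per_class_per_subject: int = 20
    sampling_rate: float = 256.0
    window_seconds: float = 20.0
    background_exponent: float = 1.0
    effect_bands: tuple[tuple[float, float, float], ...] = ((4.0, 7.0, 3.0),)
    subject_gain_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.segments_per_class_per_subject < 1:
            raise ValueError("counts must be positive")
        if self.sampling_rate <= 0 or self.window_seconds <= 0:
            raise ValueError("sampling_rate and window_seconds must be positive")
        nyq = self.sampling_rate / 2.0
        for lo, hi, gain in self.effect_bands:
            if not 0 <= lo < hi <= nyq:
                raise ValueError(
                    f"effect band ({lo}, {hi}) must lie within (0, Nyquist={nyq})"
                )
            if gain < 0:
                raise ValueError("effect gains must be >= 0")

    @property
    def n_window(self) -> int:
        return int(round(self.window_seconds * self.sampling_rate))


def _spectral_envelope(freqs: np.ndarray, beta: float) -> np.ndarray:
    env = np.zeros_like(freqs)
    pos = freqs > 0
    env[pos] = freqs[pos] ** (-beta / 2.0)
    return env


def _one_window(
    rng: np.random.Generator,
    config: SyntheticConfig,
    seizure: bool,
    subject_gain: float,
) -> np.ndarray:
    n = config.n_window
    freqs = np.fft.rfftfreq(n, d=1.0 / config.sampling_rate)
    env = _spectral_envelope(freqs, config.background_exponent)
    spectrum = env * (
        rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    ) / np.sqrt(2.0)
    if seizure:
        for lo, hi, gain in config.effect_bands:
            sel = (freqs >= lo) & (freqs < hi)
            phases = rng.uniform(0.0, 2.0 * np.pi, int(sel.sum()))
            spectrum[sel] += subject_gain * gain * env[sel] * np.exp(1j * phases)
    return np.fft.irfft(spectrum, n=n)


def generate_dataset(config: SyntheticConfig = SyntheticConfig()) -> list[EEGSegment]:
    """Generate balanced labeled segments for every synthetic subject."""
    rng = np.random.default_rng(config.seed)
    segments: list[EEGSegment] = []
    for s in range(config.n_subjects):
        subject = f"S{s:02d}"
        subject_gain = float(np.exp(rng.normal(0.0, config.subject_gain_sd)))
        for k in range(config.segments_per_class_per_subject):
            for label, seizure in ((SEIZURE, True), (NON_SEIZURE, False)):
                segments.append(
                    EEGSegment(
                        subject_id=subject,
                        channel="sim0",
                        samples=_one_window(rng, config, seizure, subject_gain),
                        sampling_rate=config.sampling_rate,
                        label=label,
                        origin_offset_s=k * config.window_seconds,
                    )
                )
    return segments


def make_fixture_edf(
    config: SyntheticConfig,
    path: str | Path,
    n_channels: int = 2,
    duration_s: float = 120.0,
    seizure_intervals: tuple[tuple[float, float], ...] = ((40.0, 70.0),),
) -> tuple[Path, Path]:
    """Write a small synthetic EDF record plus its annotation CSV.

    Background noise fills the whole record; the effect bands are added
    inside each seizure interval. Returns (edf_path, csv_path).
    """
    path = Path(path)
    fs = config.sampling_rate
    if abs(fs - round(fs)) > 1e-9 or abs(duration_s - round(duration_s)) > 1e-9:
        raise ValueError("EDF fixture needs integer sampling rate and duration")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(config.seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    env = _spectral_envelope(freqs, config.background_exponent)
    data = np.empty((n_channels, n))
    intervals = sorted(seizure_intervals)
    for ch in range(n_channels):
        spectrum = env * (
            rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
        ) / np.sqrt(2.0)
        x = np.fft.irfft(spectrum, n=n)
        for start, end in intervals:
            i0, i1 = int(round(start * fs)), int(round(end * fs))
            m = i1 - i0
            t = np.arange(m) / fs
            burst = np.zeros(m)
            for lo, hi, gain in config.effect_bands:
                bins = np.arange(np.ceil(lo * m / fs), np.floor(hi * m / fs)) * fs / m
                for f in bins:
                    burst += (
                        gain
                        * _spectral_envelope(np.array([f]), config.background_exponent)[0]
                        * np.cos(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
                    )
            x[i0:i1] += burst * x[i0:i1].std() / max(burst.std(), 1e-12) * 0.8
        data[ch] = x
    scale = 50.0 / data.std()
    write_edf(path, data * scale, fs, [f"EEG{c}" for c in range(n_channels)])

    csv_path = path.with_suffix(".csv")
    record_id = path.stem
    with open(csv_path, "w") as fh:
        fh.write("subject_id,record_id,start_s,end_s\n")
        for start, end in intervals:
            fh.write(f"{record_id},{record_id},{start},{end}\n")
    return path, csv_path


def save_config(config: SyntheticConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(config), indent=2) + "\n")


def load_config(path: str | Path) -> SyntheticConfig:
    raw = json.loads(Path(path).read_text())
    raw["effect_bands"] = tuple(tuple(b) for b in raw.get("effect_bands", ()))
    return SyntheticConfig(**raw)
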