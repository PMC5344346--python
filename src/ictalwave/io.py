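"""EEG record/segment I/O, windowing, preprocessing and class balancing.

Two on-disk shapes are supported: EDF records (CHB-MIT style multi-channel
recordings, seizure intervals supplied separately as a CSV of
``subject_id,record_id,start_s,end_s``) and plain-text single-column sample
files (UBonn style, one integer per line). Records are cut into fixed,
non-overlapping windows; a window is labeled seizure only when it lies fully
inside an annotated interval, windows straddling an interval boundary are
discarded to avoid label noise.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import firwin, lfilter

SEIZURE = "seizure"
NON_SEIZURE = "non-seizure"

UBONN_SAMPLING_RATE = 173.61


def merge_intervals(
    intervals: list[tuple[float, float]], duration: float | None = None
) -> list[tuple[float, float]]:
    """Sort half-open [start, end) intervals and merge overlaps.

    Raises if any interval is empty, negative, or extends past ``duration``.
    """
    for s, e in intervals:
        if not 0 <= s < e:
            raise ValueError(f"invalid interval ({s}, {e}): need 0 <= start < end")
        if duration is not None and e > duration + 1e-9:
            raise ValueError(f"interval ({s}, {e}) extends past record end {duration}")
    merged: list[tuple[float, float]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class EEGRecord:
    """A multi-channel recording with merged, sorted seizure intervals."""

    subject_id: str
    channel_labels: list[str]
    samples: np.ndarray  # (n_channels, n_samples)
    sampling_rate: float
    seizure_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("one channel label per sample row required")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.seizure_intervals = merge_intervals(self.seizure_intervals, self.duration)

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sampling_rate


@dataclass
class EEGSegment:
    """One labeled fixed-length single-channel window."""

    subject_id: str
    channel: str
    samples: np.ndarray
    sampling_rate: float
    label: str
    origin_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.label not in (SEIZURE, NON_SEIZURE):
            raise ValueError(f"label must be {SEIZURE!r} or {NON_SEIZURE!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size


def read_ubonn_segment(
    path: str | Path,
    sampling_rate: float = UBONN_SAMPLING_RATE,
    label: str = NON_SEIZURE,
    subject_id: str = "",
    channel: str = "ch0",
) -> EEGSegment:
    """Read a single-column ASCII sample file into one segment."""
    path = Path(path)
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno} is not numeric: {text!r}"
                ) from None
    if not values:
        raise ValueError(f"{path}: file contains no samples")
    sid = subject_id or path.stem
    return EEGSegment(sid, channel, np.array(values), sampling_rate, label)


def read_edf_record(
    path: str | Path,
    seizure_intervals: list[tuple[float, float]] | None = None,
    subject_id: str | None = None,
) -> EEGRecord:
    """Read an EDF file into an :class:`EEGRecord` (annotations attached)."""
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # unreadable / malformed header
        raise OSError(f"could not read EDF file {path}: {exc}") from exc
    return EEGRecord(
        subject_id=subject_id or path.stem,
        channel_labels=list(raw.ch_names),
        samples=raw.get_data(),
        sampling_rate=float(raw.info["sfreq"]),
        seizure_intervals=list(seizure_intervals or []),
    )


def read_annotations_csv(path: str | Path) -> dict[tuple[str, str], list[tuple[float, float]]]:
    """Read a ``subject_id,record_id,start_s,end_s`` CSV of seizure intervals."""
    out: dict[tuple[str, str], list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["subject_id"], row["record_id"])
            out.setdefault(key, []).append((float(row["start_s"]), float(row["end_s"])))
    return out


def highpass_filter(
    segment: EEGSegment, order: int = 48, cutoff: float = 0.5
) -> EEGSegment:
    """Causal linear-phase FIR high-pass (Hamming window) of the given order.

    The default 48th-order, 0.5 Hz filter removes drift and DC while leaving
    the EEG rhythms essentially untouched. Filtering is single-pass causal,
    so the output carries the filter's constant group delay.
    """
    if order <= 0 or order % 2:
        raise ValueError("order must be a positive even integer")
    nyquist = segment.sampling_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, Nyquist={nyquist})")
    taps = firwin(
        order + 1, cutoff, window="hamming", pass_zero=False, fs=segment.sampling_rate
    )
    filtered = lfilter(taps, 1.0, segment.samples)
    return replace(segment, samples=filtered)


def segment_record(record: EEGRecord, window_seconds: float = 20.0) -> list[EEGSegment]:
    """Cut a record into consecutive non-overlapping labeled windows.

    Window k covers [k*w, (k+1)*w) seconds on every channel. A window fully
    inside a seizure interval is labeled seizure; a window disjoint from all
    intervals is non-seizure; boundary-straddling windows and trailing
    partial windows are discarded.
    """
    n_window = window_seconds * record.sampling_rate
    if abs(n_window - round(n_window)) > 1e-9:
        raise ValueError("window_seconds x sampling_rate must be a whole sample count")
    n_window = int(round(n_window))
    segments: list[EEGSegment] = []
    n_total = record.samples.shape[1]
    for k in range(n_total // n_window):
        t0 = k * window_seconds
        t1 = t0 + window_seconds
        if any(s <= t0 and t1 <= e for s, e in record.seizure_intervals):
            label = SEIZURE
        elif all(t1 <= s or t0 >= e for s, e in record.seizure_intervals):
            label = NON_SEIZURE
        else:
            continue  # straddles an interval boundary
        for ch, name in enumerate(record.channel_labels):
            segments.append(
                EEGSegment(
                    record.subject_id,
                    name,
                    record.samples[ch, k * n_window : (k + 1) * n_window],
                    record.sampling_rate,
                    label,
                    origin_offset_s=t0,
                )
            )
    return segments


def balance_classes(segments: list[EEGSegment], seed: int = 0) -> list[EEGSegment]:
    """Equalize seizure / non-seizure counts within every subject.

    The majority class of each subject is down-sampled uniformly at random
    (seeded); subjects missing a class entirely are dropped with a warning.
    Output order is deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    by_subject: dict[str, list[int]] = {}
    for i, seg in enumerate(segments):
        by_subject.setdefault(seg.subject_id, []).append(i)
    keep: list[int] = []
    for subject in sorted(by_subject):
        idx = by_subject[subject]
        pos = [i for i in idx if segments[i].label == SEIZURE]
        neg = [i for i in idx if segments[i].label == NON_SEIZURE]
        if not pos or not neg:
            warnings.warn(
                f"subject {subject!r} lacks one class entirely; excluded from balancing"
            )
            continue
        n = min(len(pos), len(neg))
        for group in (pos, neg):
            if len(group) == n:
                keep.extend(group)
            else:
                chosen = sorted(rng.choice(len(group), size=n, replace=False))
                keep.extend(group[i] for i in chosen)
    return [segments[i] for i in sorted(keep)]


def segments_to_arrays(
    segments: list[EEGSegment],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack equal-length segments into (X, y, groups) for the estimators.

    y is 1 for seizure, 0 for non-seizure; groups carries subject ids.
    """
    if not segments:
        raise ValueError("no segments given")
    lengths = {s.n_samples for s in segments}
    if len(lengths) != 1:
        raise ValueError(f"segments have differing lengths: {sorted(lengths)}")
    X = np.stack([s.samples for s in segments])
    y = np.array([1 if s.label == SEIZURE else 0 for s in segments])
    groups = np.array([s.subject_id for s in segments])
    return X, y, groups


def segments_to_csv(segments: list[EEGSegment], path: str | Path) -> None:
    """Write segments as a wide CSV (metadata columns then s0..s{n-1})."""
    if not segments:
        raise ValueError("no segments to write")
    n = segments[0].n_samples
    header = ["subject_id", "channel", "label", "sampling_rate", "origin_offset_s"]
    header += [f"s{i}" for i in range(n)]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for s in segments:
            if s.n_samples != n:
                raise ValueError("segments have differing lengths")
            writer.writerow(
                [s.subject_id, s.channel, s.label, s.sampling_rate, s.origin_offset_s]
                + [repr(float(v)) for v in s.samples]
            )


def segments_from_csv(path: str | Path) -> list[EEGSegment]:
    """Inverse of :func:`segments_to_csv`."""
    segments = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        n_meta = 5
        for row in reader:
            segments.append(
                EEGSegment(
                    subject_id=row[0],
                    channel=row[1],
                    label=row[2],
                    samples=np.array([float(v) for v in row[n_meta:]]),
                    sampling_rate=float(row[3]),
                    origin_offset_s=float(row[4]),
                )
            )
    if not segments:
        raise ValueError(f"{path}: no segments found")
    return segments


def seizure_hours(n_balanced_segments: int, window_seconds: float = 20.0) -> float:
    """Hours of seizure EEG in a balanced segment collection, to 2 decimals.

    Half of a balanced collection is seizure; e.g. 13,846 balanced 20 s
    segments contain 38.46 h of seizure EEG.
    """
    return round(n_balanced_segments / 2 * window_seconds / 3600.0, 2)


def _edf_text(value: str, width: int) -> bytes:
    text = value[:width].ljust(width)
    return text.encode("ascii")


def write_edf(
    path: str | Path,
    samples: np.ndarray,
    sampling_rate: float,
    channel_labels: list[str],
    subject_id: str = "X",
) -> None:
    """Write a minimal 16-bit EDF file (one data record per second).

    Covers the standard-header subset that EDF readers require; the sampling
    rate must be a whole number of samples per second and the duration a
    whole number of seconds.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n_ch, n_samp = samples.shape
    fs = sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("write_edf requires an integer sampling rate")
    fs = int(round(fs))
    if n_samp % fs:
        raise ValueError("write_edf requires a whole number of seconds of data")
    n_records = n_samp // fs
    pmins = samples.min(axis=1)
    pmaxs = samples.max(axis=1)
    span = np.where(pmaxs > pmins, pmaxs - pmins, 1.0)
    pmins = np.where(pmaxs > pmins, pmins, pmins - 0.5)
    pmaxs = pmins + span
    digital = np.round(
        (samples - pmins[:, None]) / span[:, None] * 65535 - 32768
    ).astype("<i2")

    header = b""
    header += _edf_text("0", 8)
    header += _edf_text(subject_id, 80)
    header += _edf_text("synthetic recording", 80)
    header += _edf_text("01.01.00", 8)
    header += _edf_text("00.00.00", 8)
    header += _edf_text(str(256 * (1 + n_ch)), 8)
    header += _edf_text("", 44)
    header += _edf_text(str(n_records), 8)
    header += _edf_text("1", 8)
    header += _edf_text(str(n_ch), 4)
    header += b"".join(_edf_text(lbl, 16) for lbl in channel_labels)
    header += b"".join(_edf_text("EEG", 80) for _ in range(n_ch))
    header += b"".join(_edf_text("uV", 8) for _ in range(n_ch))
    header += b"".join(_edf_text(f"{v:.3f}"[:8], 8) for v in pmins)
    header += b"".join(_edf_text(f"{v:.3f}"[:8], 8) for v in pmaxs)
    header += b"".join(_edf_text("-32768", 8) for _ in range(n_ch))
    header += b"".join(_edf_text("32767", 8) for _ in range(n_ch))
    header += b"".join(_edf_text("", 80) for _ in range(n_ch))
    header += b"".join(_edf_text(str(fs), 8) for _ in range(n_ch))
    header += b"".join(_edf_text("", 32) for _ in range(n_ch))
    assert len(header) == 256 * (1 + n_ch)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for ch in range(n_ch):
                fh.write(digital[ch, r * fs : (r + 1) * fs].tobytes())
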