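"""EEG record I/O, preprocessing and window labeling.

Records are multi-channel time series in microvolts with seizure-interval
annotations in seconds from record start.  Preprocessing follows common
scalp-EEG practice: polyphase anti-aliased downsampling and a zero-phase
4th-order Butterworth band-pass (default 0–75 Hz, i.e. a low-pass, since a
0 Hz low edge omits the high-pass stage).

Analysis windows are cut non-overlapping and labeled *preictal* when fully
inside the horizon before a seizure onset, discarded when they touch the
seizure itself (ictal) or the post-seizure guard period, and labeled
*interictal* otherwise.  Time intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal

from . import _edf
from .errors import FormatError, ParameterError

PREICTAL = "preictal"
INTERICTAL = "interictal"

#: Default horizon: the preictal state is taken to begin 60 minutes before
#: seizure onset (the conservative end of the reported 60–90 min range).
DEFAULT_PREICTAL_HORIZON_S = 3600.0
#: Default guard period after seizure offset, excluded to avoid postictal
#: contamination of the interictal class.
DEFAULT_GUARD_S = 1800.0


@dataclass(frozen=True)
class SeizureInterval:
    """One annotated seizure, seconds from record start, half-open."""

    onset_s: float
    offset_s: float

    def __post_init__(self):
        if not 0 <= self.onset_s < self.offset_s:
            raise ParameterError(
                f"invalid seizure interval [{self.onset_s}, {self.offset_s})"
            )


@dataclass
class EEGRecord:
    """Multi-channel EEG time series with seizure annotations."""

    channel_names: list[str]
    sampling_rate_hz: float
    samples: np.ndarray  # channels x time, microvolts
    annotations: list[SeizureInterval] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self):
        try:
            self.samples = np.asarray(self.samples, dtype=float)
        except ValueError as exc:
            raise ParameterError(f"ragged or non-numeric samples: {exc}") from exc
        if self.samples.ndim != 2:
            raise ParameterError("samples must be a 2-D channels x time array")
        if self.samples.shape[0] == 0:
            raise ParameterError("record has zero channels")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ParameterError("channel_names length must match channel count")
        if not self.sampling_rate_hz > 0:
            raise ParameterError("sampling_rate_hz must be positive")
        for ann in self.annotations:
            if ann.offset_s > self.duration_s + 1e-9:
                raise ParameterError(
                    f"annotation [{ann.onset_s}, {ann.offset_s}) exceeds the "
                    f"record duration {self.duration_s:.3f} s"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class Segment:
    """One labeled analysis window cut from a record."""

    samples: np.ndarray  # channels x window
    label: str
    start_s: float
    source_id: str
    sampling_rate_hz: float

    def __post_init__(self):
        if self.label not in (PREICTAL, INTERICTAL):
            raise ParameterError(f"label must be preictal/interictal, got {self.label!r}")


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(".annotations.csv")


def read_annotations_csv(path, source_id: str | None = None) -> list[SeizureInterval]:
    """Read a sidecar annotation CSV with header ``source_id,onset_s,offset_s``."""
    intervals = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"source_id", "onset_s", "offset_s"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(
                f"{path}: annotation CSV must have header source_id,onset_s,offset_s"
            )
        for row in reader:
            if source_id is not None and row["source_id"] != source_id:
                continue
            intervals.append(
                SeizureInterval(float(row["onset_s"]), float(row["offset_s"]))
            )
    return sorted(intervals, key=lambda iv: iv.onset_s)


def write_annotations_csv(path, records: list[EEGRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_id", "onset_s", "offset_s"])
        for rec in records:
            for iv in rec.annotations:
                writer.writerow([rec.source_id, repr(iv.onset_s), repr(iv.offset_s)])


def read_edf(path, annotations_path=None) -> EEGRecord:
    """Read an EDF file (plus optional sidecar annotation CSV) into a record.

    When ``annotations_path`` is omitted, a sidecar named
    ``<stem>.annotations.csv`` next to the EDF is used if present.
    """
    samples, rate, labels = _edf.read_edf(path)
    source_id = Path(path).stem
    if annotations_path is None:
        candidate = _sidecar_path(path)
        annotations_path = candidate if candidate.exists() else None
    annotations = []
    if annotations_path is not None:
        annotations = read_annotations_csv(annotations_path, source_id=source_id)
    return EEGRecord(
        channel_names=labels,
        sampling_rate_hz=rate,
        samples=samples,
        annotations=annotations,
        source_id=source_id,
    )


def write_edf(record: EEGRecord, path, write_annotations: bool = True) -> None:
    """Write a record as EDF; annotations go to a sidecar CSV next to it."""
    _edf.write_edf(
        path, record.samples, record.sampling_rate_hz, record.channel_names
    )
    if write_annotations and record.annotations:
        # the sidecar identifies rows by the EDF file stem so that read_edf
        # can match them back regardless of the in-memory source_id
        rec = EEGRecord(
            record.channel_names,
            record.sampling_rate_hz,
            record.samples,
            record.annotations,
            source_id=Path(path).stem,
        )
        write_annotations_csv(_sidecar_path(path), [rec])


def downsample(record: EEGRecord, target_hz: float) -> EEGRecord:
    """Resample to ``target_hz`` with polyphase anti-alias filtering."""
    if target_hz <= 0:
        raise ParameterError("target_hz must be positive")
    if target_hz > record.sampling_rate_hz:
        raise ParameterError(
            f"target rate {target_hz} Hz exceeds source rate "
            f"{record.sampling_rate_hz} Hz"
        )
    if target_hz == record.sampling_rate_hz:
        return EEGRecord(
            list(record.channel_names),
            record.sampling_rate_hz,
            record.samples.copy(),
            list(record.annotations),
            record.source_id,
        )
    ratio = Fraction(target_hz / record.sampling_rate_hz).limit_denominator(1000)
    out = signal.resample_poly(record.samples, ratio.numerator, ratio.denominator, axis=1)
    return EEGRecord(
        list(record.channel_names),
        target_hz,
        out,
        list(record.annotations),
        record.source_id,
    )


def _design_bandpass(low_hz: float, high_hz: float, fs: float, order: int = 4):
    nyq = fs / 2.0
    if high_hz >= nyq:
        raise ParameterError(f"high edge {high_hz} Hz must be below Nyquist {nyq} Hz")
    if low_hz < 0 or low_hz >= high_hz:
        raise ParameterError(f"invalid band ({low_hz}, {high_hz}) Hz")
    if low_hz == 0:
        return signal.butter(order, high_hz, btype="lowpass", fs=fs, output="sos")
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    samples: np.ndarray, fs: float, low_hz: float, high_hz: float, order: int = 4
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass on the last axis."""
    sos = _design_bandpass(low_hz, high_hz, fs, order)
    return signal.sosfiltfilt(sos, samples, axis=-1)


def bandpass_preprocess(
    record: EEGRecord, low_hz: float = 0.0, high_hz: float = 75.0
) -> EEGRecord:
    """Band-limit a record to ``[low_hz, high_hz]`` (default 0–75 Hz)."""
    filtered = bandpass_filter(record.samples, record.sampling_rate_hz, low_hz, high_hz)
    return EEGRecord(
        list(record.channel_names),
        record.sampling_rate_hz,
        filtered,
        list(record.annotations),
        record.source_id,
    )


def segment_and_label(
    record: EEGRecord,
    window_s: float = 4.0,
    preictal_horizon_s: float = DEFAULT_PREICTAL_HORIZON_S,
    guard_s: float = DEFAULT_GUARD_S,
) -> list[Segment]:
    """Cut non-overlapping windows and label them preictal/interictal.

    A window is *preictal* iff it lies fully inside
    ``[onset - preictal_horizon_s, onset)`` of some seizure; windows
    overlapping a seizure ``[onset, offset)`` or the guard period
    ``[offset, offset + guard_s)`` are discarded; every remaining window
    is *interictal*.
    """
    if window_s <= 0:
        raise ParameterError("window_s must be positive")
    if preictal_horizon_s <= 0:
        raise ParameterError("preictal_horizon_s must be positive")
    if guard_s < 0:
        raise ParameterError("guard_s must be non-negative")
    n_window = window_s * record.sampling_rate_hz
    if abs(n_window - round(n_window)) > 1e-9:
        raise ParameterError(
            f"window_s x sampling rate = {n_window} is not an integer sample count"
        )
    n_window = int(round(n_window))
    if n_window > record.n_samples:
        raise ParameterError(
            f"window of {window_s} s exceeds the record duration "
            f"{record.duration_s:.3f} s"
        )

    def overlaps(a0, a1, b0, b1):
        return a0 < b1 and b0 < a1

    segments = []
    n_windows = record.n_samples // n_window
    for w in range(n_windows):
        start = w * n_window
        t0 = start / record.sampling_rate_hz
        t1 = (start + n_window) / record.sampling_rate_hz
        discard = False
        label = INTERICTAL
        for iv in record.annotations:
            if overlaps(t0, t1, iv.onset_s, iv.offset_s):
                discard = True
                break
            if guard_s > 0 and overlaps(t0, t1, iv.offset_s, iv.offset_s + guard_s):
                discard = True
                break
            pre0 = iv.onset_s - preictal_horizon_s
            if pre0 <= t0 and t1 <= iv.onset_s:
                label = PREICTAL
        if discard:
            continue
        segments.append(
            Segment(
                samples=record.samples[:, start : start + n_window].copy(),
                label=label,
                start_s=t0,
                source_id=record.source_id,
                sampling_rate_hz=record.sampling_rate_hz,
            )
        )
    return segments
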