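"""Minimal EDF (European Data Format) codec.

Supports plain continuous EDF files with a uniform sampling rate across
channels and 16-bit samples — sufficient for scalp-EEG recordings of the
kind this package consumes.  Physical calibration values are written in
the 8-character ASCII header fields and the same *printed* values are used
to quantize the samples, so a write → read round trip is exact up to the
16-bit quantization step.

Not supported: EDF+ discontinuous records, per-channel sampling rates,
TAL annotation channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import FormatError, ParameterError

DIG_MIN = -32768
DIG_MAX = 32767


@dataclass
class _SignalHeader:
    label: str
    physical_min: float
    physical_max: float
    samples_per_record: int

    @property
    def gain(self) -> float:
        return (self.physical_max - self.physical_min) / (DIG_MAX - DIG_MIN)


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"header field {s!r} exceeds {width} ASCII chars")
    return s.ljust(width).encode("ascii")


def _format_physical(value: float) -> float:
    """Round a calibration value so it fits 8 ASCII chars, and return the
    value actually printed (used for quantization so round trips agree)."""
    for fmt in ("%.8g", "%.7g", "%.6g", "%.5g", "%.4g", "%.3g"):
        s = fmt % value
        if len(s) <= 8:
            return float(s)
    raise FormatError(f"cannot represent physical value {value} in 8 chars")


def write_edf(
    path,
    samples: np.ndarray,
    sampling_rate_hz: float,
    channel_names: list[str],
    physical_dimension: str = "uV",
) -> None:
    """Write a channels x time float array as a 16-bit EDF file."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] == 0:
        raise ParameterError("samples must be a non-empty channels x time array")
    n_channels, n_samples = samples.shape
    if len(channel_names) != n_channels:
        raise ParameterError("channel_names length must match channel count")

    # Prefer 1-second data records; fall back to a single record holding the
    # whole signal when the length is not a whole number of seconds.
    spr = int(round(sampling_rate_hz))
    if spr > 0 and abs(spr - sampling_rate_hz) < 1e-9 and n_samples % spr == 0:
        n_records = n_samples // spr
        record_duration = 1.0
    else:
        spr = n_samples
        n_records = 1
        record_duration = n_samples / sampling_rate_hz

    headers = []
    digital = np.empty_like(samples, dtype=np.int16)
    for ch in range(n_channels):
        x = samples[ch]
        pmin = _format_physical(float(np.min(x)))
        pmax = _format_physical(float(np.max(x)))
        if pmax <= pmin:
            pmax = _format_physical(pmin + 1.0)
        hdr = _SignalHeader(channel_names[ch], pmin, pmax, spr)
        headers.append(hdr)
        dig = np.round((x - pmin) / hdr.gain) + DIG_MIN
        digital[ch] = np.clip(dig, DIG_MIN, DIG_MAX).astype(np.int16)

    dur = record_duration
    dur_s = ("%d" % dur) if float(dur).is_integer() else ("%.6f" % dur).rstrip("0")
    if len(dur_s) > 8:
        raise FormatError("record duration does not fit the EDF header field")

    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii("X X X X", 80))                    # patient id
        fh.write(_ascii("Startdate X X X X", 80))          # recording id
        fh.write(_ascii("01.01.00", 8))                    # start date (fixed)
        fh.write(_ascii("00.00.00", 8))                    # start time (fixed)
        fh.write(_ascii(256 * (n_channels + 1), 8))
        fh.write(_ascii("", 44))
        fh.write(_ascii(n_records, 8))
        fh.write(_ascii(dur_s, 8))
        fh.write(_ascii(n_channels, 4))
        for h in headers:
            fh.write(_ascii(h.label[:16], 16))
        for _ in headers:
            fh.write(_ascii("", 80))                       # transducer
        for _ in headers:
            fh.write(_ascii(physical_dimension, 8))
        for h in headers:
            fh.write(_ascii("%.8g" % h.physical_min, 8))
        for h in headers:
            fh.write(_ascii("%.8g" % h.physical_max, 8))
        for _ in headers:
            fh.write(_ascii(DIG_MIN, 8))
        for _ in headers:
            fh.write(_ascii(DIG_MAX, 8))
        for _ in headers:
            fh.write(_ascii("", 80))                       # prefiltering
        for h in headers:
            fh.write(_ascii(h.samples_per_record, 8))
        for _ in headers:
            fh.write(_ascii("", 32))
        for rec in range(n_records):
            sl = slice(rec * spr, (rec + 1) * spr)
            for ch in range(n_channels):
                fh.write(digital[ch, sl].tobytes())


def _field(buf: bytes, offset: int, width: int) -> str:
    return buf[offset : offset + width].decode("ascii", errors="replace").strip()


def _parse_float(text: str, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise FormatError(f"unparseable {what} field: {text!r}") from None


def _parse_int(text: str, what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise FormatError(f"unparseable {what} field: {text!r}") from None


def read_edf(path):
    """Read an EDF file.

    Returns ``(samples, sampling_rate_hz, channel_names)`` with samples as
    a channels x time float array in physical units.
    """
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        version = _field(header, 0, 8)
        if version not in ("0", "0\x00".strip()):
            raise FormatError(f"{path}: not an EDF file (version field {version!r})")
        n_records = _parse_int(_field(header, 236, 8), "number of records")
        record_duration = _parse_float(_field(header, 244, 8), "record duration")
        n_channels = _parse_int(_field(header, 252, 4), "channel count")
        if n_channels <= 0:
            raise FormatError(f"{path}: EDF file declares {n_channels} channels")
        if n_records < 0 or record_duration <= 0:
            raise FormatError(f"{path}: invalid record geometry")

        sig = fh.read(256 * n_channels)
        if len(sig) < 256 * n_channels:
            raise FormatError(f"{path}: truncated signal headers")

        def column(offset: int, width: int) -> list[str]:
            base = offset * n_channels
            return [
                _field(sig, base + i * width, width) for i in range(n_channels)
            ]

        # cumulative per-field offsets: label 0, transducer 16, dim 96,
        # pmin 104, pmax 112, dmin 120, dmax 128, prefilter 136, spr 216
        labels = column(0, 16)
        pmins = [_parse_float(v, "physical minimum") for v in column(104, 8)]
        pmaxs = [_parse_float(v, "physical maximum") for v in column(112, 8)]
        dmins = [_parse_int(v, "digital minimum") for v in column(120, 8)]
        dmaxs = [_parse_int(v, "digital maximum") for v in column(128, 8)]
        sprs = [_parse_int(v, "samples per record") for v in column(216, 8)]
        if len(set(sprs)) != 1:
            raise FormatError(f"{path}: per-channel sampling rates not supported")
        spr = sprs[0]
        if spr <= 0:
            raise FormatError(f"{path}: invalid samples-per-record {spr}")

        raw = np.fromfile(fh, dtype="<i2")

    expected = n_records * n_channels * spr
    if raw.size < expected:
        raise FormatError(f"{path}: data section truncated")
    raw = raw[:expected].reshape(n_records, n_channels, spr)
    samples = np.empty((n_channels, n_records * spr), dtype=float)
    for ch in range(n_channels):
        dmin, dmax = dmins[ch], dmaxs[ch]
        if dmax <= dmin:
            raise FormatError(f"{path}: invalid digital range on channel {ch}")
        gain = (pmaxs[ch] - pmins[ch]) / (dmax - dmin)
        dig = raw[:, ch, :].reshape(-1).astype(float)
        samples[ch] = (dig - dmin) * gain + pmins[ch]
    sampling_rate_hz = spr / record_duration
    if not math.isfinite(sampling_rate_hz) or sampling_rate_hz <= 0:
        raise FormatError(f"{path}: invalid sampling rate")
    return samples, sampling_rate_hz, labels
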