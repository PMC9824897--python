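"""Seeded synthetic EEG records and tabular feature datasets.

The record generator builds a signal with the canonical scalp-EEG rhythm
structure: one band-limited sinusoidal component per frequency band
(delta through gamma, amplitudes falling with frequency) on top of 1/f^beta
Gaussian background noise.  Inside the preictal horizon before each
configured seizure the slow (delta/theta) components are amplified by
``preictal_delta_gain`` and 3 Hz spike-wave bursts are injected, so
downstream band-energy features carry a known class signal.  Everything is
a pure function of (config, seed).

The tabular generator plants ``n_informative`` mean-shifted Gaussian
columns among standard-normal noise columns and returns the ground-truth
informative index set, enabling feature-selection recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .io_preprocess import EEGRecord, SeizureInterval

# Per-band carrier frequency (Hz) and resting amplitude (microvolts).
_BAND_COMPONENTS = {
    "delta": (2.0, 20.0),
    "theta": (6.0, 10.0),
    "alpha": (10.5, 8.0),
    "beta": (17.5, 4.0),
    "gamma": (26.0, 2.0),
}
_SLOW_BANDS = ("delta", "theta")


@dataclass
class SynthRecordConfig:
    sampling_rate_hz: float = 256.0
    duration_s: float = 600.0
    n_channels: int = 4
    seizure_times: list[tuple[float, float]] = field(default_factory=list)
    preictal_horizon_s: float = 600.0
    preictal_delta_gain: float = 3.0
    spike_burst_rate_hz: float = 3.0
    noise_exponent: float = 1.0
    noise_sd_uv: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        if self.sampling_rate_hz <= 0:
            raise ParameterError("sampling_rate_hz must be positive")
        if self.n_channels < 1:
            raise ParameterError("n_channels must be >= 1")
        if self.preictal_delta_gain < 1:
            raise ParameterError("preictal_delta_gain must be >= 1")
        last_end = -np.inf
        for onset, offset in sorted(self.seizure_times):
            if not 0 <= onset < offset <= self.duration_s:
                raise ParameterError(
                    f"seizure ({onset}, {offset}) outside [0, {self.duration_s}]"
                )
            if onset < last_end:
                raise ParameterError("seizure intervals must be disjoint")
            last_end = offset


@dataclass
class SynthFeatureConfig:
    n_samples: int = 400
    n_features: int = 40
    n_informative: int = 5
    effect_size: float = 3.0
    class_balance: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ParameterError("n_samples must be >= 4")
        if not 0 < self.n_informative <= self.n_features:
            raise ParameterError("need 0 < n_informative <= n_features")
        if not 0 < self.class_balance < 1:
            raise ParameterError("class_balance must lie in (0, 1)")


def _one_over_f_noise(rng: np.random.Generator, n: int, beta: float, fs: float) -> np.ndarray:
    """Gaussian noise with a 1/f^beta amplitude spectrum, unit variance."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-beta / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spectrum * scale, n=n)
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _burst_envelope(
    rng: np.random.Generator, t: np.ndarray, span: tuple[float, float]
) -> np.ndarray:
    """0/1 envelope of 1-2 s bursts covering roughly half of a time span."""
    env = np.zeros_like(t)
    pos = span[0]
    while pos < span[1]:
        burst_len = rng.uniform(1.0, 2.0)
        gap = rng.uniform(1.0, 2.0)
        end = min(pos + burst_len, span[1])
        env[(t >= pos) & (t < end)] = 1.0
        pos = end + gap
    return env


def generate_record(config: SynthRecordConfig) -> EEGRecord:
    """Generate a synthetic EEG record with planted preictal structure."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate_hz
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    preictal_spans = [
        (max(0.0, onset - config.preictal_horizon_s), onset)
        for onset, _ in config.seizure_times
    ]
    burst_spans = preictal_spans + [tuple(iv) for iv in config.seizure_times]

    # Slow-rhythm gain profile: preictal_delta_gain inside each horizon.
    slow_gain = np.ones(n)
    for lo, hi in preictal_spans:
        slow_gain[(t >= lo) & (t < hi)] = config.preictal_delta_gain

    samples = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        x = np.zeros(n)
        for band, (freq, amp) in _BAND_COMPONENTS.items():
            phase = rng.uniform(0, 2 * np.pi)
            component = amp * np.sin(2 * np.pi * freq * t + phase)
            if band in _SLOW_BANDS:
                component = component * slow_gain
            x += component
        x += config.noise_sd_uv * _one_over_f_noise(rng, n, config.noise_exponent, fs)
        for span in burst_spans:
            env = _burst_envelope(rng, t, span)
            phase = rng.uniform(0, 2 * np.pi)
            spikes = sps.sawtooth(
                2 * np.pi * config.spike_burst_rate_hz * t + phase, width=0.15
            )
            x += 3.0 * config.noise_sd_uv * env * spikes
        samples[ch] = x

    return EEGRecord(
        channel_names=[f"SYN{ch:02d}" for ch in range(config.n_channels)],
        sampling_rate_hz=fs,
        samples=samples,
        annotations=[SeizureInterval(a, b) for a, b in config.seizure_times],
        source_id=f"synthetic-{config.seed}",
    )


def record_suite(
    seed: int = 0,
    n_records: int = 2,
    duration_s: float = 1200.0,
    preictal_delta_gain: float = 3.0,
) -> list[SynthRecordConfig]:
    """Canonical synthetic study conditions for pipeline evaluation.

    Each 20-minute, 4-channel, 256 Hz record carries one seizure at
    [900, 960) s with a 300 s preictal horizon, so 4 s windows yield 75
    preictal and ~195 interictal segments per record (60 s guard).
    """
    onset = 0.75 * duration_s
    return [
        SynthRecordConfig(
            duration_s=duration_s,
            n_channels=4,
            seizure_times=[(onset, onset + 60.0)],
            preictal_horizon_s=300.0,
            preictal_delta_gain=preictal_delta_gain,
            seed=seed * 1009 + i,
        )
        for i in range(n_records)
    ]


def generate_feature_dataset(
    config: SynthFeatureConfig,
) -> tuple[np.ndarray, np.ndarray, set[int]]:
    """Generate (X, y, informative_indices) with planted mean shifts.

    Informative columns differ between classes by ``effect_size``
    within-class standard deviations; the remaining columns are
    class-independent standard normal noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, d, k = config.n_samples, config.n_features, config.n_informative
    n_pos = int(round(config.class_balance * n))
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)
    X = rng.standard_normal((n, d))
    informative = set(
        int(i) for i in rng.choice(d, size=k, replace=False)
    )
    shift = config.effect_size
    for j in informative:
        X[y == 1, j] += shift / 2.0
        X[y == 0, j] -= shift / 2.0
    return X, y, informative
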