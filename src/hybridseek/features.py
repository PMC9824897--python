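"""Per-band, per-channel feature extraction.

Eight features are computed for every (band, channel) pair:

===== =======================================================
name  definition
===== =======================================================
FMN   sample mean
FVR   sample variance (1/(q-1) normalization)
FSDN  sample standard deviation, d = sqrt(FVR)
FSKW  sum((x-mean)^3) / (q d^3)
FKRT  sum((x-mean)^4) / (q d^4)
FWEY  total relative detail energy of the wavelet decomposition
      (1 minus the approximation band's relative energy)
FWEN  Shannon entropy (bits) of the relative sub-band energies
FHEN  Shannon entropy (bits) of the amplitude histogram
===== =======================================================

Skewness and kurtosis use the *population* count q in the denominator but
the *sample* standard deviation d, matching the package's stated moment
conventions exactly; a two-pass brute-force evaluation is the reference.
Degenerate inputs (constant signal, zero energy) yield 0 with a logged
warning instead of raising, so batch extraction never aborts mid-record.
All logs are base 2 (entropies in bits).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pywt

from .bands import BandSignals
from .errors import ParameterError

logger = logging.getLogger(__name__)

FEATURE_ORDER = ("FMN", "FVR", "FSDN", "FSKW", "FKRT", "FWEY", "FWEN", "FHEN")

DEFAULT_N_BINS = 16


@dataclass(frozen=True)
class WaveletConfig:
    """Discrete wavelet transform settings.

    Defaults: Daubechies-4 at level 5, so for a 256 Hz signal the deepest
    approximation band covers 0-4 Hz.
    """

    wavelet: str = "db4"
    level: int = 5

    def __post_init__(self):
        if self.level < 1:
            raise ParameterError("decomposition level must be >= 1")
        try:
            pywt.Wavelet(self.wavelet)
        except ValueError as exc:
            raise ParameterError(f"unknown wavelet {self.wavelet!r}") from exc


@dataclass
class FeatureVector:
    """Ordered (name, value) pairs, band-major then channel then feature."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ParameterError("names and values must have equal length")

    def __len__(self) -> int:
        return len(self.names)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def statistical_features(x) -> tuple[float, float, float, float, float]:
    """Mean, variance, standard deviation, skewness and kurtosis.

    Constant input (d = 0) returns skewness = kurtosis = 0 by convention.
    """
    x = np.asarray(x, dtype=float).ravel()
    q = len(x)
    if q < 2:
        raise ParameterError("statistical features need at least 2 samples")
    fmn = float(np.mean(x))
    dev = x - fmn
    fvr = float(np.sum(dev**2) / (q - 1))
    fsdn = math.sqrt(fvr)
    if fsdn == 0.0:
        logger.warning("constant input: skewness and kurtosis set to 0")
        return fmn, fvr, fsdn, 0.0, 0.0
    fskw = float(np.sum(dev**3) / (q * fsdn**3))
    fkrt = float(np.sum(dev**4) / (q * fsdn**4))
    return fmn, fvr, fsdn, fskw, fkrt


def wavelet_features(x, cfg: WaveletConfig = WaveletConfig()) -> tuple[np.ndarray, float]:
    """Relative sub-band energies and their Shannon entropy (bits).

    Returns ``(fwey, fwen)`` where ``fwey`` holds one relative energy per
    sub-band ordered [approximation, detail_level, ..., detail_1] and
    ``fwen`` is the entropy of that distribution.  Zero-energy input
    yields all zeros by convention.
    """
    x = np.asarray(x, dtype=float).ravel()
    max_level = pywt.dwt_max_level(len(x), pywt.Wavelet(cfg.wavelet).dec_len)
    if cfg.level > max_level:
        raise ParameterError(
            f"signal of length {len(x)} supports at most level {max_level} "
            f"for wavelet {cfg.wavelet}, requested {cfg.level}"
        )
    coeffs = pywt.wavedec(x, cfg.wavelet, level=cfg.level)
    energies = np.array([float(np.sum(np.abs(c) ** 2)) for c in coeffs])
    total = energies.sum()
    if total == 0.0:
        logger.warning("zero-energy input: wavelet features set to 0")
        return np.zeros(len(energies)), 0.0
    rel = energies / total
    nonzero = rel[rel > 0]
    fwen = float(-np.sum(nonzero * np.log2(nonzero)))
    return rel, fwen


def entropy_feature(x, n_bins: int = DEFAULT_N_BINS) -> float:
    """Shannon entropy (bits) of the equal-width amplitude histogram."""
    x = np.asarray(x, dtype=float).ravel()
    if len(x) == 0:
        raise ParameterError("entropy_feature requires non-empty input")
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    probs = counts[counts > 0] / len(x)
    return float(-np.sum(probs * np.log2(probs)))


def extract_features(
    band_signals: BandSignals,
    cfg: WaveletConfig = WaveletConfig(),
    n_bins: int = DEFAULT_N_BINS,
) -> FeatureVector:
    """Eight features for every (band, channel), deterministically ordered.

    The per-sub-band relative wavelet energies are summarized as one
    scalar FWEY = total relative *detail* energy (1 minus the
    approximation band's share).
    """
    names: list[str] = []
    values: list[float] = []
    for band_name in band_signals.band_names:
        array = band_signals[band_name]
        for ch in range(array.shape[0]):
            x = array[ch]
            fmn, fvr, fsdn, fskw, fkrt = statistical_features(x)
            rel, fwen = wavelet_features(x, cfg)
            fwey = float(1.0 - rel[0]) if rel.sum() > 0 else 0.0
            fhen = entropy_feature(x, n_bins)
            for feat, value in zip(
                FEATURE_ORDER, (fmn, fvr, fsdn, fskw, fkrt, fwey, fwen, fhen)
            ):
                names.append(f"{band_name}.ch{ch}.{feat}")
                values.append(value)
    vec = FeatureVector(names=names, values=np.asarray(values))
    if not np.all(np.isfinite(vec.values)):
        bad = [n for n, v in zip(vec.names, vec.values) if not np.isfinite(v)]
        raise ParameterError(f"non-finite feature values: {bad}")
    return vec
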