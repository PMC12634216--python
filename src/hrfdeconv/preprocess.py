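"""Deconvolution-oriented preprocessing and signal-property metrics.

Minimal preprocessing: optical-density conversion, first-order polynomial
detrend and baseline (mean) correction — deliberately *not* a band-pass
filter, whose dephasing would distort frequencies the HRF bleeds into.
Metrics: a PSD-band signal-to-noise ratio with the hemodynamic band fixed at
0.01–0.2 Hz (channels below SNR 5.0 are flagged for exclusion), and
moment-based skewness / excess kurtosis (both 0 for a Gaussian), used to
check that deconvolved activity is sparser/heavier-tailed than the convolved
hemoglobin it came from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
import scipy.signal
import scipy.stats

from .errors import ShortSignalWarning, UndefinedMomentsError, ValidationError

__all__ = [
    "BandDefinition",
    "od_from_intensity",
    "detrend_baseline",
    "psd_snr",
    "moment_stats",
]


@dataclass
class BandDefinition:
    """Hemodynamic signal band (Hz) and the PSD-SNR exclusion threshold."""

    low_hz: float = 0.01
    high_hz: float = 0.2
    exclusion_threshold: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValidationError(
                f"band must satisfy 0 < low < high, got [{self.low_hz}, {self.high_hz}]"
            )


def od_from_intensity(raw, reference: float | None = None, base: str = "10") -> np.ndarray:
    """Optical density from raw light intensity: OD(t) = -log(raw(t) / reference).

    The reference defaults to the channel's temporal mean. Log base 10 by
    default; ``base="e"`` for the natural-log variant.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw <= 0) or not np.all(np.isfinite(raw)):
        raise ValidationError("raw intensity must be positive and finite")
    if reference is None:
        reference = float(raw.mean())
    if reference <= 0:
        raise ValidationError("reference intensity must be positive")
    log = np.log10 if base == "10" else np.log
    return -log(raw / reference)


def detrend_baseline(signal) -> np.ndarray:
    """Remove the least-squares first-order (linear) trend, then subtract the
    mean so the signal centres on zero, as the deconvolution model assumes."""
    signal = np.asarray(signal, dtype=float)
    if signal.size < 3:
        raise ValidationError("detrend needs at least 3 samples")
    out = scipy.signal.detrend(signal, type="linear")
    return out - out.mean()


def psd_snr(
    signal, sfreq: float, bands: BandDefinition | None = None
) -> Tuple[float, bool]:
    """Power-spectral-density band SNR.

    Welch PSD (segments of min(n, 2048) samples, 50% overlap); the ratio is
    total power inside [low, high] Hz over total power outside it, DC
    excluded. Returns ``(ratio, excluded)`` where the flag is set when the
    ratio falls below the exclusion threshold (default 5.0). A signal whose
    out-of-band power is exactly zero returns +inf with a warning.
    """
    bands = bands or BandDefinition()
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    if n < 2 * sfreq / bands.low_hz:
        warnings.warn(
            f"signal shorter than 2 cycles of {bands.low_hz} Hz; "
            "band powers may be unreliable",
            ShortSignalWarning,
        )
    nperseg = min(n, 2048)
    freqs, psd = scipy.signal.welch(
        signal, fs=sfreq, nperseg=nperseg, noverlap=nperseg // 2
    )
    nonzero = freqs > 0
    in_band = nonzero & (freqs >= bands.low_hz) & (freqs <= bands.high_hz)
    out_band = nonzero & ~in_band
    p_signal = float(psd[in_band].sum())
    p_noise = float(psd[out_band].sum())
    if p_noise == 0:
        warnings.warn("zero out-of-band power; SNR is infinite", ShortSignalWarning)
        return np.inf, False
    ratio = p_signal / p_noise
    return ratio, ratio < bands.exclusion_threshold


def moment_stats(signal) -> Tuple[float, float]:
    """Skewness and excess kurtosis from the third and fourth central sample
    moments (population convention): ``m3 / m2^1.5`` and ``m4 / m2² - 3``.

    Both are 0 for a Gaussian; positive excess kurtosis means a sharper peak
    and heavier tails (leptokurtic).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size < 4:
        raise ValidationError("moment statistics need at least 4 samples")
    if signal.var() == 0:
        raise UndefinedMomentsError("zero-variance signal has undefined moments")
    skew = float(scipy.stats.skew(signal, bias=True))
    kurt = float(scipy.stats.kurtosis(signal, fisher=True, bias=True))
    return skew, kurt
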