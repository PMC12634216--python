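"""Temporal resizing of HRF kernels via cubic-spline interpolation.

An HRF estimated at one montage's sampling rate is re-used on a recording at
another rate by fitting a natural cubic spline through the kernel samples
(knots at t = i / src_sfreq) and evaluating it on the destination grid
t = j / dst_sfreq. The duration is preserved; both grids follow the half-open
[0, duration) convention, so the last destination sample can fall slightly
beyond the last source knot — those points are clamped to the endpoint value
with a warning rather than extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ExtrapolationWarning, ValidationError
from .types import HRFEstimate, kernel_length

__all__ = ["ResampleRequest", "spline_resample", "resample_hrf"]


@dataclass
class ResampleRequest:
    kernel: np.ndarray
    src_sfreq: float
    dst_sfreq: float
    duration_s: float

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.src_sfreq <= 0 or self.dst_sfreq <= 0:
            raise ValidationError("sampling rates must be positive")
        expected = kernel_length(self.duration_s, self.src_sfreq)
        if self.kernel.size != expected:
            raise ValidationError(
                f"kernel length {self.kernel.size} != round(duration_s * src_sfreq) "
                f"= {expected}"
            )


def spline_resample(req: ResampleRequest) -> np.ndarray:
    """Natural cubic spline through the source samples, evaluated on the
    destination grid of length ``round(duration_s * dst_sfreq)``."""
    if req.kernel.size < 4:
        raise ValidationError("cubic spline needs at least 4 kernel samples")
    t_src = np.arange(req.kernel.size) / req.src_sfreq
    n_dst = kernel_length(req.duration_s, req.dst_sfreq)
    t_dst = np.arange(n_dst) / req.dst_sfreq
    spline = CubicSpline(t_src, req.kernel, bc_type="natural")
    beyond = t_dst > t_src[-1]
    if np.any(beyond):
        warnings.warn(
            f"{int(beyond.sum())} destination sample(s) beyond the source support "
            "clamped to the endpoint value",
            ExtrapolationWarning,
        )
        t_dst = np.minimum(t_dst, t_src[-1])
    return spline(t_dst)


def resample_hrf(h: HRFEstimate, dst_sfreq: float) -> HRFEstimate:
    """Resample an :class:`HRFEstimate` (and its spread, if present) to a new
    sampling rate; a no-op when the rates already agree."""
    if abs(dst_sfreq - h.sfreq) < 1e-12:
        return h
    req = ResampleRequest(
        kernel=h.kernel, src_sfreq=h.sfreq, dst_sfreq=dst_sfreq, duration_s=h.duration_s
    )
    kernel = spline_resample(req)
    spread = None
    if h.spread is not None:
        spread = spline_resample(
            ResampleRequest(
                kernel=h.spread, src_sfreq=h.sfreq,
                dst_sfreq=dst_sfreq, duration_s=h.duration_s,
            )
        )
    return HRFEstimate(
        kernel=kernel,
        duration_s=h.duration_s,
        sfreq=dst_sfreq,
        chromophore=h.chromophore,
        location=None if h.location is None else h.location.copy(),
        context=dict(h.context),
        spread=spread,
    )
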