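"""Canonical double-gamma HRF.

The universal fallback kernel used when no estimated HRF is available near a
queried optode: a gamma-density peak minus a scaled, later gamma-density
undershoot,

    h(t) = g(t; a1, b1) - c * g(t; a2, b2)

with g the gamma probability density (shape a, rate b). The defaults
(a1=6, b1=1, a2=16, b2=1, c=1/6) follow the widely used double-gamma
convention with a peak near 5 s and an undershoot about one sixth of the
peak; they are configurable and recorded in the estimate's context.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import gamma as gamma_dist

from .deconv import scale_hrf
from .errors import ValidationError
from .types import HRFEstimate, kernel_length

__all__ = ["DoubleGammaParams", "double_gamma_hrf"]


@dataclass
class DoubleGammaParams:
    """Shape/rate parameters of the two gamma components plus the undershoot
    ratio ``c`` (0 disables the undershoot)."""

    peak_shape: float = 6.0
    peak_rate: float = 1.0
    undershoot_shape: float = 16.0
    undershoot_rate: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration_s: float = 30.0
    sfreq: float = 10.0

    def __post_init__(self) -> None:
        for name in ("peak_shape", "peak_rate", "undershoot_shape", "undershoot_rate"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.undershoot_ratio < 0:
            raise ValidationError("undershoot_ratio must be >= 0")
        if self.duration_s <= 0 or self.sfreq <= 0:
            raise ValidationError("duration_s and sfreq must be positive")
        if kernel_length(self.duration_s, self.sfreq) < 4:
            raise ValidationError("duration_s * sfreq must be at least 4 samples")

    @property
    def peak_time_s(self) -> float:
        """Mode of the (un-differenced) peak gamma: (a1 - 1) / b1."""
        return (self.peak_shape - 1.0) / self.peak_rate


def double_gamma_hrf(
    p: DoubleGammaParams | None = None, chromophore: str = "hbo"
) -> HRFEstimate:
    """Sample the double-gamma kernel on [0, duration) and peak-scale it.

    The HbR variant is the negated kernel (negative-going), scaled so its
    trough magnitude is 1.
    """
    p = p or DoubleGammaParams()
    t = np.arange(kernel_length(p.duration_s, p.sfreq)) / p.sfreq
    kernel = gamma_dist.pdf(t, p.peak_shape, scale=1.0 / p.peak_rate)
    if p.undershoot_ratio > 0:
        kernel = kernel - p.undershoot_ratio * gamma_dist.pdf(
            t, p.undershoot_shape, scale=1.0 / p.undershoot_rate
        )
    if str(chromophore).lower() == "hbr":
        kernel = -kernel
    h = HRFEstimate(
        kernel=kernel,
        duration_s=p.duration_s,
        sfreq=p.sfreq,
        chromophore=chromophore,
        context={"model": "canonical-double-gamma", **{
            f"param_{k}": v for k, v in asdict(p).items()
            if k not in ("duration_s", "sfreq")
        }},
    )
    return scale_hrf(h)
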