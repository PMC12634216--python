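"""Core domain containers.

Everything downstream (deconvolution, the HRF store, the simulator) passes
these around. They are deliberately thin: numpy arrays plus the metadata that
must travel with them (sampling rate, chromophore, 3-D optode location,
experimental context).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ValidationError

#: Recognized chromophore labels (oxygenated / deoxygenated hemoglobin).
CHROMOPHORES = ("hbo", "hbr")


def _as_float_array(x, name: str, ndim: int = 1) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValidationError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class ChannelRecording:
    """One channel's hemoglobin (or optical-density) time series.

    Parameters
    ----------
    channel_id : str
        Montage channel label, e.g. ``"S1_D1 hbo"``.
    chromophore : {"hbo", "hbr"}
    sfreq : float
        Sampling rate in Hz, finite and positive.
    samples : array-like
        Time series, mol/L for hemoglobin (arbitrary units after the signal
        has been replaced by deconvolved neural activity).
    location : array-like of shape (3,)
        Optode location in millimetres.
    """

    channel_id: str
    chromophore: str
    sfreq: float
    samples: np.ndarray
    location: np.ndarray

    def __post_init__(self) -> None:
        self.chromophore = str(self.chromophore).lower()
        if self.chromophore not in CHROMOPHORES:
            raise ValidationError(
                f"chromophore must be one of {CHROMOPHORES}, got {self.chromophore!r}"
            )
        self.sfreq = float(self.sfreq)
        if not np.isfinite(self.sfreq) or self.sfreq <= 0:
            raise ValidationError(f"sfreq must be finite and positive, got {self.sfreq}")
        self.samples = _as_float_array(self.samples, "samples")
        if self.samples.size < 2:
            raise ValidationError("recording needs at least 2 samples")
        self.location = _as_float_array(self.location, "location")
        if self.location.shape != (3,) or not np.all(np.isfinite(self.location)):
            raise ValidationError("location must be a finite 3-vector (mm)")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    def replace_samples(self, samples: np.ndarray) -> "ChannelRecording":
        """Return a copy with new samples and identical metadata."""
        return ChannelRecording(
            channel_id=self.channel_id,
            chromophore=self.chromophore,
            sfreq=self.sfreq,
            samples=samples,
            location=self.location.copy(),
        )


@dataclass
class EventTrain:
    """Full-scan-length impulse series marking modeled neural events.

    Zero where no event; the impulse amplitude otherwise (weighted impulses
    are honoured; a duration-coded boxcar is a run of consecutive unit
    impulses).
    """

    impulses: np.ndarray
    sfreq: float

    def __post_init__(self) -> None:
        self.impulses = _as_float_array(self.impulses, "impulses")
        self.sfreq = float(self.sfreq)
        if self.sfreq <= 0 or not np.isfinite(self.sfreq):
            raise ValidationError(f"sfreq must be finite and positive, got {self.sfreq}")

    @classmethod
    def from_onsets(
        cls, onsets_s, n_samples: int, sfreq: float, amplitudes=None
    ) -> "EventTrain":
        """Build an impulse train from onsets in seconds.

        Onsets are mapped to samples by rounding to the nearest index
        (0-based). Onsets beyond the scan raise a validation error.
        """
        onsets_s = np.atleast_1d(np.asarray(onsets_s, dtype=float))
        if amplitudes is None:
            amplitudes = np.ones_like(onsets_s)
        amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
        if amplitudes.shape != onsets_s.shape:
            raise ValidationError("amplitudes must match onsets in length")
        impulses = np.zeros(int(n_samples))
        for t, a in zip(onsets_s, amplitudes):
            idx = int(round(t * sfreq))
            if idx < 0 or idx >= n_samples:
                raise ValidationError(
                    f"onset {t} s maps to sample {idx}, outside scan of {n_samples} samples"
                )
            impulses[idx] += a
        return cls(impulses=impulses, sfreq=sfreq)

    @property
    def n_samples(self) -> int:
        return self.impulses.size

    @property
    def onset_indices(self) -> np.ndarray:
        return np.flatnonzero(self.impulses)

    @property
    def n_events(self) -> int:
        return int(np.count_nonzero(self.impulses))


_REG_MATRICES = ("identity", "first_difference")


@dataclass
class DeconvConfig:
    """Tuning knobs for the regularized deconvolution.

    lam
        Tikhonov regularization weight λ ≥ 0; 1.0 by default (stable value
        that suppresses noise without flattening the latent kernel).
    reg_matrix
        ``"identity"`` (classical ridge, default) or ``"first_difference"``
        (penalizes roughness instead of amplitude).
    edge_fraction
        Edge-expansion proportion of the kernel duration added to each side
        before deconvolution and trimmed after; 0.25 by default.
    eps
        Small positive scalar added to the peak when scaling kernels; 1e-7.
    cond_threshold
        Channels whose regularized normal matrix exceeds this 2-norm
        condition number are dropped; 1e8.
    time_limit_s
        Cooperative per-channel wall-clock limit for a solve; 60 s.
    trim_prop
        Proportion trimmed per tail when pooling subject kernels; 0.1.
    """

    lam: float = 1.0
    reg_matrix: str = "identity"
    edge_fraction: float = 0.25
    eps: float = 1e-7
    cond_threshold: float = 1e8
    time_limit_s: float = 60.0
    trim_prop: float = 0.1

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValidationError(f"lam must be >= 0, got {self.lam}")
        if self.reg_matrix not in _REG_MATRICES:
            raise ValidationError(
                f"reg_matrix must be one of {_REG_MATRICES}, got {self.reg_matrix!r}"
            )
        if not (0 <= self.edge_fraction < 1):
            raise ValidationError(
                f"edge_fraction must be in [0, 1), got {self.edge_fraction}"
            )
        if self.eps <= 0:
            raise ValidationError(f"eps must be positive, got {self.eps}")
        if self.cond_threshold <= 0 or self.time_limit_s <= 0:
            raise ValidationError("cond_threshold and time_limit_s must be positive")
        if not (0 <= self.trim_prop < 0.5):
            raise ValidationError(f"trim_prop must be in [0, 0.5), got {self.trim_prop}")

    @classmethod
    def from_file(cls, path) -> "DeconvConfig":
        """Parse a ``key=value`` config file (blank lines and ``#`` comments
        ignored)."""
        kwargs = {}
        floats = {"lam", "edge_fraction", "eps", "cond_threshold", "time_limit_s", "trim_prop"}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key in floats:
                kwargs[key] = float(value)
            elif key == "reg_matrix":
                kwargs[key] = value
            else:
                raise ValidationError(f"{path}:{lineno}: unknown config key {key!r}")
        return cls(**kwargs)


def kernel_length(duration_s: float, sfreq: float) -> int:
    """Number of kernel samples for a duration at a sampling rate."""
    return int(round(duration_s * sfreq))


@dataclass
class HRFEstimate:
    """A fixed-duration HRF kernel with its provenance.

    The kernel is in arbitrary units; after :func:`~hrfdeconv.deconv.scale_hrf`
    its peak (or trough, for negative-going HbR kernels) has magnitude 1.
    """

    kernel: np.ndarray
    duration_s: float
    sfreq: float
    chromophore: str = "hbo"
    location: Optional[np.ndarray] = None
    context: dict = field(default_factory=dict)
    subject_kernels: Optional[list] = None
    spread: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.kernel = _as_float_array(self.kernel, "kernel")
        self.chromophore = str(self.chromophore).lower()
        if self.chromophore not in CHROMOPHORES:
            raise ValidationError(
                f"chromophore must be one of {CHROMOPHORES}, got {self.chromophore!r}"
            )
        expected = kernel_length(self.duration_s, self.sfreq)
        if self.kernel.size != expected:
            raise ValidationError(
                f"kernel length {self.kernel.size} != round(duration_s * sfreq) = {expected}"
            )
        if self.location is not None:
            self.location = _as_float_array(self.location, "location")
        if self.spread is not None:
            self.spread = _as_float_array(self.spread, "spread")
            if self.spread.size != self.kernel.size:
                raise ValidationError("spread must match kernel length")
        if self.subject_kernels is not None:
            self.subject_kernels = [
                _as_float_array(k, "subject kernel") for k in self.subject_kernels
            ]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, half-open [0, duration)."""
        return np.arange(self.kernel.size) / self.sfreq


@dataclass
class SubjectPoolHRF:
    """Channel-level pooled HRF: per-sample trimmed mean across subjects and
    the per-sample (untrimmed) standard deviation."""

    mean_kernel: np.ndarray
    std_kernel: np.ndarray
    n_subjects: int
    trim_prop: float
    subject_kernels: Optional[list] = None

    def __post_init__(self) -> None:
        self.mean_kernel = _as_float_array(self.mean_kernel, "mean_kernel")
        self.std_kernel = _as_float_array(self.std_kernel, "std_kernel")
        if self.mean_kernel.size != self.std_kernel.size:
            raise ValidationError("mean and std kernels must have the same length")
        if np.any(self.std_kernel < 0):
            raise ValidationError("std_kernel must be elementwise non-negative")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
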