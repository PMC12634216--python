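"""Regularized Toeplitz deconvolution.

The measurement model is a discrete convolution: the observed hemoglobin
signal ``y`` is the latent neural event train convolved with the channel's
hemodynamic response function (HRF), plus noise. Writing the convolution as a
Toeplitz design matrix ``H`` (columns are shifted copies of the driver), the
Tikhonov-regularized estimate of the latent vector ``x`` is

    x = (HᵀH + λLᵀL)⁻¹ Hᵀ y

with regularization matrix ``L`` (identity by default, i.e. classical ridge)
and weight ``λ`` (default 1.0). The same inversion is used twice:

* HRF estimation — the driver is the event train, ``x`` is the HRF kernel;
* activity estimation — the driver is a previously estimated, peak-scaled
  HRF, ``x`` is the neural activity over the whole scan.

Two stabilization steps bracket the solve. The signal is z-scored before
deconvolution, and estimated kernels are scaled so their peak magnitude is 1
(with a small ε in the denominator) before being used as drivers. Edge
artifacts — the wildly varying first and last samples typical of Toeplitz
deconvolution — are suppressed by expanding the kernel window by a fraction
of its duration on each side before the solve and trimming the expansion
afterwards.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import scipy.linalg
from scipy.stats import trim_mean

from .errors import (
    ChannelDroppedError,
    ConditioningError,
    DegenerateHRFError,
    DegenerateSignalWarning,
    DimensionError,
    EdgeClipWarning,
    NoEventsError,
    ValidationError,
)
from .types import (
    ChannelRecording,
    DeconvConfig,
    EventTrain,
    HRFEstimate,
    SubjectPoolHRF,
    kernel_length,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "build_design_matrix",
    "regularization_matrix",
    "tikhonov_solve",
    "zscore",
    "expand_edges",
    "assess_conditioning",
    "estimate_channel_hrf",
    "pool_hrfs",
    "scale_hrf",
    "estimate_activity",
]


@dataclass
class DesignMatrix:
    """An n × d convolution (Toeplitz) design matrix.

    ``entries[i, j] = driver[i - j]`` for ``i >= j`` else 0, so the product
    with a length-d kernel is the linear convolution of driver and kernel
    truncated to n samples.
    """

    entries: np.ndarray

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    @property
    def d(self) -> int:
        return self.entries.shape[1]


def build_design_matrix(driver: Sequence[float], kernel_length_d: int) -> DesignMatrix:
    """Toeplitz design matrix whose product with a kernel convolves it with
    ``driver`` (truncated to the driver length).

    Parameters
    ----------
    driver : array-like, length n
        The known half of the convolution (event train or scaled HRF).
    kernel_length_d : int
        Number of columns d, 1 <= d <= n.
    """
    driver = np.asarray(driver, dtype=float)
    if driver.ndim != 1:
        raise ValidationError("driver must be 1-dimensional")
    if not np.all(np.isfinite(driver)):
        raise ValidationError("driver must be finite")
    n = driver.size
    d = int(kernel_length_d)
    if d < 1 or d > n:
        raise DimensionError(f"kernel length d={d} must satisfy 1 <= d <= n={n}")
    first_row = np.zeros(d)
    first_row[0] = driver[0]
    entries = scipy.linalg.toeplitz(driver, first_row)
    return DesignMatrix(entries=entries)


def regularization_matrix(d: int, kind: str = "identity") -> np.ndarray:
    """Return L: identity (ridge) or the (d-1) × d first-difference operator."""
    if kind == "identity":
        return np.eye(d)
    if kind == "first_difference":
        L = np.zeros((d - 1, d))
        idx = np.arange(d - 1)
        L[idx, idx] = -1.0
        L[idx, idx + 1] = 1.0
        return L
    raise ValidationError(f"unknown regularization matrix kind {kind!r}")


def _normal_matrix(H: np.ndarray, lam: float, reg: str) -> np.ndarray:
    A = H.T @ H
    if lam > 0:
        L = regularization_matrix(H.shape[1], reg)
        A = A + lam * (L.T @ L)
    return A


def tikhonov_solve(
    H: DesignMatrix | np.ndarray,
    y: Sequence[float],
    lam: float,
    reg: str = "identity",
) -> np.ndarray:
    """Minimize ``||Hx - y||² + lam ||Lx||²`` via the normal equations.

    Solved with a symmetric positive-definite factorization rather than an
    explicit inverse. With ``lam = 0`` the normal matrix must be invertible,
    otherwise a :class:`ConditioningError` is raised.
    """
    Hm = H.entries if isinstance(H, DesignMatrix) else np.asarray(H, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size != Hm.shape[0]:
        raise ValidationError(
            f"y must be 1-D with length {Hm.shape[0]}, got shape {y.shape}"
        )
    if lam < 0:
        raise ValidationError(f"lam must be >= 0, got {lam}")
    A = _normal_matrix(Hm, lam, reg)
    b = Hm.T @ y
    try:
        x = scipy.linalg.solve(A, b, assume_a="pos")
    except (scipy.linalg.LinAlgError, ValueError) as exc:
        raise ConditioningError(f"normal equations not positive definite: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise ConditioningError("solve produced non-finite values")
    return x


def zscore(signal: Sequence[float]) -> np.ndarray:
    """Z-score with the population standard deviation.

    A zero-variance signal returns all zeros and emits
    :class:`DegenerateSignalWarning` — a flat channel carries no information
    and dividing by a tiny epsilon would only amplify noise.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size < 2:
        raise ValidationError("z-score needs at least 2 samples")
    sd = signal.std()
    # relative floor: a numerically-constant signal has sd ~ eps * |mean|
    if sd <= 1e-12 * max(1.0, float(np.abs(signal).max())):
        warnings.warn("zero-variance signal z-scored to zeros", DegenerateSignalWarning)
        return np.zeros_like(signal)
    return (signal - signal.mean()) / sd


def expand_edges(
    events: EventTrain,
    duration_s: float,
    edge_fraction: float,
    sfreq: float,
) -> Tuple[EventTrain, int]:
    """Shift events earlier and widen the kernel window to push Toeplitz edge
    artifacts outside the region that will be kept.

    The pad is ``round(edge_fraction * duration_s * sfreq)`` samples; events
    are moved ``pad`` samples earlier and the kernel length grows by ``2*pad``
    so the true HRF sits in the centre of the expanded window. Events whose
    shifted index would be negative are dropped with a warning.

    Returns
    -------
    (shifted EventTrain, expanded kernel length in samples)
    """
    if not (0 <= edge_fraction < 1):
        raise ValidationError(f"edge_fraction must be in [0, 1), got {edge_fraction}")
    base = kernel_length(duration_s, sfreq)
    pad = int(round(edge_fraction * duration_s * sfreq))
    expanded = base + 2 * pad
    if pad == 0:
        if events.n_events == 0:
            raise NoEventsError("event train has no events")
        return events, expanded
    shifted = np.zeros_like(events.impulses)
    n_dropped = 0
    for idx in np.flatnonzero(events.impulses):
        new_idx = idx - pad
        if new_idx < 0:
            n_dropped += 1
        else:
            shifted[new_idx] += events.impulses[idx]
    if n_dropped:
        warnings.warn(
            f"{n_dropped} event(s) shifted before scan start were dropped",
            EdgeClipWarning,
        )
    if not np.any(shifted):
        raise NoEventsError("all events dropped during edge expansion")
    return EventTrain(impulses=shifted, sfreq=events.sfreq), expanded


def assess_conditioning(
    H: DesignMatrix | np.ndarray,
    cond_threshold: float,
    lam: float = 1.0,
    reg: str = "identity",
) -> Tuple[bool, float]:
    """2-norm condition number of the regularized normal matrix
    ``HᵀH + λLᵀL``.

    Returns ``(passed, cond)``; fails only when the condition number is
    strictly greater than the threshold (equality passes).
    """
    Hm = H.entries if isinstance(H, DesignMatrix) else np.asarray(H, dtype=float)
    if Hm.size == 0:
        raise ValidationError("design matrix is empty")
    A = _normal_matrix(Hm, lam, reg)
    cond = float(np.linalg.cond(A, 2))
    passed = np.isfinite(cond) and cond <= cond_threshold
    return passed, cond


def _cholesky_solve_with_cond(
    A: np.ndarray, b: np.ndarray
) -> Tuple[np.ndarray, float]:
    """Solve SPD ``Ax = b`` via Cholesky and return ``(x, cond_estimate)``.

    The condition estimate is the LAPACK reciprocal 1-norm estimator on the
    factor (cost O(n²) after the factorization), used on the large square
    activity designs where an exact SVD condition number would dominate the
    runtime.
    """
    anorm = float(np.linalg.norm(A, 1))
    try:
        c, low = scipy.linalg.cho_factor(A, check_finite=False)
    except scipy.linalg.LinAlgError as exc:
        raise ConditioningError(f"normal matrix not positive definite: {exc}") from exc
    rcond, info = scipy.linalg.lapack.dpocon(c, anorm, uplo=b"L" if low else b"U")
    if info != 0:  # pragma: no cover - dpocon only fails on bad arguments
        raise ConditioningError(f"condition estimator failed (info={info})")
    cond = np.inf if rcond == 0 else 1.0 / rcond
    x = scipy.linalg.cho_solve((c, low), b, check_finite=False)
    return x, float(cond)


def estimate_channel_hrf(
    rec: ChannelRecording,
    events: EventTrain,
    duration_s: float,
    cfg: Optional[DeconvConfig] = None,
) -> HRFEstimate:
    """Estimate one channel's HRF from its recording and event train.

    Pipeline: z-score the signal, expand edges, build the Toeplitz design
    from the shifted event train, check conditioning, solve the regularized
    normal equations, and keep the central ``round(duration_s * sfreq)``
    samples of the expanded solution.

    The design columns are centred before the solve: z-scoring (and any
    baseline correction upstream) leaves a constant offset that the event
    convolution cannot produce, and centring absorbs it as an implicit,
    unpenalized intercept instead of letting it bias the kernel.

    Raises
    ------
    ChannelDroppedError
        Conditioning above threshold or the cooperative time limit exceeded.
        Recoverable: callers exclude the channel and continue.
    """
    cfg = cfg or DeconvConfig()
    if events.n_samples != rec.n_samples:
        raise ValidationError(
            f"event train length {events.n_samples} != recording length {rec.n_samples}"
        )
    if events.n_events == 0:
        raise NoEventsError("event train has no events")
    d = kernel_length(duration_s, rec.sfreq)
    if d < 2:
        raise ValidationError("duration_s * sfreq must be at least 2 samples")

    t0 = time.monotonic()
    y = zscore(rec.samples)
    shifted, d_exp = expand_edges(events, duration_s, cfg.edge_fraction, rec.sfreq)
    if d_exp > rec.n_samples:
        raise DimensionError(
            f"expanded kernel length {d_exp} exceeds scan length {rec.n_samples}"
        )
    H = build_design_matrix(shifted.impulses, d_exp)
    H = DesignMatrix(entries=H.entries - H.entries.mean(axis=0, keepdims=True))
    passed, cond = assess_conditioning(H, cfg.cond_threshold, cfg.lam, cfg.reg_matrix)
    elapsed = time.monotonic() - t0
    status = "pass"
    if not passed:
        status = "drop(conditioning)"
    elif elapsed > cfg.time_limit_s:
        status = "drop(time)"
    logger.info(
        "channel=%s cond=%.3g solve_time=%.3fs status=%s",
        rec.channel_id, cond, elapsed, status,
    )
    if status == "drop(conditioning)":
        raise ChannelDroppedError(
            f"channel {rec.channel_id}: condition number {cond:.3g} exceeds "
            f"threshold {cfg.cond_threshold:.3g}"
        )
    if status == "drop(time)":
        raise ChannelDroppedError(
            f"channel {rec.channel_id}: exceeded time limit {cfg.time_limit_s}s"
        )
    x = tikhonov_solve(H, y, cfg.lam, cfg.reg_matrix)
    if time.monotonic() - t0 > cfg.time_limit_s:
        raise ChannelDroppedError(
            f"channel {rec.channel_id}: exceeded time limit {cfg.time_limit_s}s"
        )
    pad = (d_exp - d) // 2
    kernel = x[pad : pad + d]
    return HRFEstimate(
        kernel=kernel,
        duration_s=duration_s,
        sfreq=rec.sfreq,
        chromophore=rec.chromophore,
        location=rec.location.copy(),
    )


def pool_hrfs(estimates: List[HRFEstimate], trim_prop: float = 0.1) -> SubjectPoolHRF:
    """Pool per-subject kernels into a per-sample trimmed mean and spread.

    The trimmed mean discards ``floor(trim_prop * n)`` values at each tail of
    the per-sample sorted subject values; the standard deviation is computed
    over all (untrimmed) subject values with ddof=1 (0 for a single subject).
    Subject kernels are preserved for later region-of-interest meta-analysis.
    """
    if not estimates:
        raise ValidationError("need at least one estimate to pool")
    if not (0 <= trim_prop < 0.5):
        raise ValidationError(f"trim_prop must be in [0, 0.5), got {trim_prop}")
    lengths = {e.kernel.size for e in estimates}
    sfreqs = {e.sfreq for e in estimates}
    if len(lengths) > 1 or len(sfreqs) > 1:
        raise ValidationError(
            f"kernels must share length and sfreq; got lengths {sorted(lengths)}, "
            f"sfreqs {sorted(sfreqs)}"
        )
    stack = np.vstack([e.kernel for e in estimates])
    n = stack.shape[0]
    mean = trim_mean(stack, trim_prop, axis=0) if trim_prop > 0 else stack.mean(axis=0)
    std = stack.std(axis=0, ddof=1) if n > 1 else np.zeros(stack.shape[1])
    return SubjectPoolHRF(
        mean_kernel=mean,
        std_kernel=std,
        n_subjects=n,
        trim_prop=trim_prop,
        subject_kernels=[row.copy() for row in stack],
    )


def scale_hrf(h: HRFEstimate, eps: float = 1e-7) -> HRFEstimate:
    """Scale a kernel so its peak magnitude is 1 (HRFmax = 1).

    The dominant extremum sets the scale: positive-going kernels (HbO
    polarity) are divided by ``max + eps``; negative-going kernels (HbR
    polarity, where the trough dominates) by ``|min| + eps`` so the trough
    magnitude is 1 with sign preserved. Relative shape — including any
    undershoot — is unchanged. An all-zero kernel has no usable extremum.
    """
    if eps <= 0:
        raise ValidationError(f"eps must be positive, got {eps}")
    kmax = float(h.kernel.max(initial=-np.inf))
    kmin = float(h.kernel.min(initial=np.inf))
    if kmax == 0 and kmin == 0:
        raise DegenerateHRFError("kernel is identically zero; cannot peak-scale")
    denom = (kmax if kmax >= abs(kmin) else abs(kmin)) + eps
    return HRFEstimate(
        kernel=h.kernel / denom,
        duration_s=h.duration_s,
        sfreq=h.sfreq,
        chromophore=h.chromophore,
        location=None if h.location is None else h.location.copy(),
        context=dict(h.context),
        subject_kernels=None if h.subject_kernels is None
        else [k / denom for k in h.subject_kernels],
        spread=None if h.spread is None else h.spread / denom,
    )


def estimate_activity(
    rec: ChannelRecording,
    h: HRFEstimate,
    cfg: Optional[DeconvConfig] = None,
) -> np.ndarray:
    """Deconvolve an HRF out of a channel signal to estimate neural activity.

    The design matrix is the full n × n convolution matrix of the scaled HRF
    kernel (zero-padded to the scan length), so the activity estimate covers
    the whole scan in arbitrary units. The HRF must already be resampled to
    the recording's rate and peak-scaled; the scan signal is z-scored before
    the solve.
    """
    cfg = cfg or DeconvConfig()
    if abs(h.sfreq - rec.sfreq) > 1e-9:
        raise ValidationError(
            f"HRF sfreq {h.sfreq} != recording sfreq {rec.sfreq}; resample first"
        )
    peak = max(float(h.kernel.max()), abs(float(h.kernel.min())))
    if abs(peak - 1.0) > 0.05:
        raise ValidationError(
            f"HRF peak magnitude {peak:.3g} is far from 1; apply scale_hrf first"
        )
    n = rec.n_samples
    if h.kernel.size > n:
        raise DimensionError("HRF kernel longer than the recording")
    t0 = time.monotonic()
    driver = np.zeros(n)
    driver[: h.kernel.size] = h.kernel
    H = build_design_matrix(driver, n)
    y = zscore(rec.samples)
    A = _normal_matrix(H.entries, cfg.lam, cfg.reg_matrix)
    try:
        x, cond = _cholesky_solve_with_cond(A, H.entries.T @ y)
    except ConditioningError as exc:
        raise ChannelDroppedError(f"channel {rec.channel_id}: {exc}") from exc
    elapsed = time.monotonic() - t0
    passed = cond <= cfg.cond_threshold
    logger.info(
        "channel=%s activity cond=%.3g time=%.3fs status=%s",
        rec.channel_id, cond, elapsed, "pass" if passed else "drop",
    )
    if not passed:
        raise ChannelDroppedError(
            f"channel {rec.channel_id}: activity design condition estimate "
            f"{cond:.3g} exceeds threshold {cfg.cond_threshold:.3g}"
        )
    if elapsed > cfg.time_limit_s:
        raise ChannelDroppedError(
            f"channel {rec.channel_id}: exceeded time limit {cfg.time_limit_s}s"
        )
    if not np.all(np.isfinite(x)):
        raise ChannelDroppedError(f"channel {rec.channel_id}: non-finite activity")
    return x
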