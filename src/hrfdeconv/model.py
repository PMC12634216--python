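"""Model/Results interface over the deconvolution pipeline.

Two small model classes present the two inversions the package performs the
way statistical modelling packages present a fit:

* :class:`HRFDeconvolution` — estimate one channel's HRF across a cohort of
  recordings; ``fit()`` returns :class:`HRFDeconvolutionResults` carrying the
  pooled trimmed-mean kernel, the per-sample subject spread, per-subject
  kernels, drop diagnostics and a ``summary()`` table.
* :class:`NeuralActivityModel` — deconvolve a known (stored or pooled) HRF
  out of a recording; ``fit()`` returns :class:`NeuralActivityResults` with
  the activity series and before/after signal-shape diagnostics.

Both wrap the functions in :mod:`hrfdeconv.deconv`; nothing here adds new
estimation logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .deconv import (
    estimate_activity,
    estimate_channel_hrf,
    pool_hrfs,
    scale_hrf,
)
from .errors import ChannelDroppedError, ValidationError
from .preprocess import moment_stats, psd_snr
from .resample import resample_hrf
from .synth import SimulationSpec, simulate_cohort
from .types import (
    ChannelRecording,
    DeconvConfig,
    EventTrain,
    HRFEstimate,
    SubjectPoolHRF,
)

__all__ = [
    "HRFDeconvolution",
    "HRFDeconvolutionResults",
    "NeuralActivityModel",
    "NeuralActivityResults",
]


class HRFDeconvolution:
    """Cohort-level HRF estimation for one channel.

    Parameters
    ----------
    recordings, events
        Paired per-subject recordings and event trains (same channel).
    duration_s
        HRF kernel duration in seconds (default 30).
    config
        :class:`~hrfdeconv.types.DeconvConfig`; defaults used when omitted.
    """

    def __init__(
        self,
        recordings: List[ChannelRecording],
        events: List[EventTrain],
        duration_s: float = 30.0,
        config: Optional[DeconvConfig] = None,
    ) -> None:
        if len(recordings) != len(events) or not recordings:
            raise ValidationError("need equal, nonzero numbers of recordings and events")
        self.recordings = recordings
        self.events = events
        self.duration_s = float(duration_s)
        self.config = config or DeconvConfig()

    @classmethod
    def from_simulation(cls, spec: SimulationSpec, **kwargs):
        """Build the model from a simulated cohort; returns
        ``(model, true_hrf)`` so recovery can be scored."""
        recordings, trains, true_hrf = simulate_cohort(spec)
        return cls(recordings, trains, **kwargs), true_hrf

    def fit(self) -> "HRFDeconvolutionResults":
        estimates, dropped = [], []
        for rec, ev in zip(self.recordings, self.events):
            try:
                estimates.append(
                    estimate_channel_hrf(rec, ev, self.duration_s, self.config)
                )
            except ChannelDroppedError as exc:
                dropped.append((rec.channel_id, str(exc)))
        if not estimates:
            raise ChannelDroppedError(
                "every subject's deconvolution failed to converge"
            )
        pool = pool_hrfs(estimates, self.config.trim_prop)
        return HRFDeconvolutionResults(
            model=self, pool=pool, estimates=estimates, dropped=dropped
        )


@dataclass
class HRFDeconvolutionResults:
    """Pooled HRF estimate with subject-level provenance and diagnostics."""

    model: HRFDeconvolution
    pool: SubjectPoolHRF
    estimates: List[HRFEstimate]
    dropped: List[tuple] = field(default_factory=list)

    @property
    def params(self) -> np.ndarray:
        """Pooled trimmed-mean kernel (arbitrary units)."""
        return self.pool.mean_kernel

    @property
    def spread(self) -> np.ndarray:
        """Per-sample standard deviation across subjects."""
        return self.pool.std_kernel

    @property
    def sfreq(self) -> float:
        return self.estimates[0].sfreq

    @property
    def peak_time_s(self) -> float:
        return float(np.argmax(np.abs(self.params)) / self.sfreq)

    def to_estimate(self, scaled: bool = True, location=None, context=None) -> HRFEstimate:
        """Package the pooled kernel as an :class:`HRFEstimate` (peak-scaled
        by default, ready for activity deconvolution or storage)."""
        ref = self.estimates[0]
        h = HRFEstimate(
            kernel=self.params.copy(),
            duration_s=self.model.duration_s,
            sfreq=self.sfreq,
            chromophore=ref.chromophore,
            location=None if location is None else np.asarray(location, float),
            context=dict(context or {}),
            subject_kernels=[k.copy() for k in self.pool.subject_kernels],
            spread=self.spread.copy(),
        )
        return scale_hrf(h, self.model.config.eps) if scaled else h

    def summary(self) -> str:
        lines = [
            "HRF deconvolution results",
            "=" * 41,
            f"{'subjects fit':<28}{self.pool.n_subjects:>13d}",
            f"{'subjects dropped':<28}{len(self.dropped):>13d}",
            f"{'kernel duration (s)':<28}{self.model.duration_s:>13.1f}",
            f"{'sampling rate (Hz)':<28}{self.sfreq:>13.2f}",
            f"{'trim proportion / tail':<28}{self.pool.trim_prop:>13.2f}",
            f"{'lambda':<28}{self.model.config.lam:>13.3g}",
            f"{'peak time (s)':<28}{self.peak_time_s:>13.2f}",
            f"{'peak amplitude (a.u.)':<28}{self.params.max():>13.4f}",
            f"{'mean subject spread (a.u.)':<28}{self.spread.mean():>13.4f}",
            "=" * 41,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Pooled kernel with a ±1 SD subject band and faint subject traces."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.arange(self.params.size) / self.sfreq
        for k in self.pool.subject_kernels:
            ax.plot(t, k, color="0.8", lw=0.5, zorder=1)
        ax.fill_between(
            t, self.params - self.spread, self.params + self.spread,
            alpha=0.3, label="±1 SD", zorder=2,
        )
        ax.plot(t, self.params, lw=2, label="trimmed mean", zorder=3)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("HRF (a.u.)")
        ax.legend()
        return ax


class NeuralActivityModel:
    """Deconvolve a known HRF out of one recording to recover latent
    activity; the HRF is resampled to the recording's rate and peak-scaled
    automatically."""

    def __init__(
        self,
        recording: ChannelRecording,
        hrf: HRFEstimate,
        config: Optional[DeconvConfig] = None,
    ) -> None:
        self.recording = recording
        self.config = config or DeconvConfig()
        self.hrf = scale_hrf(resample_hrf(hrf, recording.sfreq), self.config.eps)

    def fit(self) -> "NeuralActivityResults":
        activity = estimate_activity(self.recording, self.hrf, self.config)
        return NeuralActivityResults(model=self, activity=activity)


@dataclass
class NeuralActivityResults:
    model: NeuralActivityModel
    activity: np.ndarray

    @property
    def recording(self) -> ChannelRecording:
        """The input recording with hemoglobin replaced by activity (a.u.),
        metadata preserved."""
        return self.model.recording.replace_samples(self.activity)

    def diagnostics(self) -> dict:
        """Before/after shape metrics: deconvolution should sharpen the
        signal (higher excess kurtosis) relative to the convolved input."""
        rec = self.model.recording
        skew_in, kurt_in = moment_stats(rec.samples)
        skew_out, kurt_out = moment_stats(self.activity)
        snr_in, _ = psd_snr(rec.samples, rec.sfreq)
        return {
            "skewness_in": skew_in,
            "skewness_out": skew_out,
            "kurtosis_in": kurt_in,
            "kurtosis_out": kurt_out,
            "kurtosis_change": kurt_out - kurt_in,
            "psd_snr_in": snr_in,
        }

    def summary(self) -> str:
        d = self.diagnostics()
        lines = [
            "Neural activity deconvolution",
            "=" * 41,
            f"{'samples':<28}{self.activity.size:>13d}",
            f"{'lambda':<28}{self.model.config.lam:>13.3g}",
            f"{'excess kurtosis (in)':<28}{d['kurtosis_in']:>13.4f}",
            f"{'excess kurtosis (out)':<28}{d['kurtosis_out']:>13.4f}",
            f"{'kurtosis change':<28}{d['kurtosis_change']:>13.4f}",
            f"{'skewness (in)':<28}{d['skewness_in']:>13.4f}",
            f"{'skewness (out)':<28}{d['skewness_out']:>13.4f}",
            "=" * 41,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        rec = self.model.recording
        t = np.arange(rec.n_samples) / rec.sfreq
        sd = rec.samples.std() or 1.0
        ax.plot(t, (rec.samples - rec.samples.mean()) / sd, label="hemoglobin (z)", lw=0.8)
        ax.plot(t, self.activity, label="activity (a.u.)", lw=0.8)
        ax.set_xlabel("time (s)")
        ax.legend()
        return ax
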