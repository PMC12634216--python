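"""Synthetic event-related fNIRS recordings with known ground truth.

Each simulated channel is a known HRF (double-gamma by default; a delayed and
blunted "child-like" preset is available) convolved with a sparse unit-impulse
event train, plus the dominant physiological confounds of real fNIRS:
sinusoidal cardiac (~1 Hz), respiratory (~0.3 Hz) and Mayer-wave (~0.1 Hz)
oscillations with random phases, white sensor noise, and a slow linear drift.
When a target PSD-band SNR is requested, the combined noise is scaled by a
root-found factor until the measured in-band / out-of-band power ratio of the
composite signal hits the target — note the Mayer wave sits *inside* the
0.01–0.2 Hz hemodynamic band, so it both corrupts the estimate and counts as
"signal" power, exactly the ambiguity real recordings present.

Ground truth (HRF kernel and event train) is returned with every recording so
estimation error can be measured directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
import scipy.optimize

from .canonical import DoubleGammaParams, double_gamma_hrf
from .errors import ValidationError
from .preprocess import BandDefinition, psd_snr
from .types import ChannelRecording, EventTrain, HRFEstimate

__all__ = [
    "NoiseComponent",
    "SimulationSpec",
    "child_hrf_params",
    "generate_events",
    "simulate_recording",
    "simulate_cohort",
]


@dataclass
class NoiseComponent:
    """One sinusoidal physiological confound (frequency in Hz, amplitude in
    the same arbitrary units as the convolved signal)."""

    frequency_hz: float
    amplitude: float


def default_noise_components() -> List[NoiseComponent]:
    return [
        NoiseComponent(1.0, 0.5),   # cardiac
        NoiseComponent(0.3, 0.3),   # respiratory
        NoiseComponent(0.1, 0.2),   # Mayer wave (inside the hemodynamic band)
    ]


def child_hrf_params(duration_s: float = 30.0, sfreq: float = 10.0) -> DoubleGammaParams:
    """Delayed (~8 s peak) and blunted-undershoot HRF preset for young
    children."""
    return DoubleGammaParams(
        peak_shape=9.0,
        peak_rate=1.0,
        undershoot_shape=18.0,
        undershoot_rate=1.0,
        undershoot_ratio=0.1,
        duration_s=duration_s,
        sfreq=sfreq,
    )


@dataclass
class SimulationSpec:
    """Study conditions for one simulated cohort.

    Defaults mirror a slow event-related pediatric protocol: a 30 s HRF
    sampled at 10 Hz, 20 events at least 25 s apart (so responses barely
    overlap), cardiac/respiratory/Mayer sinusoids plus white noise and drift,
    and a target PSD-band SNR of 5 — the exclusion boundary, i.e. the worst
    signal quality that would still enter an analysis.
    """

    n_channels: int = 1
    n_subjects: int = 1
    duration_s: float = 560.0
    sfreq: float = 10.0
    n_events: int = 20
    min_isi_s: float = 25.0
    initial_rest_s: float = 10.0
    hrf_truth: DoubleGammaParams = field(
        default_factory=lambda: DoubleGammaParams(duration_s=30.0, sfreq=10.0)
    )
    noise: List[NoiseComponent] = field(default_factory=default_noise_components)
    white_noise_sd: float = 0.3
    drift_slope_per_s: float = 0.001
    target_snr: Optional[float] = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValidationError("n_events must be >= 1")
        if self.min_isi_s < 0:
            raise ValidationError("min_isi_s must be >= 0")
        if self.n_events * self.min_isi_s >= self.duration_s:
            raise ValidationError(
                f"cannot pack {self.n_events} events with ISI >= {self.min_isi_s}s "
                f"into {self.duration_s}s"
            )
        if abs(self.hrf_truth.sfreq - self.sfreq) > 1e-9:
            self.hrf_truth = replace(self.hrf_truth, sfreq=self.sfreq)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sfreq))


def generate_events(spec: SimulationSpec, rng: Optional[np.random.Generator] = None) -> EventTrain:
    """Uniformly random onsets respecting the minimum inter-stimulus
    interval, as a unit-amplitude impulse train.

    Onsets are drawn by spreading sorted uniforms over the duration left
    after reserving one ISI per event and an initial rest baseline. The task
    may run to the end of the scan, so the last responses can be truncated —
    as in real recordings, where acquisition stops shortly after the final
    trial.
    """
    rng = rng or np.random.default_rng(spec.seed)
    usable = (
        spec.duration_s - spec.initial_rest_s - spec.n_events * spec.min_isi_s
        - 1.0 / spec.sfreq  # last onset strictly inside the scan after rounding
    )
    if usable <= 0:
        raise ValidationError("duration too short for the requested events and ISI")
    base = np.sort(rng.uniform(0, usable, size=spec.n_events))
    onsets = spec.initial_rest_s + base + np.arange(spec.n_events) * spec.min_isi_s
    return EventTrain.from_onsets(onsets, spec.n_samples, spec.sfreq)


def _clean_signal(spec: SimulationSpec, events: EventTrain, kernel: np.ndarray) -> np.ndarray:
    return np.convolve(events.impulses, kernel)[: spec.n_samples]


def _noise_signal(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(spec.n_samples) / spec.sfreq
    noise = np.zeros(spec.n_samples)
    for comp in spec.noise:
        phase = rng.uniform(0, 2 * np.pi)
        noise += comp.amplitude * np.sin(2 * np.pi * comp.frequency_hz * t + phase)
    noise += rng.normal(0, spec.white_noise_sd, size=spec.n_samples)
    noise += spec.drift_slope_per_s * t
    return noise


def _calibrate_noise_scale(
    spec: SimulationSpec, clean: np.ndarray, noise: np.ndarray
) -> float:
    """Scale on the combined noise so the measured PSD-band SNR of
    clean + scale*noise hits the target (monotone in the scale; bisected
    with a root finder on log-scale)."""
    target = spec.target_snr
    bands = BandDefinition()

    def measured(log_scale: float) -> float:
        ratio, _ = psd_snr(clean + np.exp(log_scale) * noise, spec.sfreq, bands)
        return ratio - target

    lo, hi = np.log(1e-4), np.log(1e4)
    f_lo, f_hi = measured(lo), measured(hi)
    if f_lo < 0:
        raise ValidationError(
            f"target SNR {target} unreachable: even near-zero noise measures below it"
        )
    if f_hi > 0:
        # in-band noise (Mayer) floors the ratio above the target: use max noise
        return float(np.exp(hi))
    return float(np.exp(scipy.optimize.brentq(measured, lo, hi, xtol=1e-3)))


def simulate_recording(
    spec: SimulationSpec,
    events: Optional[EventTrain] = None,
    rng: Optional[np.random.Generator] = None,
    channel_id: str = "sim0",
    location=(0.0, 0.0, 0.0),
) -> Tuple[ChannelRecording, dict]:
    """One channel's recording plus its ground truth.

    Returns ``(recording, truth)`` with ``truth`` holding the event train,
    the true HRF (peak-scaled double-gamma) and the noise scale applied.
    """
    rng = rng or np.random.default_rng(spec.seed)
    if events is None:
        events = generate_events(spec, rng)
    true_hrf = double_gamma_hrf(spec.hrf_truth)
    clean = _clean_signal(spec, events, true_hrf.kernel)
    noise = _noise_signal(spec, rng)
    scale = 1.0
    if spec.target_snr is not None and np.any(noise):
        scale = _calibrate_noise_scale(spec, clean, noise)
    samples = clean + scale * noise
    rec = ChannelRecording(
        channel_id=channel_id,
        chromophore="hbo",
        sfreq=spec.sfreq,
        samples=samples,
        location=np.asarray(location, dtype=float),
    )
    truth = {
        "events": events,
        "hrf": true_hrf,
        "clean": clean,
        "noise_scale": scale,
        "seed": spec.seed,
    }
    return rec, truth


def simulate_cohort(
    spec: SimulationSpec,
) -> Tuple[List[ChannelRecording], List[EventTrain], HRFEstimate]:
    """One recording per subject (single channel), each with its own event
    schedule and noise draw but a shared ground-truth HRF.

    Returns ``(recordings, event_trains, true_hrf)``; deterministic given
    ``spec.seed``.
    """
    master = np.random.default_rng(spec.seed)
    true_hrf = double_gamma_hrf(spec.hrf_truth)
    recordings, trains = [], []
    for subject in range(spec.n_subjects):
        rng = np.random.default_rng(master.integers(2**31))
        events = generate_events(spec, rng)
        rec, _ = simulate_recording(spec, events=events, rng=rng, channel_id="ch0")
        recordings.append(rec)
        trains.append(events)
    return recordings, trains, true_hrf
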