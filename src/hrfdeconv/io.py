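"""Readers and writers for the package's native text formats.

Recordings travel as a delimited signals table (a ``time`` column in seconds
plus one column per channel) with a montage sidecar TSV giving each channel's
3-D location, chromophore and sampling rate. Events are a TSV of onsets in
seconds (optional amplitude column) or a single full-length impulse column.
Readers validate rather than coerce: a channel missing from the montage, an
irregular time step, or an onset beyond the scan are errors that name the
offender.
"""

from __future__ import annotations

from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .errors import NoEventsError, ValidationError
from .types import ChannelRecording, EventTrain

__all__ = [
    "read_montage",
    "write_montage",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
]

_MONTAGE_COLUMNS = ["channel_id", "x_mm", "y_mm", "z_mm", "chromophore", "sfreq"]


def read_montage(path) -> pd.DataFrame:
    montage = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _MONTAGE_COLUMNS if c not in montage.columns]
    if missing:
        raise ValidationError(f"montage {path} missing columns: {missing}")
    dup = montage.duplicated(subset=["channel_id"])
    if dup.any():
        raise ValidationError(
            f"montage {path} has duplicate channel_ids: "
            f"{sorted(montage.loc[dup, 'channel_id'])}"
        )
    coords = montage[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValidationError(f"montage {path} has non-finite coordinates")
    return montage


def write_montage(recordings: List[ChannelRecording], path) -> None:
    rows = [
        {
            "channel_id": r.channel_id,
            "x_mm": r.location[0],
            "y_mm": r.location[1],
            "z_mm": r.location[2],
            "chromophore": r.chromophore,
            "sfreq": r.sfreq,
        }
        for r in recordings
    ]
    pd.DataFrame(rows, columns=_MONTAGE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_recording(signals_path, montage_path) -> List[ChannelRecording]:
    """Parse a signals table and its montage sidecar into recordings.

    The sampling rate of each channel is validated against the time column
    (relative tolerance 1e-6); the time step must be regular.
    """
    signals = pd.read_csv(signals_path, sep="\t", float_precision="round_trip")
    if "time" not in signals.columns:
        raise ValidationError(f"signals table {signals_path} has no 'time' column")
    montage = read_montage(montage_path).set_index("channel_id")
    t = signals["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValidationError("signals table needs at least 2 rows")
    dt = np.diff(t)
    if np.any(np.abs(dt - dt[0]) > 1e-6 * max(abs(dt[0]), 1e-12)):
        raise ValidationError(f"irregular time step in {signals_path}")
    sfreq_from_time = 1.0 / dt[0]
    recordings = []
    for column in signals.columns:
        if column == "time":
            continue
        if column not in montage.index:
            raise ValidationError(
                f"channel {column!r} in signals table missing from montage"
            )
        row = montage.loc[column]
        if abs(row["sfreq"] - sfreq_from_time) > 1e-6 * sfreq_from_time:
            raise ValidationError(
                f"channel {column!r}: montage sfreq {row['sfreq']} disagrees with "
                f"time column ({sfreq_from_time:.6f} Hz)"
            )
        recordings.append(
            ChannelRecording(
                channel_id=column,
                chromophore=str(row["chromophore"]),
                sfreq=float(row["sfreq"]),
                samples=signals[column].to_numpy(dtype=float),
                location=np.array([row["x_mm"], row["y_mm"], row["z_mm"]], dtype=float),
            )
        )
    return recordings


def write_recording(recordings: List[ChannelRecording], signals_path, montage_path) -> None:
    """Write the signals table + montage sidecar; the paired reader parses
    them back losslessly (17 significant digits round-trips doubles)."""
    if not recordings:
        raise ValidationError("nothing to write")
    n = {r.n_samples for r in recordings}
    sf = {r.sfreq for r in recordings}
    if len(n) > 1 or len(sf) > 1:
        raise ValidationError("all channels must share length and sfreq to share a table")
    table = {"time": np.arange(recordings[0].n_samples) / recordings[0].sfreq}
    for r in recordings:
        table[r.channel_id] = r.samples
    pd.DataFrame(table).to_csv(signals_path, sep="\t", index=False, float_format="%.17g")
    write_montage(recordings, montage_path)


def read_events(path, n_samples: int, sfreq: float) -> EventTrain:
    """Events from a TSV: either ``onset_s`` (+ optional ``amplitude``)
    columns, or a single full-length impulse column."""
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if table.empty:
        raise NoEventsError(f"event file {path} is empty")
    if "onset_s" in table.columns:
        amplitudes = (
            table["amplitude"].to_numpy(dtype=float)
            if "amplitude" in table.columns
            else None
        )
        return EventTrain.from_onsets(
            table["onset_s"].to_numpy(dtype=float), n_samples, sfreq, amplitudes
        )
    if table.shape[1] == 1:
        impulses = table.iloc[:, 0].to_numpy(dtype=float)
        if impulses.size != n_samples:
            raise ValidationError(
                f"impulse column length {impulses.size} != scan length {n_samples}"
            )
        if not np.any(impulses):
            raise NoEventsError(f"impulse column in {path} has no events")
        return EventTrain(impulses=impulses, sfreq=sfreq)
    raise ValidationError(
        f"event file {path} must have an 'onset_s' column or a single impulse column"
    )


def write_events(events: EventTrain, path) -> None:
    onsets = events.onset_indices / events.sfreq
    pd.DataFrame(
        {"onset_s": onsets, "amplitude": events.impulses[events.onset_indices]}
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")
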