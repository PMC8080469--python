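"""Flicker-event recovery from the audio trigger channel, and epoching.

The trigger channel carries analogue pulses synchronized with the visual
flicker.  Onsets are recovered by z-scoring the whole channel and marking
every sample where the absolute z-score rises above 3 from at-or-below 3.
Because a flicker train emits one pulse per cycle, trial onsets are then the
events without a preceding event within 400 ms (trials are separated by at
least 500 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ChannelMismatchError, DegenerateDataError
from .io import Recording

__all__ = ["EventSeries", "Epochs", "detect_flicker_events", "segment_trials", "epoch"]


@dataclass
class EventSeries:
    """Strictly increasing 0-based sample indices with their sampling rate."""

    sample_indices: np.ndarray
    fs: float

    def __post_init__(self):
        self.sample_indices = np.asarray(self.sample_indices, dtype=int)
        if self.sample_indices.ndim != 1:
            raise ValueError("sample_indices must be 1-D")
        if self.sample_indices.size and (
            np.any(np.diff(self.sample_indices) <= 0) or self.sample_indices[0] < 0
        ):
            raise ValueError("sample indices must be non-negative, strictly increasing")

    def __len__(self):
        return self.sample_indices.size

    @property
    def times(self) -> np.ndarray:
        return self.sample_indices / self.fs

    def to_table(self) -> np.ndarray:
        return np.column_stack([self.sample_indices, self.times])


@dataclass
class Epochs:
    """Trials x channels x samples, cut at the given onsets."""

    data: np.ndarray
    onsets: EventSeries
    tmin: float
    tmax: float
    fs: float
    channel_labels: list

    def __post_init__(self):
        n_samp = int(round((self.tmax - self.tmin) * self.fs))
        if self.data.shape != (len(self.onsets), len(self.channel_labels), n_samp):
            raise ValueError(
                f"epoch array shape {self.data.shape} inconsistent with "
                f"{len(self.onsets)} trials x {len(self.channel_labels)} channels "
                f"x {n_samp} samples"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.fs


def detect_flicker_events(audio: np.ndarray, fs: float) -> EventSeries:
    """Threshold-crossing events on the z-scored trigger channel.

    A sample ``n >= 1`` is an event iff ``|z[n]| > 3`` and ``|z[n-1]| <= 3``,
    with z-scores computed over the entire channel.
    """
    audio = np.asarray(audio, dtype=float).ravel()
    sd = audio.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateDataError("trigger channel has zero variance")
    z = np.abs((audio - audio.mean()) / sd)
    above = z > 3.0
    rises = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    return EventSeries(rises, fs)


def segment_trials(events: EventSeries, min_gap: float = 0.4) -> EventSeries:
    """Keep only events without a preceding event within ``min_gap`` seconds.

    The first event is always kept; a gap of exactly ``min_gap`` is kept.
    Idempotent whenever kept events are themselves separated by >= min_gap,
    which holds by construction.
    """
    idx = events.sample_indices
    if idx.size == 0:
        return EventSeries(idx, events.fs)
    gap_samp = min_gap * events.fs
    keep = np.ones(idx.size, dtype=bool)
    keep[1:] = np.diff(idx) >= gap_samp  # strict < min_gap suppresses
    return EventSeries(idx[keep], events.fs)


def epoch(
    rec: Recording,
    onsets: EventSeries,
    tmin: float = 0.0,
    tmax: float = 2.0,
    picks: str = "eeg",
) -> Epochs:
    """Cut ``[onset+tmin, onset+tmax)`` windows out of the EEG channels.

    Trials whose window would exceed the recording are dropped (a count is
    recorded on the returned object as ``n_dropped``).
    """
    if tmax <= tmin:
        raise ValueError("tmax must exceed tmin: zero-length windows not allowed")
    if abs(onsets.fs - rec.fs) > 1e-9:
        raise ChannelMismatchError("event and recording sampling rates differ")
    ch_idx = rec.indices(picks) if picks != "all" else np.arange(rec.data.shape[0])
    labels = [rec.channel_labels[i] for i in ch_idx]
    n_samp = int(round((tmax - tmin) * rec.fs))
    off = int(round(tmin * rec.fs))
    starts = onsets.sample_indices + off
    ok = (starts >= 0) & (starts + n_samp <= rec.n_samples)
    n_dropped = int(np.sum(~ok))
    if not np.any(ok):
        raise DegenerateDataError("no trial window fits inside the recording")
    starts = starts[ok]
    sl = starts[:, None] + np.arange(n_samp)[None, :]
    data = rec.data[ch_idx][:, sl].transpose(1, 0, 2).copy()
    ep = Epochs(
        data=data,
        onsets=EventSeries(onsets.sample_indices[ok], rec.fs),
        tmin=tmin,
        tmax=tmax,
        fs=rec.fs,
        channel_labels=labels,
    )
    ep.n_dropped = n_dropped
    return ep
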