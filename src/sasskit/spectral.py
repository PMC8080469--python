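"""Narrowband filtering, analytic signal and single-trial SSVEP metrics.

The SSVEP pipeline band-pass filters the *continuous* data around the
flicker frequency with a linear-phase FIR (1.65 s long, applied with
group-delay compensation so the net response is zero-phase), takes the
Hilbert analytic signal, and averages instantaneous amplitude and phase
within each 2 s trial.  Phases are always expressed relative to the flicker:
the reference is a cosine of the flicker frequency starting at each trial
onset, so a source ``A cos(2*pi*f*(t - t_onset) + phi)`` has single-trial
phase ``phi``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import DegenerateDataError, SasskitError
from .events import EventSeries
from .io import OCCIPITAL_SET, Recording

__all__ = [
    "BandSpec",
    "TrialMetrics",
    "fir_bandpass",
    "analytic",
    "trial_phase_amplitude",
    "virtual_channel",
    "welch_psd",
    "multitaper_psd",
    "amplitude_topography",
]


@dataclass(frozen=True)
class BandSpec:
    """A symmetric passband ``center +/- half_width`` with FIR duration in s."""

    center: float = 10.0
    half_width: float = 1.0
    filter_dur: float = 1.65

    def __post_init__(self):
        if not 0 < self.center - self.half_width:
            raise ValueError("band must not reach 0 Hz")

    def edges(self):
        return (self.center - self.half_width, self.center + self.half_width)

    def n_taps(self, fs: float) -> int:
        n = int(round(self.filter_dur * fs))
        return n if n % 2 == 1 else n + 1

    def validate(self, fs: float):
        if self.center + self.half_width >= fs / 2:
            raise SasskitError(
                f"band {self.edges()} Hz exceeds the Nyquist frequency {fs / 2} Hz"
            )


@dataclass
class TrialMetrics:
    """Per-trial SSVEP amplitude (uV) and phase relative to flicker (rad)."""

    amplitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self):
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.angle(np.exp(1j * np.asarray(self.phase, dtype=float)))

    @property
    def n_trials(self) -> int:
        return self.amplitude.size


def fir_bandpass(data: np.ndarray, fs: float, band: BandSpec) -> np.ndarray:
    """Zero-phase band-pass via a windowed linear-phase FIR.

    The filter has ``round(filter_dur*fs)`` taps (forced odd); applying the
    symmetric kernel centered on each sample compensates the group delay, so
    the output has the same length and no phase shift in the passband.
    """
    band.validate(fs)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    taps = sps.firwin(band.n_taps(fs), band.edges(), fs=fs, pass_zero=False)
    out = sps.fftconvolve(data, taps[None, :], mode="same", axes=1)
    return out


def analytic(data: np.ndarray) -> np.ndarray:
    """Hilbert analytic signal along the last axis (real part = input)."""
    return sps.hilbert(np.asarray(data, dtype=float), axis=-1)


def virtual_channel(
    rec_or_data, channel_labels=None, occipital_set=OCCIPITAL_SET
) -> np.ndarray:
    """Average of the occipital sensors as one representative channel."""
    if isinstance(rec_or_data, Recording):
        data, labels = rec_or_data.data, rec_or_data.channel_labels
    else:
        data, labels = np.asarray(rec_or_data), list(channel_labels)
    occ = list(occipital_set)
    if not occ:
        raise DegenerateDataError("occipital set is empty")
    missing = [l for l in occ if l not in labels]
    if missing:
        raise DegenerateDataError(f"occipital channels not in data: {missing}")
    idx = [labels.index(l) for l in occ]
    return data[idx].mean(axis=0)


def trial_phase_amplitude(
    rec: Recording,
    onsets: EventSeries,
    band: BandSpec = BandSpec(),
    occipital_set=OCCIPITAL_SET,
    f_flicker: float = 10.0,
    tmin: float = 0.0,
    tmax: float = 2.0,
    projection: np.ndarray | None = None,
) -> TrialMetrics:
    """Single-trial amplitude and phase (relative to flicker) on the virtual
    occipital channel.

    The continuous EEG is optionally cleaned with a spatial projection
    (rows/cols in the recording's EEG channel order), band-pass filtered,
    averaged over the occipital set, and Hilbert-transformed.  Per trial the
    amplitude is the mean modulus over the window and the phase is the
    circular mean of the instantaneous phase minus the flicker reference
    ``2*pi*f_flicker*(t - t_onset)``.
    """
    eeg = rec.eeg_data()
    if projection is not None:
        eeg = projection @ eeg
    filt = fir_bandpass(eeg, rec.fs, band)
    virt = virtual_channel(filt, rec.eeg_labels, occipital_set)
    ana = analytic(virt)
    n_samp = int(round((tmax - tmin) * rec.fs))
    off = int(round(tmin * rec.fs))
    rel_t = (off + np.arange(n_samp)) / rec.fs
    ref = np.exp(1j * 2 * np.pi * f_flicker * rel_t)
    amps, phs = [], []
    for on in onsets.sample_indices:
        seg = ana[on + off : on + off + n_samp]
        if seg.size != n_samp:
            continue
        amps.append(np.abs(seg).mean())
        phs.append(np.angle(np.mean(np.exp(1j * np.angle(seg)) * np.conj(ref))))
    if not amps:
        raise DegenerateDataError("no complete trial inside the recording")
    return TrialMetrics(np.array(amps), np.array(phs))


def welch_psd(data: np.ndarray, fs: float, seg_len: float = 2.0, overlap: float = 0.5):
    """Welch PSD per channel (Hann windows); returns ``(freqs, psd)`` in
    uV^2/Hz."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    nper = int(round(seg_len * fs))
    nper = min(nper, data.shape[1])
    freqs, psd = sps.welch(
        data, fs=fs, nperseg=nper, noverlap=int(round(overlap * nper)), axis=1
    )
    return freqs, psd


def multitaper_psd(data: np.ndarray, fs: float, bandwidth: float = 0.5):
    """Full-length DPSS multitaper PSD per channel (resolution ~ 1/duration)."""
    from mne.time_frequency import psd_array_multitaper

    data = np.atleast_2d(np.asarray(data, dtype=float))
    psd, freqs = psd_array_multitaper(
        data, sfreq=fs, bandwidth=bandwidth, normalization="full", verbose="error"
    )
    return freqs, psd


def amplitude_topography(
    rec: Recording,
    onsets: EventSeries,
    band: BandSpec = BandSpec(),
    tmin: float = 0.0,
    tmax: float = 2.0,
    projection: np.ndarray | None = None,
):
    """Per-channel mean single-trial band amplitude (linear uV).

    Display code should plot ``log10`` of these values so cleaned and
    artifact-contaminated maps share a scale.
    """
    eeg = rec.eeg_data()
    if projection is not None:
        eeg = projection @ eeg
    filt = fir_bandpass(eeg, rec.fs, band)
    env = np.abs(analytic(filt))
    n_samp = int(round((tmax - tmin) * rec.fs))
    off = int(round(tmin * rec.fs))
    vals = []
    for on in onsets.sample_indices:
        seg = env[:, on + off : on + off + n_samp]
        if seg.shape[1] == n_samp:
            vals.append(seg.mean(axis=1))
    if not vals:
        raise DegenerateDataError("no complete trial inside the recording")
    return dict(zip(rec.eeg_labels, np.mean(vals, axis=0)))
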