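"""Ground-truth-annotated synthetic AM-tACS / SSVEP sessions.

The generator emulates the structure of a two-session experiment: a
calibration session of visual 10-Hz flicker trials without stimulation, and a
second session with amplitude-modulated tACS (220 Hz carrier, 10 Hz
envelope) applied during identical flicker trials.  At the sensors the
stimulation artifact is orders of magnitude larger than the brain signal;
crucially, a per-channel *nonlinear* transfer (quadratic and/or rectifying)
demodulates the AM carrier and deposits an artifact directly at the envelope
frequency, with a channel-dependent topography distinct from the SSVEP's.
That envelope-frequency artifact is what SASS has to remove.

Every stochastic element is drawn from streams derived from a single seed,
so identical configurations produce bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from .exceptions import SasskitError
from .io import MONTAGE_64_LABELS, Recording, standard_montage_64

__all__ = [
    "NoiseConfig",
    "HeartbeatConfig",
    "SynthConfig",
    "SynthTruth",
    "generate_session",
    "apply_channel_nonlinearity",
    "generate_ecg_and_modulation",
    "default_ssvep_pattern",
    "default_artifact_pattern",
]


@dataclass
class NoiseConfig:
    """Background EEG noise: spatially mixed 1/f sources plus sensor noise."""

    exponent: float = 1.0  # power-spectral slope of the shared sources
    rank: int = 8  # number of spatially mixed background sources
    sigma: float = 3.0  # per-channel std of the mixed 1/f background, uV
    sensor_sigma: float = 0.5  # independent white sensor noise, uV


@dataclass
class HeartbeatConfig:
    enabled: bool = False
    rate: float = 1.1  # mean heart rate, Hz
    depth: float = 0.1  # fractional artifact modulation at the R-peak
    jitter: float = 0.03  # fractional R-R interval jitter
    bump_sigma: float = 0.08  # width of the modulation bump, s


@dataclass
class SynthConfig:
    """Parameters of a synthetic session pair.

    Defaults reproduce the recorded paradigm: 500 Hz sampling, 200 trials of
    2 s 10-Hz flicker separated by 0.5-1 s, AM-tACS with a 220 Hz carrier and
    10 Hz envelope whose sensor amplitude is ``artifact_gain`` times the mean
    SSVEP amplitude.
    """

    fs: float = 500.0
    n_trials: int = 200
    trial_len: float = 2.0
    iti_range: tuple = (0.5, 1.0)
    f_ssvep: float = 10.0
    f_carrier: float = 220.0

    ssvep_amp_mean: float = 2.0  # median single-trial SSVEP amplitude, uV
    ssvep_amp_sigma: float = 0.4  # log-sd of the lognormal amplitude spread
    ssvep_phase_lag: float = 1.0  # mean phase relative to flicker onset, rad
    ssvep_phase_kappa: float = 5.0  # von Mises concentration of phase jitter

    artifact_gain: float = 1e3  # carrier amplitude / mean SSVEP amplitude
    carrier_phase: float = 0.7  # rad
    envelope_phase: float = 0.3  # rad; not locked to flicker onsets

    # per-channel nonlinear transfer y = x + c2*x^2 + cr*max(x, 0);
    # None -> defaults (heterogeneous quadratic term, no rectifier)
    nonlin_c2: np.ndarray | None = None
    nonlin_cr: np.ndarray | None = None
    nonlin_c2_scale: float = 0.05

    ssvep_pattern: np.ndarray | None = None
    artifact_pattern: np.ndarray | None = None

    noise: NoiseConfig = field(default_factory=NoiseConfig)
    heartbeat: HeartbeatConfig = field(default_factory=HeartbeatConfig)

    audio_pulse_per_cycle: bool = True
    audio_pulse_height: float = 1.0
    audio_pulse_width: float = 0.006  # s
    audio_noise: float = 0.02

    anti_alias: bool = True  # 125 Hz low-pass as in the recording amplifier;
    # disable to inspect the raw AM carrier and its sidebands
    lead_in: float = 2.0  # s of artifact+noise before the first trial
    lead_out: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.iti_range[0] < 0.4:
            raise ValueError("minimum inter-trial interval must be >= 0.4 s")
        if self.artifact_gain < 0 or self.noise.sigma < 0:
            raise ValueError("gains must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("nonlin_c2", "nonlin_cr", "ssvep_pattern", "artifact_pattern"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseConfig(**d["noise"])
        if "heartbeat" in d and isinstance(d["heartbeat"], dict):
            d["heartbeat"] = HeartbeatConfig(**d["heartbeat"])
        if "iti_range" in d:
            d["iti_range"] = tuple(d["iti_range"])
        for key in ("nonlin_c2", "nonlin_cr", "ssvep_pattern", "artifact_pattern"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


@dataclass
class SynthTruth:
    """Everything the generator knows that an analysis must recover."""

    clean_data: np.ndarray  # 64 x samples, uV: brain signal + noise
    artifact_data: np.ndarray  # 64 x samples, uV
    trial_onsets: np.ndarray  # sample indices
    true_trial_phase: np.ndarray  # rad, relative to flicker onset
    true_trial_amplitude: np.ndarray  # uV at the SSVEP pattern peak
    r_peak_samples: np.ndarray | None = None
    modulation_envelope: np.ndarray | None = None
    artifact_band_rank: int = 0  # spatial rank of the envelope-band artifact


def _pattern_from_center(center: np.ndarray, width: float) -> np.ndarray:
    mont = standard_montage_64()
    pos = np.array([mont[l] for l in MONTAGE_64_LABELS])
    d2 = np.sum((pos - center) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * width**2))


def default_ssvep_pattern() -> np.ndarray:
    """Occipital bump peaking between O1/Oz/O2, unit maximum."""
    mont = standard_montage_64()
    center = np.mean([mont[l] for l in ("O1", "Oz", "O2")], axis=0)
    pat = _pattern_from_center(center, 0.35)
    return pat / pat.max()


def default_artifact_pattern() -> np.ndarray:
    """Stimulation-electrode footprint: bumps over CPz and the inion.

    A small floor keeps every channel weakly coupled to the injected
    current, as observed with real scalp volume conduction.
    """
    mont = standard_montage_64()
    inion = np.asarray(mont["Oz"]) * 1.25
    pat = 0.7 * _pattern_from_center(np.asarray(mont["CPz"]), 0.45)
    pat = pat + 0.9 * _pattern_from_center(inion, 0.45)
    pat = pat + 0.08
    return pat / pat.max()


def apply_channel_nonlinearity(x, c2, cr=None):
    """Per-channel electrode nonlinearity ``y_i = x + c2_i x^2 + cr_i max(x, 0)``.

    ``x`` is the common injected waveform (1-D); returns channels x samples.
    A quadratic term demodulates an AM carrier: the square of the envelope
    contains energy at the envelope frequency and its harmonics, with
    amplitude proportional to ``c2``.
    """
    x = np.asarray(x, dtype=float)
    c2 = np.atleast_1d(np.asarray(c2, dtype=float))
    cr = np.zeros_like(c2) if cr is None else np.atleast_1d(np.asarray(cr, dtype=float))
    if cr.shape != c2.shape:
        raise ValueError("c2 and cr must have identical shapes")
    out = x[None, :] + c2[:, None] * (x * x)[None, :]
    if np.any(cr != 0):
        out = out + cr[:, None] * np.maximum(x, 0.0)[None, :]
    if not np.all(np.isfinite(out)):
        raise SasskitError("channel nonlinearity produced non-finite samples")
    return out


def generate_ecg_and_modulation(cfg: SynthConfig, n_samples: int, rng=None):
    """Quasi-periodic ECG trace, R-peak samples and the artifact modulation.

    The modulation envelope is ``1 + depth * sum_k h(t - t_k)`` with a
    Gaussian bump ``h`` of unit height, so the artifact amplitude rises by
    ``depth`` at each R-peak.
    """
    hb = cfg.heartbeat
    if not hb.enabled:
        raise SasskitError("heartbeat generation requested but not enabled")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    t_end = n_samples / fs
    peaks = []
    t = 0.5 + rng.uniform(0, 1.0 / hb.rate)
    while t < t_end - 0.2:
        peaks.append(int(round(t * fs)))
        t += (1.0 / hb.rate) * (1.0 + hb.jitter * rng.standard_normal())
    peaks = np.array(sorted(set(peaks)), dtype=int)

    tt = np.arange(n_samples) / fs
    ecg = 20.0 * rng.standard_normal(n_samples)  # baseline noise, uV
    mod = np.ones(n_samples)
    half = int(round(0.2 * fs))
    tpl_t = (np.arange(-half, half + 1)) / fs
    template = 1000.0 * (
        1.2 * np.exp(-(tpl_t**2) / (2 * 0.012**2))
        - 0.25 * np.exp(-((tpl_t - 0.04) ** 2) / (2 * 0.02**2))
        - 0.15 * np.exp(-((tpl_t + 0.04) ** 2) / (2 * 0.02**2))
    )
    bump_half = int(round(4 * hb.bump_sigma * fs))
    bump_t = np.arange(-bump_half, bump_half + 1) / fs
    bump = np.exp(-(bump_t**2) / (2 * hb.bump_sigma**2))
    for p in peaks:
        lo, hi = p - half, p + half + 1
        s0, s1 = max(lo, 0), min(hi, n_samples)
        ecg[s0:s1] += template[s0 - lo : s1 - lo]
        lo, hi = p - bump_half, p + bump_half + 1
        s0, s1 = max(lo, 0), min(hi, n_samples)
        mod[s0:s1] += hb.depth * bump[s0 - lo : s1 - lo]
    return ecg, peaks, mod


def _pink_noise(rng, n_sources, n_samples, exponent, fs):
    """Unit-variance 1/f^exponent (power) noise rows via spectral shaping."""
    white = rng.standard_normal((n_sources, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], 1.0) ** (-exponent / 2.0)
    shape[0] = 0.0
    out = np.fft.irfft(spec * shape[None, :], n=n_samples, axis=1)
    out /= out.std(axis=1, keepdims=True)
    return out


def _session_rngs(cfg: SynthConfig, with_stim: bool):
    struct = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    sess = np.random.default_rng(
        np.random.SeedSequence(cfg.seed, spawn_key=(1, int(bool(with_stim))))
    )
    return struct, sess


def _structure(cfg: SynthConfig, rng_struct):
    """Spatial patterns and nonlinearity coefficients (shared by the pair)."""
    ssvep_pat = (
        default_ssvep_pattern() if cfg.ssvep_pattern is None else np.asarray(cfg.ssvep_pattern, float)
    )
    art_pat = (
        default_artifact_pattern()
        if cfg.artifact_pattern is None
        else np.asarray(cfg.artifact_pattern, float)
    )
    if cfg.nonlin_c2 is None:
        c2 = cfg.nonlin_c2_scale * rng_struct.uniform(0.5, 1.5, size=64)
    else:
        c2 = np.asarray(cfg.nonlin_c2, dtype=float)
    if cfg.nonlin_cr is None:
        cr = np.zeros(64)
    else:
        cr = np.asarray(cfg.nonlin_cr, dtype=float)
    mix = rng_struct.standard_normal((64, max(cfg.noise.rank, 1)))
    mix /= np.linalg.norm(mix, axis=1, keepdims=True)
    return ssvep_pat, art_pat, c2, cr, mix


def generate_session(cfg: SynthConfig, with_stim: bool):
    """Generate one session; returns ``(Recording, SynthTruth)``.

    The Recording holds 64 EEG rows, an ``audio`` trigger row and, when
    heartbeat simulation is enabled, an ``ECG`` row.  EEG rows equal
    ``truth.clean_data + truth.artifact_data`` exactly.
    """
    rng_struct, rng = _session_rngs(cfg, with_stim)
    ssvep_pat, art_pat, c2, cr, mix = _structure(cfg, rng_struct)
    fs = cfg.fs
    trial_samp = int(round(cfg.trial_len * fs))

    # --- timeline -------------------------------------------------------
    onsets = np.empty(cfg.n_trials, dtype=int)
    cur = int(round(cfg.lead_in * fs))
    for i in range(cfg.n_trials):
        onsets[i] = cur
        iti = rng.uniform(*cfg.iti_range)
        cur += trial_samp + int(round(iti * fs))
    n_samples = cur + int(round(cfg.lead_out * fs))

    # --- SSVEP source ----------------------------------------------------
    amps = cfg.ssvep_amp_mean * np.exp(cfg.ssvep_amp_sigma * rng.standard_normal(cfg.n_trials))
    phases = cfg.ssvep_phase_lag + rng.vonmises(0.0, cfg.ssvep_phase_kappa, cfg.n_trials)
    phases = np.angle(np.exp(1j * phases))
    source = np.zeros(n_samples)
    tt = np.arange(trial_samp) / fs
    for on, a, ph in zip(onsets, amps, phases):
        source[on : on + trial_samp] += a * np.cos(
            2 * np.pi * cfg.f_ssvep * tt + ph
        )

    # --- background noise -----------------------------------------------
    clean = mix @ _pink_noise(rng, max(cfg.noise.rank, 1), n_samples, cfg.noise.exponent, fs)
    clean *= cfg.noise.sigma
    if cfg.noise.sensor_sigma > 0:
        clean += cfg.noise.sensor_sigma * rng.standard_normal((64, n_samples))
    clean += ssvep_pat[:, None] * source[None, :]

    # --- stimulation artifact -------------------------------------------
    r_peaks, mod = None, None
    if cfg.heartbeat.enabled:
        ecg, r_peaks, mod = generate_ecg_and_modulation(cfg, n_samples, rng)
    band_rank = 0
    if with_stim:
        t_full = np.arange(n_samples) / fs
        env = 0.5 * (1.0 + np.cos(2 * np.pi * cfg.f_ssvep * t_full + cfg.envelope_phase))
        x = env * np.cos(2 * np.pi * cfg.f_carrier * t_full + cfg.carrier_phase)
        if mod is not None:
            x = x * mod
        gain = cfg.artifact_gain * cfg.ssvep_amp_mean
        artifact = gain * art_pat[:, None] * apply_channel_nonlinearity(x, c2, cr)
        profiles = []
        if np.any(c2 != 0):
            profiles.append(art_pat * c2)
        if np.any(cr != 0):
            profiles.append(art_pat * cr)
        band_rank = int(np.linalg.matrix_rank(np.array(profiles))) if profiles else 0
    else:
        artifact = np.zeros((64, n_samples))

    if cfg.anti_alias:
        taps = signal.firwin(int(round(0.2 * fs)) | 1, 125.0, fs=fs)
        clean = signal.fftconvolve(clean, taps[None, :], mode="same", axes=1)
        if with_stim:
            artifact = signal.fftconvolve(artifact, taps[None, :], mode="same", axes=1)

    # --- auxiliary channels ---------------------------------------------
    audio = cfg.audio_noise * rng.standard_normal(n_samples)
    width = max(1, int(round(cfg.audio_pulse_width * fs)))
    n_cycles = (
        int(np.floor(cfg.trial_len * cfg.f_ssvep)) if cfg.audio_pulse_per_cycle else 1
    )
    cycle_samp = fs / cfg.f_ssvep
    for on in onsets:
        for k in range(n_cycles):
            st = on + int(round(k * cycle_samp))
            audio[st : st + width] += cfg.audio_pulse_height

    rows = [clean + artifact, audio[None, :]]
    labels = list(MONTAGE_64_LABELS) + ["audio"]
    types = ["eeg"] * 64 + ["misc"]
    if cfg.heartbeat.enabled:
        rows.append(ecg[None, :])
        labels.append("ECG")
        types.append("ecg")
    data = np.vstack(rows)
    events = [(int(on), "Stimulus/S  1") for on in onsets]
    rec = Recording(labels, types, fs, data, events=events)
    truth = SynthTruth(
        clean_data=clean,
        artifact_data=artifact,
        trial_onsets=onsets,
        true_trial_phase=phases,
        true_trial_amplitude=amps,
        r_peak_samples=r_peaks,
        modulation_envelope=mod,
        artifact_band_rank=band_rank,
    )
    return rec, truth
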