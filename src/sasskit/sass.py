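"""Stimulation Artifact Source Separation (SASS).

SASS removes tACS artifacts from EEG by exploiting a pair of recordings:
one during stimulation and one without.  Sensor covariance matrices ``A``
(stimulation) and ``B`` (no stimulation) of narrowband-filtered data are
jointly diagonalized by solving the generalized eigenproblem

    A w_i = lambda_i B w_i,      lambda_i = (w_i' A w_i) / (w_i' B w_i).

Each eigenvalue is the power ratio of its component with versus without
stimulation, so artifact components carry the largest eigenvalues.  Stacking
the eigenvector rows into ``W`` (sorted by descending eigenvalue), the
projection

    P = pinv(W) @ S @ W

with a diagonal selector ``S`` that zeroes the top ``k`` components removes
the artifact subspace while leaving the remaining components untouched.
``k`` is chosen automatically so that the mean squared difference of
per-sensor narrowband power between the cleaned stimulation data and the
no-stimulation data is minimal.

Because electrode nonlinearities give every artifact harmonic its own
topography, SASS is fitted separately per frequency band when several
harmonics must be cleaned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .exceptions import ChannelMismatchError, DegenerateDataError, SasskitError
from .io import Recording
from .spectral import BandSpec, fir_bandpass

__all__ = [
    "CovariancePair",
    "SassModel",
    "compute_covariance",
    "joint_diagonalize",
    "build_projection",
    "select_k",
    "sass_fit",
    "sass_apply",
    "sass_multiband",
    "sass_apply_multiband",
]


def compute_covariance(data: np.ndarray) -> np.ndarray:
    """Unregularized sample covariance (channels x channels, ddof = 1)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if not np.all(np.isfinite(data)):
        raise SasskitError("covariance input contains non-finite samples")
    n_ch, n_samp = data.shape
    if n_samp <= n_ch:
        warnings.warn(
            f"covariance from {n_samp} samples over {n_ch} channels is rank-deficient",
            stacklevel=2,
        )
    centered = data - data.mean(axis=1, keepdims=True)
    return centered @ centered.T / max(n_samp - 1, 1)


@dataclass
class CovariancePair:
    """Covariances during (`A`) and in absence of (`B`) stimulation."""

    A: np.ndarray
    B: np.ndarray
    channel_labels: list = field(default_factory=list)
    band: BandSpec | None = None

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.A.shape != self.B.shape or self.A.shape[0] != self.A.shape[1]:
            raise ChannelMismatchError("A and B must be square with equal shapes")
        for name, M in (("A", self.A), ("B", self.B)):
            if not np.allclose(M, M.T, atol=1e-10 * max(1.0, np.abs(M).max())):
                raise SasskitError(f"covariance {name} is not symmetric")

    @property
    def n_channels(self) -> int:
        return self.A.shape[0]


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each eigenvector row positive."""
    idx = np.argmax(np.abs(W), axis=1)
    signs = np.sign(W[np.arange(W.shape[0]), idx])
    signs[signs == 0] = 1.0
    return W * signs[:, None]


def joint_diagonalize(pair: CovariancePair):
    """Solve ``A w = lambda B w``; rows of ``W`` sorted by descending lambda.

    ``B`` must be positive definite.  The eigenvectors are B-orthonormal
    (``W B W' = I``) so ``W A W' = diag(lambda)``.
    """
    try:
        lam, vecs = linalg.eigh(pair.A, pair.B)
    except linalg.LinAlgError as exc:
        raise DegenerateDataError(
            "no-stimulation covariance is singular; record more data without "
            "stimulation or widen the analysis band"
        ) from exc
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    W = _fix_signs(vecs[:, order].T)
    return W, lam


def build_projection(W: np.ndarray, k_reject: int) -> np.ndarray:
    """``P = pinv(W) S W`` with ``S`` zeroing the first ``k_reject`` rows.

    Rows of ``W`` are assumed sorted by descending eigenvalue, so the nulled
    components are the strongest artifact carriers.  ``P`` is idempotent
    with rank ``n - k_reject`` and annihilates the rejected components'
    spatial patterns (the corresponding columns of ``pinv(W)``).
    """
    n = W.shape[0]
    if not 0 <= k_reject <= n:
        raise ValueError(f"k_reject must lie in [0, {n}]")
    if k_reject == n:
        warnings.warn("rejecting every component: projection is zero", stacklevel=2)
    if k_reject == 0:
        return np.eye(n)
    s = np.ones(n)
    s[:k_reject] = 0.0
    Winv = _pinv(W)
    return (Winv * s[None, :]) @ W


def _pinv(W: np.ndarray) -> np.ndarray:
    return np.linalg.pinv(W, rcond=1e-12)


def spatial_patterns(W: np.ndarray) -> np.ndarray:
    """Columns of ``pinv(W)``: each component's sensor-space footprint."""
    return _pinv(W)


def select_k(
    stim_band_data: np.ndarray,
    nostim_band_data: np.ndarray,
    W: np.ndarray,
    return_criterion: bool = False,
):
    """Number of components to reject.

    For each candidate ``k`` the stimulation data are cleaned with ``P_k``
    and the criterion is the mean over sensors of the squared difference
    between per-sensor narrowband power (variance of the band-filtered
    signal) of cleaned-stimulation and no-stimulation data.  Returns the
    ``k`` minimizing the criterion; ties break toward smaller ``k``.
    """
    A = compute_covariance(stim_band_data)
    pow_nostim = np.var(np.atleast_2d(nostim_band_data), axis=1, ddof=1)
    n = W.shape[0]
    crit = np.empty(n + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # k = n is a legitimate sweep endpoint
        for k in range(n + 1):
            P = build_projection(W, k)
            pow_clean = np.diag(P @ A @ P.T)
            crit[k] = np.mean((pow_clean - pow_nostim) ** 2)
    k_best = int(np.argmin(crit))  # argmin returns the first (smallest) tie
    return (k_best, crit) if return_criterion else k_best


@dataclass
class SassModel:
    """A fitted SASS projection for one frequency band."""

    W: np.ndarray
    eigenvalues: np.ndarray
    k_reject: int
    channel_labels: list
    band: BandSpec
    patterns: np.ndarray = None
    P: np.ndarray = None
    criterion: np.ndarray = None

    def __post_init__(self):
        if self.patterns is None:
            self.patterns = spatial_patterns(self.W)
        if self.P is None:
            self.P = build_projection(self.W, self.k_reject)

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]

    @property
    def selector(self) -> np.ndarray:
        s = np.ones(self.n_channels)
        s[: self.k_reject] = 0.0
        return np.diag(s)

    def eigen_spectrum(self) -> np.ndarray:
        """Eigenvalues = per-component stimulation/no-stimulation power ratio."""
        return self.eigenvalues.copy()


def sass_fit(
    nostim: Recording,
    stim: Recording,
    band: BandSpec = BandSpec(),
) -> SassModel:
    """Fit SASS from a session pair.

    Both continuous recordings are band-pass filtered, the covariance pair
    is formed from the EEG channels, jointly diagonalized, and the rejected
    component count selected by the power-matching criterion.
    """
    if nostim.eeg_labels != stim.eeg_labels:
        raise ChannelMismatchError("session pair has different EEG channel sets")
    nostim_f = fir_bandpass(nostim.eeg_data(), nostim.fs, band)
    stim_f = fir_bandpass(stim.eeg_data(), stim.fs, band)
    pair = CovariancePair(
        A=compute_covariance(stim_f),
        B=compute_covariance(nostim_f),
        channel_labels=stim.eeg_labels,
        band=band,
    )
    W, lam = joint_diagonalize(pair)
    k, crit = select_k(stim_f, nostim_f, W, return_criterion=True)
    return SassModel(
        W=W,
        eigenvalues=lam,
        k_reject=k,
        channel_labels=list(stim.eeg_labels),
        band=band,
        criterion=crit,
    )


def sass_apply(model: SassModel, data, channel_labels=None):
    """Apply the projection to channels x samples data (or a Recording).

    Linear and idempotent; with ``k_reject = 0`` it is the identity.
    """
    if isinstance(data, Recording):
        if data.eeg_labels != model.channel_labels:
            raise ChannelMismatchError("recording channels do not match the model")
        return model.P @ data.eeg_data()
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if channel_labels is not None and list(channel_labels) != model.channel_labels:
        raise ChannelMismatchError("channel labels do not match the model")
    if data.shape[0] != model.n_channels:
        raise ChannelMismatchError(
            f"data has {data.shape[0]} channels, model expects {model.n_channels}"
        )
    return model.P @ data


def sass_multiband(
    nostim: Recording,
    stim: Recording,
    centers,
    half_width: float = 1.0,
    filter_dur: float = 1.65,
):
    """Fit one SASS model per artifact frequency (e.g. envelope harmonics).

    Artifact topographies are frequency-dependent, so a separate projection
    is computed for every band.  Overlapping bands trigger a warning.
    """
    centers = sorted(centers)
    for lo, hi in zip(centers[:-1], centers[1:]):
        if hi - lo < 2 * half_width:
            warnings.warn(
                f"bands at {lo} and {hi} Hz overlap (half-width {half_width} Hz)",
                stacklevel=2,
            )
    return [
        sass_fit(nostim, stim, BandSpec(c, half_width, filter_dur)) for c in centers
    ]


def sass_apply_multiband(models, data, fs: float):
    """Clean a broadband signal with per-band projections.

    Filter-bank scheme: each band component is extracted, its rejected part
    ``(I - P_b)`` subtracted from the broadband signal, and everything
    outside the fitted bands passes through unchanged.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    out = data.copy()
    for model in models:
        band_part = fir_bandpass(data, fs, model.band)
        out -= (np.eye(model.n_channels) - model.P) @ band_part
    return out
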