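import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sasskit.exceptions import ChannelMismatchError
from sasskit.sass import (
    CovariancePair,
    SassModel,
    build_projection,
    compute_covariance,
    joint_diagonalize,
    sass_apply,
    sass_apply_multiband,
    sass_fit,
    sass_multiband,
    select_k,
)
from sasskit.spectral import BandSpec, fir_bandpass
from sasskit.synth import NoiseConfig, SynthConfig, generate_session


def random_spd(rng, n, dof=None):
    x = rng.standard_normal((n, (dof or 4 * n)))
    return x @ x.T / x.shape[1]


def whitening_oracle(A, B):
    """Independent GEVD: whiten by B^{-1/2}, ordinary eigh, transform back."""
    evals, evecs = np.linalg.eigh(B)
    Bm12 = evecs @ np.diag(evals**-0.5) @ evecs.T
    lam, V = np.linalg.eigh(Bm12 @ A @ Bm12)
    order = np.argsort(lam)[::-1]
    return (Bm12 @ V[:, order]).T, lam[order]


class TestCovariance:
    def test_constant_channel_zero_row(self, rng):
        data = rng.standard_normal((3, 1000))
        data[1] = 7.0
        C = compute_covariance(data)
        assert np.all(C[1] == 0) and np.all(C[:, 1] == 0)

    def test_duplicated_channel_rank_deficient(self, rng):
        data = rng.standard_normal((3, 1000))
        data[2] = data[0]
        C = compute_covariance(data)
        assert np.linalg.eigvalsh(C)[0] < 1e-10

    def test_white_noise_off_diagonals_small(self, rng):
        C = compute_covariance(rng.standard_normal((6, 100_000)))
        off = C[~np.eye(6, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_matches_numpy_cov(self, rng):
        data = rng.standard_normal((4, 500))
        np.testing.assert_allclose(compute_covariance(data), np.cov(data), atol=1e-12)


class TestJointDiagonalize:
    def test_equal_matrices_give_unit_eigenvalues(self, rng):
        B = random_spd(rng, 5)
        W, lam = joint_diagonalize(CovariancePair(B, B))
        np.testing.assert_allclose(lam, 1.0, atol=1e-10)

    def test_diagonal_closed_form(self):
        A = np.diag([4.0, 1.0])
        W, lam = joint_diagonalize(CovariancePair(A, np.eye(2)))
        np.testing.assert_allclose(lam, [4.0, 1.0])
        np.testing.assert_allclose(np.abs(W), np.eye(2), atol=1e-12)

    @pytest.mark.parametrize("n", [4, 6, 10, 16])
    def test_whitening_oracle_agreement(self, rng, n):
        A = random_spd(rng, n)
        B = random_spd(rng, n)
        W, lam = joint_diagonalize(CovariancePair(A, B))
        Wo, lamo = whitening_oracle(A, B)
        np.testing.assert_allclose(lam, lamo, rtol=1e-8)
        for w, wo in zip(W, Wo):
            cos = abs(w @ wo) / (np.linalg.norm(w) * np.linalg.norm(wo))
            assert cos > 1 - 1e-8

    def test_eigen_identities(self, rng):
        A, B = random_spd(rng, 8), random_spd(rng, 8)
        W, lam = joint_diagonalize(CovariancePair(A, B))
        for w, l in zip(W, lam):
            resid = np.linalg.norm(A @ w - l * (B @ w)) / np.linalg.norm(A @ w)
            assert resid < 1e-8
            np.testing.assert_allclose(l, (w @ A @ w) / (w @ B @ w), rtol=1e-10)
        # W B W' = I for eigh-based GEVD
        np.testing.assert_allclose(W @ B @ W.T, np.eye(8), atol=1e-8)

    def test_sign_convention_reproducible(self, rng):
        A, B = random_spd(rng, 6), random_spd(rng, 6)
        W1, _ = joint_diagonalize(CovariancePair(A, B))
        W2, _ = joint_diagonalize(CovariancePair(A.copy(), B.copy()))
        np.testing.assert_array_equal(W1, W2)
        idx = np.argmax(np.abs(W1), axis=1)
        assert np.all(W1[np.arange(6), idx] > 0)


class TestProjection:
    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 8), st.integers(0, 10_000))
    def test_idempotent_and_rank(self, k, seed):
        rng = np.random.default_rng(seed)
        W = rng.standard_normal((8, 8)) + 4 * np.eye(8)
        P = build_projection(W, k)
        assert np.linalg.norm(P @ P - P) < 1e-8
        assert np.linalg.matrix_rank(P, tol=1e-8) == 8 - k

    def test_k0_identity_and_kn_zero(self, rng):
        W = rng.standard_normal((5, 5)) + 3 * np.eye(5)
        np.testing.assert_array_equal(build_projection(W, 0), np.eye(5))
        with pytest.warns(UserWarning):
            P = build_projection(W, 5)
        assert np.allclose(P, 0)

    def test_annihilates_rejected_subspace(self, rng):
        """An artifact confined to the span of the rejected components'
        spatial patterns is removed to numerical precision."""
        n, k = 8, 2
        W = rng.standard_normal((n, n)) + 4 * np.eye(n)
        P = build_projection(W, k)
        patterns = np.linalg.pinv(W)[:, :k]
        clean = rng.standard_normal((n, 500))
        artifact = patterns @ rng.standard_normal((k, 500))
        resid = np.linalg.norm(P @ (clean + artifact) - P @ clean)
        assert resid / np.linalg.norm(clean) < 1e-6


class TestSelectK:
    def test_identical_data_selects_zero(self, rng):
        data = rng.standard_normal((4, 5000))
        W, _ = joint_diagonalize(
            CovariancePair(compute_covariance(data), compute_covariance(data))
        )
        assert select_k(data, data, W) == 0

    def test_rank_one_artifact_selects_one(self, rng):
        n = 6
        nostim = rng.standard_normal((n, 20_000))
        stim = rng.standard_normal((n, 20_000))
        pattern = rng.standard_normal(n)
        stim = stim + 50 * np.outer(pattern, np.sin(np.arange(20_000) * 0.1))
        W, _ = joint_diagonalize(
            CovariancePair(compute_covariance(stim), compute_covariance(nostim))
        )
        k, crit = select_k(stim, nostim, W, return_criterion=True)
        assert k == 1
        assert crit[1] < 1e-3 * crit[0]

    def test_criterion_matches_bruteforce(self, rng):
        """The covariance-based criterion equals explicitly projecting the
        time series and measuring per-sensor variance."""
        n = 5
        stim = rng.standard_normal((n, 4000))
        nostim = rng.standard_normal((n, 4000))
        W, _ = joint_diagonalize(
            CovariancePair(compute_covariance(stim), compute_covariance(nostim))
        )
        _, crit = select_k(stim, nostim, W, return_criterion=True)
        pow_ns = np.var(nostim, axis=1, ddof=1)
        import warnings

        for k in range(n + 1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cleaned = build_projection(W, k) @ stim
            brute = np.mean((np.var(cleaned, axis=1, ddof=1) - pow_ns) ** 2)
            np.testing.assert_allclose(crit[k], brute, rtol=1e-8)


class TestFitApply:
    def test_identical_statistics_select_zero_and_identity(self):
        """When stimulation adds nothing the criterion is already minimal at
        k = 0 and the projection is the identity (exact for equal data)."""
        cfg = SynthConfig(n_trials=12, seed=9, artifact_gain=0.0)
        rec0, _ = generate_session(cfg, with_stim=False)
        model = sass_fit(rec0, rec0, BandSpec(10, 1))
        assert model.k_reject == 0
        np.testing.assert_array_equal(model.P, np.eye(64))

    def test_no_artifact_projection_is_harmless(self):
        """On an independent artifact-free pair, finite-sample power matching
        may still null a couple of noise directions, but the SSVEP metrics
        survive essentially unchanged."""
        from sasskit.events import EventSeries
        from sasskit.spectral import trial_phase_amplitude

        cfg = SynthConfig(n_trials=12, seed=9, artifact_gain=0.0)
        rec0, _ = generate_session(cfg, with_stim=False)
        rec1, tr1 = generate_session(cfg, with_stim=True)
        model = sass_fit(rec0, rec1, BandSpec(10, 1))
        assert model.k_reject <= 4
        ev = EventSeries(tr1.trial_onsets, cfg.fs)
        m_proj = trial_phase_amplitude(rec1, ev, BandSpec(10, 1), projection=model.P)
        m_raw = trial_phase_amplitude(rec1, ev, BandSpec(10, 1))
        assert np.corrcoef(m_proj.amplitude, m_raw.amplitude)[0, 1] > 0.85

    def test_eigenvalue_spectrum_shape(self, quick_model):
        lam = quick_model.eigen_spectrum()
        assert lam[0] > 1e3  # artifact component towers over the rest
        assert lam[0] / lam[1] > 100  # sharp decay after the artifact
        assert np.all(np.diff(lam) <= 1e-9)  # sorted descending

    def test_apply_idempotent_and_k0_identity(self, quick_pair, quick_model):
        _, _, (rec1, _) = quick_pair
        once = sass_apply(quick_model, rec1)
        twice = quick_model.P @ once
        np.testing.assert_allclose(twice, once, atol=1e-8 * np.abs(once).max())
        m0 = SassModel(
            W=quick_model.W,
            eigenvalues=quick_model.eigenvalues,
            k_reject=0,
            channel_labels=quick_model.channel_labels,
            band=quick_model.band,
        )
        np.testing.assert_array_equal(sass_apply(m0, rec1), rec1.eeg_data())

    def test_channel_mismatch_errors(self, quick_model, rng):
        with pytest.raises(ChannelMismatchError):
            sass_apply(quick_model, rng.standard_normal((5, 100)))

    def test_cleaned_band_power_within_3db_of_nostim(self, quick_pair, quick_model):
        """Occipital 10 Hz power after cleaning approaches the no-stim level."""
        cfg, (rec0, _), (rec1, _) = quick_pair
        from sasskit.spectral import virtual_channel

        band = BandSpec(10, 1)
        v0 = virtual_channel(fir_bandpass(rec0.eeg_data(), cfg.fs, band), rec0.eeg_labels)
        v1 = virtual_channel(
            fir_bandpass(sass_apply(quick_model, rec1), cfg.fs, band), rec1.eeg_labels
        )
        ratio_db = 10 * np.log10(np.var(v1) / np.var(v0))
        assert abs(ratio_db) < 3.0


class TestMultiband:
    def test_single_center_matches_sass_fit(self, quick_pair):
        cfg, (rec0, _), (rec1, _) = quick_pair
        models = sass_multiband(rec0, rec1, [10.0])
        direct = sass_fit(rec0, rec1, BandSpec(10, 1))
        np.testing.assert_allclose(models[0].P, direct.P, atol=1e-10)

    def test_harmonic_topographies_differ(self):
        """Distinct nonlinearity mixes at 10 vs 20 Hz give the two bands'
        dominant artifact patterns low cosine similarity."""
        rng = np.random.default_rng(0)
        c2 = 0.05 * rng.uniform(0.2, 1.0, 64)
        cr = np.where(np.arange(64) < 32, 0.3, 0.01)  # rectifier on one side
        cfg = SynthConfig(n_trials=30, seed=6, nonlin_c2=c2, nonlin_cr=cr)
        rec0, _ = generate_session(cfg, with_stim=False)
        rec1, _ = generate_session(cfg, with_stim=True)
        m10, m20 = sass_multiband(rec0, rec1, [10.0, 20.0])
        p10 = m10.patterns[:, 0] / np.linalg.norm(m10.patterns[:, 0])
        p20 = m20.patterns[:, 0] / np.linalg.norm(m20.patterns[:, 0])
        assert abs(p10 @ p20) < 0.9

    def test_filter_bank_recombination(self, quick_pair):
        """Multiband cleaning of a band-limited signal agrees with cleaning
        that band alone, up to filter-bank reconstruction error."""
        cfg, (rec0, _), (rec1, _) = quick_pair
        models = sass_multiband(rec0, rec1, [10.0])
        # artifact-free input so the bound reflects pure filter-bank error
        band_sig = fir_bandpass(rec0.eeg_data(), cfg.fs, BandSpec(10, 1))
        combined = sass_apply_multiband(models, band_sig, cfg.fs)
        direct = models[0].P @ band_sig
        scale = np.sqrt(np.mean(direct**2))
        assert np.sqrt(np.mean((combined - direct) ** 2)) < 0.1 * scale

    def test_overlapping_bands_warn(self, quick_pair):
        cfg, (rec0, _), (rec1, _) = quick_pair
        with pytest.warns(UserWarning, match="overlap"):
            sass_multiband(rec0, rec1, [10.0, 11.0])
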