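"""ASR core: PSD square root, calibration statistics, window rejection."""

import numpy as np
import pytest

from easr import (
    ASRParameters,
    ASRState,
    CalibrationError,
    DimensionError,
    InsufficientDataError,
    NumericDomainError,
    asr_calibrate,
    asr_process,
    matrix_sqrt_psd,
)

FS = 100.0


def white_noise_matrix(rng, n_channels=8, seconds=60.0, fs=FS):
    return rng.standard_normal((n_channels, int(seconds * fs)))


class TestMatrixSqrtPsd:
    def test_identity(self):
        np.testing.assert_allclose(matrix_sqrt_psd(np.eye(4)), np.eye(4), atol=1e-12)

    def test_diagonal(self):
        np.testing.assert_allclose(
            matrix_sqrt_psd(np.diag([4.0, 9.0])), np.diag([2.0, 3.0]), atol=1e-12
        )

    def test_random_psd_square_root(self, rng):
        A = rng.normal(size=(6, 6))
        C = A @ A.T
        S = matrix_sqrt_psd(C)
        assert np.linalg.norm(S @ S.T - C) < 1e-8 * np.linalg.norm(C)
        np.testing.assert_allclose(S, S.T, atol=1e-10)

    def test_non_symmetric_rejected(self):
        with pytest.raises(NumericDomainError):
            matrix_sqrt_psd(np.array([[1.0, 2.0], [0.0, 1.0]]))

    def test_indefinite_rejected(self):
        with pytest.raises(NumericDomainError):
            matrix_sqrt_psd(np.diag([1.0, -1.0]))


class TestCalibrate:
    def test_white_noise_keeps_nearly_all_windows(self, rng):
        X = white_noise_matrix(rng)
        state = asr_calibrate(X, fs=FS)
        assert state.n_calib_windows_used >= 0.9 * 60

    def test_state_invariants(self, rng):
        X = white_noise_matrix(rng)
        state = asr_calibrate(X, fs=FS)
        # V_C orthonormal
        np.testing.assert_allclose(
            state.eigvecs.T @ state.eigvecs, np.eye(8), atol=1e-8
        )
        # mixing is a symmetric PSD square root
        np.testing.assert_allclose(state.mixing, state.mixing.T, atol=1e-10)
        assert np.linalg.eigvalsh(state.mixing).min() > -1e-10
        assert (state.thresholds > 0).all()
        # threshold matrix structure T = diag(T_i) V_C^T
        np.testing.assert_allclose(
            state.threshold_matrix, np.diag(state.thresholds) @ state.eigvecs.T,
            atol=1e-10,
        )

    def test_mixing_reproduces_calibration_covariance(self, rng):
        X = white_noise_matrix(rng, seconds=30.0)
        # z-screen disabled so the calibration data is the whole (trimmed)
        # recording and the expected covariance is unambiguous
        state = asr_calibrate(X, fs=FS, params=ASRParameters(z_low=-1e9, z_high=1e9))
        assert state.n_calib_windows_used == 30
        trimmed = X[:, : 30 * int(FS)]
        centred = trimmed - trimmed.mean(axis=1, keepdims=True)
        C = centred @ centred.T / centred.shape[1]
        assert (
            np.linalg.norm(state.mixing @ state.mixing.T - C)
            < 1e-8 * np.linalg.norm(C)
        )

    def test_gross_outlier_window_is_excluded(self, rng):
        X = white_noise_matrix(rng)
        burst = X.copy()
        burst[:, 1000:1100] *= 100.0
        clean_state = asr_calibrate(X, fs=FS)
        burst_state = asr_calibrate(burst, fs=FS)
        assert burst_state.n_calib_windows_used < clean_state.n_calib_windows_used
        # exclusion keeps the thresholds at the clean level (the component
        # bases differ slightly, so compare summary levels, not element-wise)
        assert burst_state.thresholds.max() == pytest.approx(
            clean_state.thresholds.max(), rel=0.5
        )
        # without the z-screen the outlier inflates the calibration covariance
        no_screen = asr_calibrate(
            burst, fs=FS, params=ASRParameters(z_low=-1e9, z_high=1e9)
        )
        assert no_screen.max_calib_variance > 2 * burst_state.max_calib_variance

    def test_thresholds_grow_linearly_in_k(self, rng):
        X = white_noise_matrix(rng, seconds=30.0)
        t1 = asr_calibrate(X, fs=FS, params=ASRParameters(cutoff_k=10)).thresholds
        t2 = asr_calibrate(X, fs=FS, params=ASRParameters(cutoff_k=20)).thresholds
        t3 = asr_calibrate(X, fs=FS, params=ASRParameters(cutoff_k=30)).thresholds
        np.testing.assert_allclose(t3 - t2, t2 - t1, rtol=1e-9)

    def test_no_clean_window_raises_with_informative_message(self, rng):
        X = white_noise_matrix(rng, seconds=10.0)
        params = ASRParameters(z_low=-1e-6, z_high=1e-6)
        with pytest.raises(CalibrationError, match="z-score"):
            asr_calibrate(X, fs=FS, params=params)

    def test_too_short_raises(self, rng):
        with pytest.raises(InsufficientDataError):
            asr_calibrate(rng.standard_normal((4, 150)), fs=FS)

    def test_one_row_rejected(self, rng):
        with pytest.raises(DimensionError):
            asr_calibrate(rng.standard_normal((1, 1000)), fs=FS)

    def test_save_load_round_trip(self, rng, tmp_path):
        state = asr_calibrate(white_noise_matrix(rng, seconds=20.0), fs=FS)
        path = state.save(tmp_path / "state.npz")
        back = ASRState.load(path)
        np.testing.assert_array_equal(back.mixing, state.mixing)
        np.testing.assert_array_equal(back.thresholds, state.thresholds)
        assert back.n_calib_windows_used == state.n_calib_windows_used


class TestProcess:
    def test_identity_when_nothing_flagged(self, rng):
        X = white_noise_matrix(rng)
        params = ASRParameters(cutoff_k=1e6)
        state = asr_calibrate(X, fs=FS, params=params)
        out = asr_process(X, state, params=params, fs=FS)
        np.testing.assert_allclose(out, X, rtol=0, atol=1e-6 * np.abs(X).max())

    def test_full_rank_pseudoinverse_identity(self, rng):
        # with no truncation the Eq.-6 operator collapses to the identity
        X = white_noise_matrix(rng, seconds=20.0)
        state = asr_calibrate(X, fs=FS)
        V = np.linalg.eigh((X @ X.T) / X.shape[1])[1]
        R = state.mixing @ np.linalg.pinv(V.T @ state.mixing) @ V.T
        np.testing.assert_allclose(R, np.eye(8), atol=1e-8)

    def test_everything_flagged_zeroes_the_window(self, rng):
        X = white_noise_matrix(rng, seconds=20.0)
        params = ASRParameters(max_dims=1.0, blend_windows=False)
        state = asr_calibrate(X, fs=FS, params=params)
        wild = X.copy()
        wild[:, 200:250] += 1e7 * rng.standard_normal((8, 50))
        out = asr_process(wild, state, params=params, fs=FS)
        window = slice(200, 250)
        assert np.abs(out[:, window]).max() < 1e-6 * np.abs(wild[:, window]).max()

    def test_burst_suppressed_clean_windows_untouched(self, rng):
        X = white_noise_matrix(rng)
        state = asr_calibrate(X, fs=FS)
        contaminated = X.copy()
        burst = slice(1000, 1050)                   # inside window 20
        contaminated[0, burst] += 20.0 * np.abs(contaminated[0, burst]).max()
        params = ASRParameters(blend_windows=False)
        out = asr_process(contaminated, state, params=params, fs=FS)
        assert out[:, burst].var() < 0.5 * contaminated[:, burst].var()
        control = slice(3000, 3050)                 # far from the burst
        np.testing.assert_allclose(
            out[:, control], contaminated[:, control],
            atol=1e-6 * np.abs(X).max(),
        )

    def test_output_shape_matches_input_with_partial_window(self, rng):
        X = white_noise_matrix(rng, seconds=20.0)
        state = asr_calibrate(X, fs=FS)
        oddly_sized = X[:, : 1575]                  # 31.5 processing windows
        out = asr_process(oddly_sized, state, fs=FS)
        assert out.shape == oddly_sized.shape

    def test_scaling_equivariance(self, rng):
        X = white_noise_matrix(rng, seconds=30.0)
        X[0, 500:550] += 15.0                        # something to flag
        out1 = asr_process(X, asr_calibrate(X, fs=FS), fs=FS)
        c = 37.5
        out2 = asr_process(c * X, asr_calibrate(c * X, fs=FS), fs=FS)
        np.testing.assert_allclose(out2, c * out1, rtol=1e-7, atol=1e-8)

    def test_negation_equivariance(self, rng):
        X = white_noise_matrix(rng, seconds=30.0)
        X[0, 500:550] += 15.0
        out = asr_process(X, asr_calibrate(X, fs=FS), fs=FS)
        out_neg = asr_process(-X, asr_calibrate(-X, fs=FS), fs=FS)
        np.testing.assert_allclose(out_neg, -out, rtol=1e-7, atol=1e-8)

    def test_reconstruction_invariant_to_eigvec_sign_flips(self, rng):
        # Eq.-6 oracle: flipping eigenvector signs leaves the operator unchanged
        X = white_noise_matrix(rng, seconds=20.0)
        state = asr_calibrate(X, fs=FS)
        W = X[:, :50]
        _, V = np.linalg.eigh((W @ W.T) / 50)
        keep = np.array([True] * 6 + [False] * 2)

        def operator(Vmat):
            S = (Vmat.T @ state.mixing) * keep[:, None]
            return state.mixing @ np.linalg.pinv(S) @ Vmat.T

        flips = np.diag(rng.choice([-1.0, 1.0], size=8))
        np.testing.assert_allclose(operator(V), operator(V @ flips), atol=1e-8)

    def test_channel_mismatch_rejected(self, rng):
        state = asr_calibrate(white_noise_matrix(rng, seconds=20.0), fs=FS)
        with pytest.raises(DimensionError):
            asr_process(rng.standard_normal((5, 1000)), state, fs=FS)

    def test_shorter_than_one_window_rejected(self, rng):
        state = asr_calibrate(white_noise_matrix(rng, seconds=20.0), fs=FS)
        with pytest.raises(InsufficientDataError):
            asr_process(rng.standard_normal((8, 10)), state, fs=FS)
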