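"""Time-series conditioning: detrending, filtering, smoothing, normalization."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from hyperbold.preprocess import (
    FWHM_TO_SIGMA,
    NuisanceSet,
    bandpass,
    concatenate_runs,
    detrend_poly,
    normalize_voxelwise,
    regress_nuisance,
    smooth_gaussian,
)
from hyperbold.volio import Mask3D

from conftest import make_series


class TestDetrendPoly:
    def test_polynomial_annihilation(self):
        t = np.linspace(-1, 1, 50)
        cubic = 3.0 + 2.0 * t - t**2 + 0.5 * t**3
        series = make_series(np.broadcast_to(cubic, (2, 2, 1, 50)).copy())
        out = detrend_poly(series, order=5)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_constant_removed_at_order_zero(self):
        series = make_series(np.full((2, 2, 1, 20), 7.0))
        np.testing.assert_allclose(detrend_poly(series, order=0).data, 0.0, atol=1e-12)

    def test_noisy_linear_drift_vs_regression_oracle(self, rng):
        """Residuals match an explicit least-squares line fit on one voxel."""
        n = 60
        t = np.linspace(-1, 1, n)
        y = 5.0 + 2.0 * t + rng.normal(0, 0.5, n)
        series = make_series(y.reshape(1, 1, 1, n))
        out = detrend_poly(series, order=1).data.ravel()
        X = np.column_stack([np.ones(n), t])
        resid_oracle = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(out, resid_oracle, atol=1e-10)
        # residual slope is zero
        assert np.polyfit(t, out, 1)[0] == pytest.approx(0.0, abs=1e-10)

    def test_zero_mean_residuals(self, rng):
        series = make_series(rng.normal(size=(3, 3, 2, 40)))
        out = detrend_poly(series, order=3)
        np.testing.assert_allclose(out.data.mean(axis=3), 0.0, atol=1e-12)

    def test_degenerate_length_rejected(self):
        with pytest.raises(ValueError):
            detrend_poly(make_series(np.zeros((1, 1, 1, 5))), order=5)


class TestBandpass:
    def _sinusoid_series(self, freq_hz, n=400, tr=1.5):
        t = np.arange(n) * tr
        y = np.sin(2 * np.pi * freq_hz * t)
        return make_series(np.broadcast_to(y, (2, 1, 1, n)).copy(), tr_s=tr)

    def test_passband_amplitude_preserved(self):
        """0.05 Hz sinusoid amplitude preserved within 5% (FFT oracle)."""
        series = self._sinusoid_series(0.05)
        out = bandpass(series, 0.01, 0.1)
        amp_in = _fft_amplitude(series.data[0, 0, 0], 0.05, 1.5)
        amp_out = _fft_amplitude(out.data[0, 0, 0], 0.05, 1.5)
        assert amp_out == pytest.approx(amp_in, rel=0.05)

    def test_stopband_attenuated(self):
        """0.3 Hz sinusoid reduced by at least 90%."""
        series = self._sinusoid_series(0.3)
        out = bandpass(series, 0.01, 0.1)
        amp_in = _fft_amplitude(series.data[0, 0, 0], 0.3, 1.5)
        amp_out = _fft_amplitude(out.data[0, 0, 0], 0.3, 1.5)
        assert amp_out <= 0.1 * amp_in

    def test_dc_removed(self, rng):
        series = make_series(100.0 + rng.normal(size=(2, 2, 1, 200)))
        out = bandpass(series, 0.01, 0.1)
        np.testing.assert_allclose(out.data.mean(axis=3), 0.0, atol=1e-8)

    def test_band_invalid_for_tr_rejected(self):
        series = make_series(np.zeros((1, 1, 1, 50)), tr_s=1.5)
        with pytest.raises(ValueError, match="band"):
            bandpass(series, 0.01, 0.5)  # Nyquist is 1/3 Hz


def _fft_amplitude(y, freq_hz, tr):
    freqs = np.fft.rfftfreq(len(y), d=tr)
    spec = np.abs(np.fft.rfft(y))
    return spec[np.argmin(np.abs(freqs - freq_hz))]


class TestSmoothGaussian:
    def test_zero_fwhm_identity(self, rng):
        series = make_series(rng.normal(size=(5, 5, 4, 3)))
        np.testing.assert_array_equal(smooth_gaussian(series, 0.0).data, series.data)

    def test_impulse_matches_brute_force_convolution(self):
        """Peak of a smoothed impulse equals the renormalized kernel center."""
        data = np.zeros((9, 9, 9, 1))
        data[4, 4, 4, 0] = 1.0
        series = make_series(data, voxel=(1.0, 1.0, 1.0))
        out = smooth_gaussian(series, fwhm_mm=2.0)
        sigma = 2.0 * FWHM_TO_SIGMA
        num = gaussian_filter(data[..., 0], sigma=sigma, mode="constant")
        den = gaussian_filter(np.ones((9, 9, 9)), sigma=sigma, mode="constant")
        np.testing.assert_allclose(out.data[..., 0], num / den, rtol=1e-8)

    def test_constant_in_mask_unchanged(self, small_mask):
        data = np.where(small_mask.data, 42.0, 0.0)[..., np.newaxis]
        series = make_series(data)
        out = smooth_gaussian(series, 1.5, small_mask)
        np.testing.assert_allclose(out.data[small_mask.data], 42.0, rtol=1e-10)

    def test_in_mask_mean_nearly_conserved(self, rng, small_mask):
        """The renormalized kernel averages within the mask: it reproduces
        constants exactly and perturbs the in-mask mean of a noisy field by
        far less than the field's own SD."""
        series = make_series(rng.normal(100, 5, size=small_mask.data.shape + (2,)))
        out = smooth_gaussian(series, 2.0, small_mask)
        for t in range(2):
            drift = abs(
                out.data[small_mask.data, t].mean()
                - series.data[small_mask.data, t].mean()
            )
            assert drift < 0.05 * series.data[small_mask.data, t].std()

    def test_matches_nilearn_reference(self, rng):
        """Unmasked interior smoothing agrees with nilearn's smooth_img."""
        import nibabel as nib
        from nilearn.image import smooth_img

        data = rng.normal(100, 5, size=(12, 12, 12, 2))
        series = make_series(data.copy())
        out = smooth_gaussian(series, fwhm_mm=2.0)
        img = nib.Nifti1Image(data, np.eye(4))
        ref = np.asarray(smooth_img(img, fwhm=2.0).dataobj)
        # compare away from edges where boundary handling differs
        core = (slice(4, 8),) * 3
        np.testing.assert_allclose(out.data[core], ref[core], rtol=1e-3)

    def test_anisotropic_voxels_scale_sigma(self):
        data = np.zeros((9, 9, 9, 1))
        data[4, 4, 4, 0] = 1.0
        series = make_series(data, voxel=(1.0, 2.0, 1.0))
        out = smooth_gaussian(series, fwhm_mm=2.0)
        sigma = (2.0 * FWHM_TO_SIGMA, 1.0 * FWHM_TO_SIGMA, 2.0 * FWHM_TO_SIGMA)
        num = gaussian_filter(data[..., 0], sigma=sigma, mode="constant")
        den = gaussian_filter(np.ones((9, 9, 9)), sigma=sigma, mode="constant")
        np.testing.assert_allclose(out.data[..., 0], num / den, rtol=1e-8)


class TestNormalizeVoxelwise:
    def test_mean_zero_sd_one(self, rng):
        series = make_series(rng.normal(50, 7, size=(4, 4, 3, 30)))
        out = normalize_voxelwise(series)
        np.testing.assert_allclose(out.data.mean(axis=3), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.data.std(axis=3), 1.0, atol=1e-12)

    def test_constant_voxel_zeroed_and_flagged(self):
        data = np.ones((2, 1, 1, 10))
        data[1] = np.random.default_rng(0).normal(size=10)
        out = normalize_voxelwise(make_series(data))
        assert (out.data[0] == 0).all()
        flags = out.meta["degenerate_voxels"]
        assert flags[0, 0, 0] and not flags[1, 0, 0]

    def test_idempotent(self, rng):
        series = make_series(rng.normal(size=(3, 3, 2, 25)))
        once = normalize_voxelwise(series)
        twice = normalize_voxelwise(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)


class TestRegressNuisance:
    def test_self_regression_gives_zero(self, rng):
        comp = rng.normal(size=20)
        series = make_series(np.broadcast_to(comp, (2, 1, 1, 20)).copy())
        out = regress_nuisance(series, NuisanceSet(comp[:, np.newaxis]))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_orthogonal_signal_untouched(self):
        n = 16
        comp = np.sin(2 * np.pi * np.arange(n) / n)
        signal = np.cos(2 * np.pi * np.arange(n) / n)  # orthogonal on the grid
        series = make_series(signal.reshape(1, 1, 1, n))
        out = regress_nuisance(series, NuisanceSet(comp[:, np.newaxis]))
        np.testing.assert_allclose(out.data.ravel(), signal, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        """10-timepoint example vs the explicit projection X(X'X)^-1 X'y."""
        n = 10
        X = rng.normal(size=(n, 3))
        y = rng.normal(size=n)
        series = make_series(y.reshape(1, 1, 1, n))
        out = regress_nuisance(series, NuisanceSet(X)).data.ravel()
        proj = X @ np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(out, y - proj, atol=1e-10)
        # residual orthogonal to every component
        np.testing.assert_allclose(X.T @ out, 0.0, atol=1e-10)

    def test_collinear_components_rejected(self, rng):
        base = rng.normal(size=12)
        X = np.column_stack([base, 2.0 * base])
        with pytest.raises(ValueError, match="collinear"):
            regress_nuisance(make_series(rng.normal(size=(1, 1, 1, 12))), NuisanceSet(X))

    def test_identical_components_rejected(self):
        comp = np.arange(8.0)
        with pytest.raises(ValueError, match="identical"):
            NuisanceSet(np.column_stack([comp, comp]))


class TestConcatenateRuns:
    def test_four_runs_of_400_give_1600(self, rng):
        runs = [
            make_series(rng.normal(size=(2, 2, 1, 400)), subject_id="s1", run_id=f"r{i}")
            for i in range(4)
        ]
        out = concatenate_runs(runs)
        assert out.n_volumes == 1600
        assert out.meta["run_boundaries"] == [400, 800, 1200, 1600]

    def test_single_run_identity(self, rng):
        run = make_series(rng.normal(size=(2, 2, 1, 30)))
        np.testing.assert_array_equal(concatenate_runs([run]).data, run.data)

    def test_order_permutation_preserves_moments(self, rng):
        runs = [
            normalize_voxelwise(make_series(rng.normal(size=(2, 2, 1, 50))))
            for _ in range(3)
        ]
        fwd = concatenate_runs(runs)
        rev = concatenate_runs(runs[::-1])
        np.testing.assert_allclose(
            fwd.data.mean(axis=3), rev.data.mean(axis=3), atol=1e-12
        )
        np.testing.assert_allclose(fwd.data.std(axis=3), rev.data.std(axis=3), atol=1e-12)

    def test_mismatched_grids_rejected(self, rng):
        runs = [
            make_series(rng.normal(size=(2, 2, 1, 10))),
            make_series(rng.normal(size=(3, 2, 1, 10))),
        ]
        with pytest.raises(ValueError, match="grids"):
            concatenate_runs(runs)

    def test_normalized_concatenation_has_unit_scale(self, rng):
        """Normalize-per-run then concatenate: mean 0, SD within [0.99, 1.01]."""
        runs = [
            normalize_voxelwise(make_series(rng.normal(10, 3, size=(3, 3, 2, 80))))
            for _ in range(4)
        ]
        out = concatenate_runs(runs)
        np.testing.assert_allclose(out.data.mean(axis=3), 0.0, atol=1e-12)
        sds = out.data.std(axis=3)
        assert ((sds >= 0.99) & (sds <= 1.01)).all()


def test_detrended_series_has_zero_polynomial_coefficients(rng):
    """Regressing detrended data on the same basis returns ~zero weights."""
    from numpy.polynomial import legendre

    n = 80
    series = make_series(rng.normal(size=(2, 2, 1, n)) + np.linspace(0, 5, n))
    out = detrend_poly(series, order=4)
    basis = legendre.legvander(np.linspace(-1, 1, n), 4)
    coef = np.linalg.lstsq(basis, out.data.reshape(-1, n).T, rcond=None)[0]
    np.testing.assert_allclose(coef, 0.0, atol=1e-10)
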