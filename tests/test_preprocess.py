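"""BOLD cleaning: volume discard, smoothing, band-pass, nuisance regression."""

import numpy as np
import pytest

from insulafc.cohort import BOLDRun
from insulafc.grid import GridSpec
from insulafc.preprocess import (
    FWHM_TO_SIGMA,
    PreprocessConfig,
    bandpass,
    discard_initial,
    regress_nuisance,
    smooth_gaussian,
)


def _run(rng, grid):
    return BOLDRun(subject_id="s", data=rng.standard_normal(grid.shape4d), grid=grid)


class TestDiscardInitial:
    def test_255_minus_5_is_250(self, rng):
        grid = GridSpec(dims=(8, 8, 8), n_volumes=255)
        out = discard_initial(_run(rng, grid), 5)
        assert out.grid.n_volumes == 250
        assert out.data.shape[-1] == 250

    def test_remaining_data_unchanged(self, rng):
        grid = GridSpec(dims=(8, 8, 8), n_volumes=30)
        run = _run(rng, grid)
        out = discard_initial(run, 4)
        assert np.array_equal(out.data, run.data[..., 4:])

    def test_zero_is_identity(self, rng):
        grid = GridSpec(dims=(8, 8, 8), n_volumes=30)
        run = _run(rng, grid)
        assert discard_initial(run, 0) is run

    def test_boundary_leaves_one_volume(self, rng):
        grid = GridSpec(dims=(8, 8, 8), n_volumes=255)
        assert discard_initial(_run(rng, grid), 254).grid.n_volumes == 1

    def test_discarding_everything_raises(self, rng):
        grid = GridSpec(dims=(8, 8, 8), n_volumes=30)
        with pytest.raises(ValueError):
            discard_initial(_run(rng, grid), 30)


class TestSmoothGaussian:
    def test_zero_fwhm_is_identity(self, rng):
        grid = GridSpec(dims=(8, 8, 8), n_volumes=20)
        run = _run(rng, grid)
        assert smooth_gaussian(run, 0.0) is run

    def test_negative_fwhm_raises(self, rng):
        grid = GridSpec(dims=(8, 8, 8), n_volumes=20)
        with pytest.raises(ValueError):
            smooth_gaussian(_run(rng, grid), -1.0)

    def test_impulse_matches_closed_form_kernel(self):
        # single central impulse against direct evaluation of the sampled
        # separable Gaussian (sigma in voxels = fwhm/(2*sqrt(2 ln2))/3mm)
        grid = GridSpec(dims=(21, 21, 21), voxel_size_mm=(3, 3, 3), n_volumes=20)
        data = np.zeros(grid.shape4d)
        data[10, 10, 10, :] = 1.0
        out = smooth_gaussian(BOLDRun("s", data, grid), 8.0)
        sigma = 8.0 * FWHM_TO_SIGMA / 3.0
        radius = int(4.0 * sigma + 0.5)
        offsets = np.arange(-radius, radius + 1)
        k = np.exp(-(offsets**2) / (2 * sigma**2))
        k /= k.sum()

        def kval(d):
            return k[d + radius] if abs(d) <= radius else 0.0

        for (dx, dy, dz) in [(0, 0, 0), (1, 0, 0), (2, 1, 0), (3, 2, 1), (0, 0, 4)]:
            expected = kval(dx) * kval(dy) * kval(dz)
            assert out.data[10 + dx, 10 + dy, 10 + dz, 0] == pytest.approx(expected, abs=1e-12)

    def test_constant_volume_unchanged(self):
        grid = GridSpec(dims=(10, 10, 10), n_volumes=20)
        run = BOLDRun("s", np.full(grid.shape4d, 3.7), grid)
        out = smooth_gaussian(run, 8.0)
        assert np.allclose(out.data, 3.7, atol=1e-10)

    def test_mass_conserved_within_a_tenth_percent(self, rng):
        grid = GridSpec(dims=(12, 12, 12), n_volumes=20)
        run = BOLDRun("s", rng.uniform(1, 2, grid.shape4d), grid)
        out = smooth_gaussian(run, 8.0)
        before = run.data[..., 0].sum()
        after = out.data[..., 0].sum()
        assert abs(after - before) / before < 1e-3


class TestBandpass:
    TR = 2.0

    def _sinusoid(self, freq, n=250):
        t = np.arange(n) * self.TR
        return np.sin(2 * np.pi * freq * t)

    def _gain(self, freq):
        """Amplitude transfer at freq measured with a DFT oracle."""
        x = self._sinusoid(freq)
        y = bandpass(x, self.TR, 0.01, 0.08)
        fx = np.abs(np.fft.rfft(x))
        fy = np.abs(np.fft.rfft(y))
        bin_ = int(round(freq * len(x) * self.TR))
        return fy[bin_] / fx[bin_]

    def test_passband_sinusoid_preserved(self):
        assert self._gain(0.04) >= 0.9

    @pytest.mark.parametrize("freq", [0.004, 0.2])
    def test_stopband_sinusoids_attenuated(self, freq):
        assert self._gain(freq) <= 0.1

    def test_output_mean_removed_and_length_kept(self, rng):
        x = rng.standard_normal(250) + 5.0
        y = bandpass(x, self.TR, 0.01, 0.08)
        assert len(y) == 250
        assert abs(y.mean()) < 1e-6 * np.abs(x).max()

    def test_constant_series_goes_to_zero(self):
        y = bandpass(np.full(250, 4.2), self.TR, 0.01, 0.08)
        assert np.allclose(y, 0.0, atol=1e-8)

    def test_band_outside_nyquist_raises(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), self.TR, 0.01, 0.3)
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), self.TR, 0.0, 0.08)


class TestRegressNuisance:
    def test_confound_column_fully_removed(self, rng):
        conf = rng.standard_normal((100, 15))
        resid = regress_nuisance(conf[:, 3].copy(), conf)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_orthogonal_series_only_demeaned(self, rng):
        conf = rng.standard_normal((100, 3))
        conf -= conf.mean(axis=0)
        y = rng.standard_normal(100)
        # orthogonalize y against confounds by explicit projection
        q, _ = np.linalg.qr(conf)
        y_orth = y - q @ (q.T @ y)
        resid = regress_nuisance(y_orth, conf)
        assert np.allclose(resid, y_orth - y_orth.mean(), atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        conf = rng.standard_normal((80, 15))
        y = rng.standard_normal(80)
        x = np.column_stack([np.ones(80), conf])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        expected = y - x @ beta
        assert np.allclose(regress_nuisance(y, conf), expected, atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self, rng):
        conf = rng.standard_normal((120, 15))
        y = rng.standard_normal((4, 120))  # multi-series, time on last axis
        resid = regress_nuisance(y, conf, axis=-1)
        design = np.column_stack([np.ones(120), conf])
        inner = resid @ design
        norms = np.linalg.norm(resid, axis=-1)[:, None] * np.linalg.norm(design, axis=0)
        assert np.all(np.abs(inner) <= 1e-8 * norms)

    def test_idempotent(self, rng):
        conf = rng.standard_normal((100, 15))
        y = rng.standard_normal(100)
        once = regress_nuisance(y, conf)
        twice = regress_nuisance(once, conf)
        assert np.linalg.norm(twice - once) <= 1e-8 * np.linalg.norm(once)

    def test_rank_deficient_design_warns_and_drops(self, rng):
        conf = rng.standard_normal((100, 4))
        conf[:, 3] = conf[:, 0]  # duplicate column
        y = rng.standard_normal(100)
        with pytest.warns(UserWarning, match="rank-deficient"):
            resid = regress_nuisance(y, conf)
        expected = regress_nuisance(y, conf[:, :3])
        assert np.allclose(resid, expected, atol=1e-10)

    def test_length_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="align"):
            regress_nuisance(rng.standard_normal(90), rng.standard_normal((100, 15)))

    def test_bandpass_and_regression_nearly_commute_with_filtered_regressors(self, rng):
        # for band-limited data and band-passed regressors, filtering before
        # or after regression agrees up to filter transition-edge effects
        conf = bandpass(rng.standard_normal((250, 5)), 2.0, 0.01, 0.08, axis=0)
        y = bandpass(rng.standard_normal(250), 2.0, 0.01, 0.08)
        a = regress_nuisance(bandpass(y, 2.0, 0.01, 0.08), conf)
        b = bandpass(regress_nuisance(y, conf), 2.0, 0.01, 0.08)
        assert np.linalg.norm(a - b) <= 0.1 * np.linalg.norm(a)


class TestPreprocessConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(band_hz=(0.08, 0.01))
        with pytest.raises(ValueError):
            PreprocessConfig(n_discard=-1)
        with pytest.raises(ValueError):
            PreprocessConfig(filter_order=3)
        with pytest.raises(ValueError):
            PreprocessConfig(nuisance_policy="whatever")
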