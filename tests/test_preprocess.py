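import numpy as np
import pytest

from fcdmap.errors import DimensionalityError, ParameterError
from fcdmap.io_formats import Series4D, VolumeGrid
from fcdmap.preprocess import (NuisanceModel, bandpass, build_nuisance_design,
                               drop_initial_volumes, exceeds_motion_limit,
                               framewise_displacement, friston24,
                               mean_framewise_displacement, regress_nuisance,
                               smooth_gaussian)

from conftest import make_series


class TestDropInitialVolumes:
    def test_230_minus_10_gives_220(self, grid_3mm, rng):
        series = make_series(grid_3mm, n_volumes=230, rng=rng)
        assert drop_initial_volumes(series, 10).n_volumes == 220

    def test_zero_is_identity(self, noise_series):
        out = drop_initial_volumes(noise_series, 0)
        np.testing.assert_array_equal(out.data, noise_series.data)

    def test_dropping_all_raises(self, grid_3mm, rng):
        series = make_series(grid_3mm, n_volumes=20, rng=rng)
        with pytest.raises(DimensionalityError):
            drop_initial_volumes(series, 20)

    def test_removes_leading_timepoints(self, noise_series):
        out = drop_initial_volumes(noise_series, 3)
        np.testing.assert_array_equal(out.data, noise_series.data[..., 3:])


class TestMotionLimit:
    def test_zero_trace_ok(self):
        assert exceeds_motion_limit(np.zeros((30, 6))) is False

    def test_translation_above_limit(self):
        trace = np.zeros((30, 6))
        trace[10, 1] = 2.6
        assert exceeds_motion_limit(trace) is True

    def test_boundary_is_strict(self):
        trace = np.zeros((30, 6))
        trace[5, 4] = 2.5  # rotation exactly at the limit
        assert exceeds_motion_limit(trace) is False

    def test_rotation_above_limit(self):
        trace = np.zeros((30, 6))
        trace[5, 5] = -2.51
        assert exceeds_motion_limit(trace) is True


class TestFramewiseDisplacement:
    def test_constant_trace_zero(self):
        assert mean_framewise_displacement(np.ones((10, 6))) == 0.0

    def test_single_step(self):
        trace = np.zeros((2, 6))
        trace[1, 0] = 0.3
        assert mean_framewise_displacement(trace) == pytest.approx(0.3)

    def test_rotation_scaled_by_head_radius(self):
        trace = np.zeros((2, 6))
        trace[1, 3] = np.rad2deg(0.01)  # 0.01 rad
        assert mean_framewise_displacement(trace, head_radius=50.0) == \
            pytest.approx(0.5)

    def test_matches_step_sum_oracle(self, rng):
        trace = rng.standard_normal((40, 6)) * 0.1
        delta = np.diff(trace, axis=0)
        oracle = (np.abs(delta[:, :3]).sum(axis=1)
                  + 50.0 * np.abs(np.deg2rad(delta[:, 3:])).sum(axis=1)).mean()
        assert mean_framewise_displacement(trace) == pytest.approx(oracle)


class TestFriston24:
    def test_shape_and_blocks(self, rng):
        trace = rng.standard_normal((20, 6))
        design = friston24(trace)
        assert design.shape == (20, 24)
        np.testing.assert_array_equal(design[:, :6], trace)
        np.testing.assert_array_equal(design[1:, 6:12], trace[:-1])
        np.testing.assert_array_equal(design[0, 6:12], np.zeros(6))
        np.testing.assert_array_equal(design[:, 12:18], trace ** 2)

    def test_full_model_regressor_count(self, rng):
        model = NuisanceModel(wm_series=rng.standard_normal(20),
                              csf_series=rng.standard_normal(20))
        design = build_nuisance_design(model, rng.standard_normal((20, 6)), 20)
        # intercept + trend + 2 tissue + 24 motion
        assert design.shape[1] == 28


class TestRegressNuisance:
    def test_linear_trend_removed(self, grid_3mm):
        n = 40
        trend = np.linspace(-1, 1, n)
        data = np.tile(trend, (*grid_3mm.dims, 1)) * 3.5 + 2.0
        series = Series4D(grid=grid_3mm, data=data)
        out = regress_nuisance(series, NuisanceModel(include_motion=False))
        assert np.abs(out.data).max() < 1e-8

    def test_residuals_orthogonal_to_design(self, grid_3mm, rng):
        series = make_series(grid_3mm, n_volumes=40, rng=rng)
        trace = rng.standard_normal((40, 6)) * 0.2
        model = NuisanceModel(wm_series=rng.standard_normal(40),
                              csf_series=rng.standard_normal(40))
        out = regress_nuisance(series, model, trace)
        design = build_nuisance_design(model, trace, 40)
        flat = out.data.reshape(-1, 40)
        dots = np.abs(design.T @ flat.T)
        scale = np.linalg.norm(design, axis=0)[:, None] * \
            np.linalg.norm(flat, axis=1)[None, :]
        assert (dots / np.maximum(scale, 1e-30)).max() < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        grid = VolumeGrid(dims=(5, 1, 1), affine=np.eye(4))
        series = make_series(grid, n_volumes=30, rng=rng)
        trace = rng.standard_normal((30, 6)) * 0.1
        model = NuisanceModel()
        out = regress_nuisance(series, model, trace)
        design = build_nuisance_design(model, trace, 30)
        for v in range(5):
            y = series.data[v, 0, 0]
            beta = np.linalg.solve(design.T @ design, design.T @ y)
            np.testing.assert_allclose(out.data[v, 0, 0], y - design @ beta,
                                       atol=1e-10)

    def test_rank_deficient_warns(self, grid_3mm, rng):
        series = make_series(grid_3mm, n_volumes=30, rng=rng)
        trace = np.zeros((30, 6))  # constant motion params collide w/ intercept
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            regress_nuisance(series, NuisanceModel(), trace)


class TestBandpass:
    def _sinusoid(self, grid, freq, n=200, tr=2.0):
        t = np.arange(n) * tr
        wave = np.sin(2 * np.pi * freq * t)
        data = np.tile(wave, (*grid.dims, 1))
        return Series4D(grid=grid, data=data, tr_seconds=tr)

    def test_passband_preserved(self, identity_grid):
        series = self._sinusoid(identity_grid, 0.05)
        out = bandpass(series)
        ratio = out.data[0, 0, 0].std() / series.data[0, 0, 0].std()
        assert 0.9 < ratio < 1.1

    def test_stopband_attenuated(self, identity_grid):
        series = self._sinusoid(identity_grid, 0.2)
        out = bandpass(series)
        # spectral oracle: amplitude at 0.2 Hz after vs before
        spectrum_in = np.abs(np.fft.rfft(series.data[0, 0, 0]))
        spectrum_out = np.abs(np.fft.rfft(out.data[0, 0, 0]))
        peak = np.argmax(spectrum_in)
        assert spectrum_out[peak] <= 0.1 * spectrum_in[peak]

    def test_dc_removed(self, identity_grid):
        data = np.full((*identity_grid.dims, 64), 7.0)
        out = bandpass(Series4D(grid=identity_grid, data=data))
        assert np.abs(out.data).max() < 1e-10

    def test_above_nyquist_rejected(self, noise_series):
        with pytest.raises(ParameterError):
            bandpass(noise_series, 0.01, 0.3)  # Nyquist = 0.25 at TR 2 s

    def test_near_idempotent(self, noise_series):
        once = bandpass(noise_series)
        twice = bandpass(once)
        rms = np.sqrt(((twice.data - once.data) ** 2).mean())
        assert rms < 0.05 * np.sqrt((once.data ** 2).mean())


class TestSmoothing:
    def test_fwhm_zero_identity(self, rng):
        data = rng.standard_normal((8, 8, 8))
        np.testing.assert_array_equal(
            smooth_gaussian(data, 0.0, (3.0, 3.0, 3.0)), data)

    def test_impulse_mass_preserved(self):
        data = np.zeros((13, 13, 13))
        data[6, 6, 6] = 1.0
        out = smooth_gaussian(data, 6.0, (3.0, 3.0, 3.0))
        assert out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_half_maximum_width(self):
        # fwhm 6 mm at 3 mm voxels -> half-max width ~2 voxels on the profile
        data = np.zeros((15, 15, 15))
        data[7, 7, 7] = 1.0
        out = smooth_gaussian(data, 6.0, (3.0, 3.0, 3.0))
        profile = out[:, 7, 7]
        half = profile.max() / 2.0
        # interpolated width of the region above half maximum
        x = np.arange(15, dtype=float)
        fine = np.interp(np.linspace(5, 9, 4001), x, profile)
        frac = (fine >= half).mean() * 4.0
        assert frac == pytest.approx(2.0, abs=0.35)

    def test_masked_renormalization_keeps_constant(self, rng):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:8, 2:8, 2:8] = True
        data = np.full((10, 10, 10), 5.0)
        out = smooth_gaussian(data, 6.0, (3.0, 3.0, 3.0), mask=mask)
        np.testing.assert_allclose(out[mask], 5.0, atol=1e-9)
        assert np.all(out[~mask] == 0)

    def test_series_smoothed_per_volume(self, rng):
        data = rng.standard_normal((8, 8, 8, 3))
        out = smooth_gaussian(data, 6.0, (3.0, 3.0, 3.0))
        for t in range(3):
            np.testing.assert_allclose(
                out[..., t], smooth_gaussian(data[..., t], 6.0, (3.0, 3.0, 3.0)),
                atol=1e-12)
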