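import itertools

import numpy as np
import pytest

from fcdmap.errors import ParameterError, ValidationError
from fcdmap.fcd_core import (DistanceConfig, compute_fcd, fisher_z,
                             pair_distance, whole_brain_mean)
from fcdmap.io_formats import (BrainMask, Series4D, VolumeGrid, extract_series,
                               mask_indices, voxel_coordinates)
from fcdmap.preprocess import bandpass_array

from conftest import make_series


class TestPairDistance:
    def test_zero(self):
        assert pair_distance((0, 0, 0), (0, 0, 0)) == 0.0

    def test_3_4_5(self):
        assert pair_distance((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)

    def test_random_matches_norm_oracle(self, rng):
        for _ in range(20):
            a, b = rng.standard_normal(3) * 50, rng.standard_normal(3) * 50
            assert pair_distance(a, b) == pytest.approx(np.linalg.norm(a - b))

    def test_nonfinite_rejected(self):
        with pytest.raises(ParameterError):
            pair_distance((np.nan, 0, 0), (0, 0, 0))


class TestFisherZ:
    def test_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_closed_form(self):
        assert fisher_z(0.5) == pytest.approx(np.log(3) / 2, rel=1e-12)

    def test_one_is_clipped_finite(self):
        assert np.isfinite(fisher_z(1.0))
        assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-7))

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            fisher_z(-0.1)
        with pytest.raises(ParameterError):
            fisher_z(1.1)

    def test_monotone(self, rng):
        v = np.sort(rng.random(50))
        z = fisher_z(v)
        assert np.all(np.diff(z) >= 0)


def _shared_signal_series(grid, n=60, tr=2.0):
    rng = np.random.default_rng(3)
    wave = bandpass_array(rng.standard_normal(n), tr, 0.01, 0.1)
    data = np.tile(wave, (*grid.dims, 1))
    return Series4D(grid=grid, data=data, tr_seconds=tr)


class TestComputeFCD:
    def test_identical_signal_everywhere_gives_one(self, grid_3mm, full_mask):
        series = _shared_signal_series(grid_3mm)
        maps = compute_fcd(series, full_mask)
        inside = full_mask.inside
        np.testing.assert_allclose(maps.g_raw[inside], 1.0, atol=1e-10)
        np.testing.assert_allclose(maps.s_raw[inside], 1.0, atol=1e-10)
        np.testing.assert_allclose(maps.l_raw[inside], 1.0, atol=1e-10)
        assert np.all(np.isfinite(maps.g_z[inside]))

    def test_conservation_identity(self, grid_3mm, full_mask, rng):
        series = make_series(grid_3mm, n_volumes=40, rng=rng)
        maps = compute_fcd(series, full_mask)
        m = full_mask.inside
        lhs = (maps.n_short[m] + maps.n_long[m]) * maps.g_raw[m]
        rhs = maps.n_short[m] * maps.s_raw[m] + maps.n_long[m] * maps.l_raw[m]
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10)

    def test_neighbor_count_partition(self, grid_3mm, full_mask, rng):
        series = make_series(grid_3mm, n_volumes=30, rng=rng)
        maps = compute_fcd(series, full_mask)
        m = full_mask.inside
        assert np.all(maps.n_short[m] + maps.n_long[m] == full_mask.n_inside - 1)

    def test_blocked_equals_brute_force_oracle(self, rng):
        grid = VolumeGrid(dims=(5, 5, 5), affine=np.diag([3.0, 3.0, 3.0, 1.0]))
        mask = BrainMask(grid=grid, inside=np.ones(grid.dims, dtype=bool))
        series = make_series(grid, n_volumes=50, rng=rng)
        config = DistanceConfig(criterion_mm=12.0)
        maps = compute_fcd(series, mask, config, block_size=17)

        # exhaustive all-pairs oracle
        ts = extract_series(series, mask)
        coords = voxel_coordinates(grid, mask)
        m = ts.shape[0]
        r = np.corrcoef(ts)
        g = np.empty(m)
        s = np.empty(m)
        l = np.empty(m)
        for i in range(m):
            short_sum = long_sum = 0.0
            n_s = n_l = 0
            for j in range(m):
                if i == j:
                    continue
                d = np.linalg.norm(coords[i] - coords[j])
                if d <= 12.0:
                    short_sum += abs(r[i, j]); n_s += 1
                else:
                    long_sum += abs(r[i, j]); n_l += 1
            g[i] = (short_sum + long_sum) / (m - 1)
            s[i] = short_sum / n_s if n_s else 0.0
            l[i] = long_sum / n_l if n_l else 0.0
        idx = mask_indices(mask)
        np.testing.assert_allclose(maps.g_raw[idx[:, 0], idx[:, 1], idx[:, 2]],
                                   g, atol=1e-12)
        np.testing.assert_allclose(maps.s_raw[idx[:, 0], idx[:, 1], idx[:, 2]],
                                   s, atol=1e-12)
        np.testing.assert_allclose(maps.l_raw[idx[:, 0], idx[:, 1], idx[:, 2]],
                                   l, atol=1e-12)

    def test_block_size_invariance(self, grid_3mm, full_mask, rng):
        series = make_series(grid_3mm, n_volumes=30, rng=rng)
        a = compute_fcd(series, full_mask, block_size=64)
        b = compute_fcd(series, full_mask, block_size=100000)
        np.testing.assert_allclose(a.g_raw, b.g_raw, atol=1e-14)
        np.testing.assert_allclose(a.s_raw, b.s_raw, atol=1e-14)

    def test_interior_short_count_256_at_12mm(self, rng):
        # lattice enumeration oracle: 3 mm spacing, d_c = 12 mm -> offsets
        # with i^2+j^2+k^2 <= 16, excluding the origin
        oracle = sum(1 for i, j, k in itertools.product(range(-4, 5), repeat=3)
                     if 0 < i * i + j * j + k * k <= 16)
        assert oracle == 256
        grid = VolumeGrid(dims=(11, 11, 11), affine=np.diag([3.0, 3.0, 3.0, 1.0]))
        mask = BrainMask(grid=grid, inside=np.ones(grid.dims, dtype=bool))
        series = make_series(grid, n_volumes=20, rng=rng)
        maps = compute_fcd(series, mask)
        assert maps.n_short[5, 5, 5] == 256

    def test_monotone_partition_in_criterion(self, grid_3mm, full_mask, rng):
        series = make_series(grid_3mm, n_volumes=25, rng=rng)
        n_prev = None
        for dc in (6.0, 12.0, 18.0):
            maps = compute_fcd(series, full_mask, DistanceConfig(criterion_mm=dc))
            n = maps.n_short[full_mask.inside]
            if n_prev is not None:
                assert np.all(n >= n_prev)
            n_prev = n

    def test_zero_variance_voxels_dropped_with_warning(self, grid_3mm, rng):
        data = rng.standard_normal((*grid_3mm.dims, 30))
        data[0, 0, 0, :] = 5.0  # constant voxel
        series = Series4D(grid=grid_3mm, data=data)
        mask = BrainMask(grid=grid_3mm, inside=np.ones(grid_3mm.dims, bool))
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            maps = compute_fcd(series, mask)
        assert not maps.mask.inside[0, 0, 0]

    def test_all_zero_variance_raises(self, grid_3mm):
        data = np.ones((*grid_3mm.dims, 30))
        series = Series4D(grid=grid_3mm, data=data)
        mask = BrainMask(grid=grid_3mm, inside=np.ones(grid_3mm.dims, bool))
        with pytest.warns(RuntimeWarning):
            with pytest.raises(ValidationError):
                compute_fcd(series, mask)

    def test_null_level_matches_analytic_expectation(self, rng):
        # E|r| under the null ~ sqrt(2 / (pi (T-1))) for white noise length T
        grid = VolumeGrid(dims=(6, 6, 6), affine=np.diag([3.0, 3.0, 3.0, 1.0]))
        mask = BrainMask(grid=grid, inside=np.ones(grid.dims, bool))
        t = 80
        means = []
        for _ in range(5):
            series = make_series(grid, n_volumes=t, rng=rng)
            maps = compute_fcd(series, mask)
            means.append(maps.g_raw[mask.inside].mean())
        expected = np.sqrt(2.0 / (np.pi * (t - 1)))
        assert np.mean(means) == pytest.approx(expected, rel=0.05)

    def test_permutation_invariance_of_maps(self, rng):
        # relabeling voxel order (same spatial content) leaves maps unchanged:
        # compute on a mask traversed twice with different block sizes
        grid = VolumeGrid(dims=(4, 4, 4), affine=np.diag([3.0, 3.0, 3.0, 1.0]))
        mask = BrainMask(grid=grid, inside=np.ones(grid.dims, bool))
        series = make_series(grid, n_volumes=25, rng=rng)
        a = compute_fcd(series, mask, block_size=7)
        b = compute_fcd(series, mask, block_size=64)
        np.testing.assert_array_equal(a.g_raw, b.g_raw)


class TestWholeBrainMean:
    def test_constant(self, grid_3mm, full_mask):
        vol = np.full(grid_3mm.dims, 0.7)
        assert whole_brain_mean(vol, full_mask) == pytest.approx(0.7)

    def test_two_voxel_mask(self, grid_3mm):
        inside = np.zeros(grid_3mm.dims, bool)
        inside[0, 0, 0] = inside[1, 0, 0] = True
        mask = BrainMask(grid=grid_3mm, inside=inside)
        vol = np.zeros(grid_3mm.dims)
        vol[0, 0, 0], vol[1, 0, 0] = 0.2, 0.4
        assert whole_brain_mean(vol, mask) == pytest.approx(0.3)

    def test_random_matches_sum_count_oracle(self, grid_3mm, full_mask, rng):
        vol = rng.standard_normal(grid_3mm.dims)
        oracle = vol[full_mask.inside].sum() / full_mask.n_inside
        assert whole_brain_mean(vol, full_mask) == pytest.approx(oracle)
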