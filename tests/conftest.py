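import numpy as np
import pytest

from fcdmap.io_formats import BrainMask, Series4D, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid_3mm():
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    affine[:3, 3] = (-90.0, -126.0, -72.0)
    return VolumeGrid(dims=(10, 10, 10), affine=affine)


@pytest.fixture
def identity_grid():
    return VolumeGrid(dims=(5, 5, 5), affine=np.eye(4))


@pytest.fixture
def full_mask(grid_3mm):
    return BrainMask(grid=grid_3mm, inside=np.ones(grid_3mm.dims, dtype=bool))


def make_series(grid, n_volumes=50, rng=None, tr=2.0):
    rng = rng or np.random.default_rng(0)
    data = rng.standard_normal((*grid.dims, n_volumes))
    return Series4D(grid=grid, data=data, tr_seconds=tr)


@pytest.fixture
def noise_series(grid_3mm, rng):
    return make_series(grid_3mm, n_volumes=50, rng=rng)
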