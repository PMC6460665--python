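import numpy as np
import pytest

from cerefc.grids import BinaryMask, VolumeGrid, VolumeSeries


@pytest.fixture
def grid():
    return VolumeGrid((8, 8, 8))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def full_mask(grid):
    return BinaryMask(grid, np.ones(grid.dims, bool), "gray")


def make_series(grid, data):
    return VolumeSeries(grid, np.asarray(data, float))


@pytest.fixture
def random_series(grid, rng):
    return make_series(grid, rng.standard_normal(grid.dims + (30,)))


@pytest.fixture
def tiny_design():
    """A fast cohort design for pipeline smoke tests."""
    from cerefc.simulate import SimulationDesign

    return SimulationDesign(
        n_volumes=60,
        group_sizes={"ASD_F": 3, "ASD_M": 4, "TD_F": 3, "TD_M": 4},
        rng_seed=99,
    )
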