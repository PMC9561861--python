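import numpy as np
import pytest

from iclm import (
    Mask,
    RunConfig,
    VolumeGrid,
    default_grid,
    make_cohort,
    prepare_connectome,
)
from iclm.identify import ReferenceNetwork


@pytest.fixture
def grid4():
    return VolumeGrid((4, 4, 4), np.eye(4))


@pytest.fixture
def grid8():
    return default_grid(8, voxel_mm=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def _ball_mask(grid, centre, radius):
    coords = np.indices(grid.dims).reshape(3, -1).T
    d2 = ((coords - np.asarray(centre)) ** 2).sum(axis=1)
    data = (d2 <= radius**2).reshape(grid.dims)
    return Mask(grid, data.astype(np.uint8))


@pytest.fixture
def ball_mask():
    return _ball_mask


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by the slower integration tests."""
    return make_cohort(seed=1)


@pytest.fixture(scope="session")
def default_connectome(default_cohort):
    cfg = RunConfig(seed=1)
    return prepare_connectome(default_cohort.hc_fmris, default_cohort.lesions, cfg)


@pytest.fixture(scope="session")
def target_reference(default_cohort):
    gt = default_cohort.ground_truth
    return ReferenceNetwork("target", gt.networks[gt.target_index], kind="continuous")
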