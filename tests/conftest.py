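import numpy as np
import pytest

from cadeval import build_match_table, build_paper_fixture
from cadeval.annotations import VoxelMask


@pytest.fixture(scope="session")
def paper_fixture():
    return build_paper_fixture()


@pytest.fixture(scope="session")
def paper_match_table(paper_fixture):
    return build_match_table(paper_fixture.cohort)


@pytest.fixture
def grid():
    return (32, 32, 32), (1.0, 1.0, 1.0)


def make_mask(coords, grid_shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0)):
    return VoxelMask.from_coords(np.asarray(coords, dtype=np.int64), grid_shape, spacing)


@pytest.fixture
def mask_factory():
    return make_mask


def block(origin, shape, grid_shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0)):
    ox, oy, oz = origin
    coords = [
        (ox + a, oy + b, oz + c)
        for a in range(shape[0])
        for b in range(shape[1])
        for c in range(shape[2])
    ]
    return make_mask(coords, grid_shape, spacing)


@pytest.fixture
def block_factory():
    return block
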