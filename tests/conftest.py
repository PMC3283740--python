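import numpy as np
import pytest

from pai1microenv.lattice import Grid, OccupancyMask, ScalarField


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return Grid(9, 9)


@pytest.fixture
def random_field(rng, small_grid):
    return ScalarField(small_grid, rng.uniform(0.0, 5.0, small_grid.shape))


def random_connected_mask(grid: Grid, n_sites: int, rng: np.random.Generator) -> OccupancyMask:
    """Random connected blob grown by repeated single-neighbor accretion."""
    from pai1microenv.ca import grow_tumor_step

    mask = OccupancyMask.single(grid)
    while mask.count() < n_sites:
        mask, _ = grow_tumor_step(mask, 1.0, rng, max_new=n_sites - mask.count())
    return mask
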