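import numpy as np
import pytest

from wildcons.core_grid import GridSpec, RasterLayer
from wildcons.synthgen import WorldConfig, generate_world


@pytest.fixture
def unit_grid():
    """10x10 grid of 1-degree cells, upper-left corner at 0E, 10N."""
    return GridSpec(cell_size_deg=1.0, origin_lon=0.0, origin_lat=10.0, n_rows=10, n_cols=10)


@pytest.fixture
def all_land(unit_grid):
    return RasterLayer(unit_grid, np.ones(unit_grid.shape), "binary")


@pytest.fixture(scope="session")
def small_world():
    """30x30 synthetic world with planted contamination, shared by read-only tests."""
    return generate_world(
        WorldConfig(
            n_rows=30,
            n_cols=30,
            n_species=4,
            n_g=15,
            n_h=30,
            n_water=4,
            n_pre1950=3,
            n_non_native=2,
            n_no_coords=2,
            seed=11,
        )
    )
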