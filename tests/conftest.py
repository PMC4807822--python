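import numpy as np
import pandas as pd
import pytest

import synervar as sv


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_grid():
    """10 x 10 grid of 110-km cells, all terrestrial."""
    return sv.make_grid(sv.SimConfig(grid_nx=10, grid_ny=10, seed=0))


@pytest.fixture(scope="session")
def default_grid():
    """The reference 20 x 20 grid."""
    return sv.make_grid(sv.SimConfig(seed=0))


@pytest.fixture(scope="session")
def default_basis(default_grid):
    """MEM basis of the reference grid (shared across tests: eigh is the
    expensive step and the grid is identical everywhere)."""
    coords = default_grid[["x_km", "y_km"]].to_numpy()
    return sv.build_mem(sv.connectivity(coords))


def random_cells(n, rng, scale=1000.0):
    """Irregular point cloud posing as cell centroids."""
    xy = rng.uniform(0, scale, size=(n, 2))
    return pd.DataFrame(
        {"cell_id": np.arange(n), "x_km": xy[:, 0], "y_km": xy[:, 1],
         "terrestrial_frac": np.ones(n)}
    )
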