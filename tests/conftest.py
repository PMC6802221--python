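import numpy as np
import pandas as pd
import pytest

from forestdiv.synthetic import (
    GROUND,
    VEGETATION,
    PointCloud,
    generate_plots,
    simulate_communities,
    simulate_phylogeny,
)


@pytest.fixture(scope="session")
def small_states():
    return generate_plots(30, 3, seed=11)


@pytest.fixture(scope="session")
def small_tree():
    return simulate_phylogeny(25, seed=5)


@pytest.fixture(scope="session")
def small_communities(small_states, small_tree):
    return simulate_communities(small_states, small_tree, seed=7)


def grid_point_cloud(heights, cell=1.0, plot_size=100.0, ground_mask=None):
    """One return per cell centre with the given height raster.

    ``heights`` is indexed [i, j] with x = (i + 0.5) * cell,
    y = (j + 0.5) * cell.  Cells flagged in ``ground_mask`` (or with
    height 0) become ground returns.
    """
    heights = np.asarray(heights, dtype=float)
    n0, n1 = heights.shape
    ii, jj = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
    x = (ii.ravel() + 0.5) * cell
    y = (jj.ravel() + 0.5) * cell
    z = heights.ravel().copy()
    if ground_mask is None:
        ground = z <= 0
    else:
        ground = np.asarray(ground_mask, dtype=bool).ravel()
        z = np.where(ground, 0.0, z)
    cls = np.where(ground, GROUND, VEGETATION).astype(np.uint8)
    return PointCloud(x=x, y=y, z=z, classification=cls, plot_size=plot_size)


@pytest.fixture
def make_grid_cloud():
    return grid_point_cloud
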