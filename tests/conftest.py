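import numpy as np
import pytest

from marshelev.grid import AnalysisGrid, Raster
from marshelev.synthetic_scene import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_config():
    """A quick scene: coarse grid, few tiles, sparse-but-usable gauge net."""
    return SceneConfig(n_rows=60, n_cols=80, n_gauges=16, n_tiles=3,
                       tile_resolution=10.0, n_watersheds=12, seed=7)


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture(scope="session")
def default_scene():
    """The default study conditions (session-scoped: generated once)."""
    return generate_scene(SceneConfig(seed=11))


@pytest.fixture
def tiny_grid():
    return AnalysisGrid(origin_x=0.0, origin_y=150.0, n_rows=5, n_cols=5,
                        cell_size=30.0)


def make_raster(grid: AnalysisGrid, values) -> Raster:
    return Raster(grid, np.asarray(values, dtype=float))
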