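import numpy as np
import pandas as pd
import pytest

from plantedmap import WorldConfig, generate_world, world_to_tables
from plantedmap.grid import Grid


@pytest.fixture(scope="session")
def small_world():
    """A 60x60 landscape shared by read-only tests."""
    cfg = WorldConfig(grid_shape=(60, 60), n_insitu_points=200, n_plots=1500, seed=123)
    return generate_world(cfg)


@pytest.fixture(scope="session")
def small_tables(small_world):
    return world_to_tables(small_world)


@pytest.fixture
def tiny_grid():
    return Grid(n_rows=4, n_cols=5, origin_lon=100.0, origin_lat=30.0)


def make_evidence(**states) -> pd.DataFrame:
    """One-row evidence table; unspecified sources are absent."""
    from plantedmap.world import SOURCES

    row = {s: states.get(s, "absent") for s in SOURCES}
    return pd.DataFrame([row])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
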