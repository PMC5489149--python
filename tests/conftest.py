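import numpy as np
import pytest

from sdm2abund.grids import GridSpec, RasterLayer
from sdm2abund import synthetic as syn


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(0.0, 0.0, 10000.0, 6, 5, crs_tag="test")


@pytest.fixture(scope="session")
def landscape():
    """Small (30x30) landscape shared by the slower model tests."""
    grid = GridSpec(0.0, 0.0, 10000.0, 30, 30, crs_tag="synthetic")
    env, land, fine = syn.gen_landscape(grid=grid, seed=11)
    return env, land, fine


@pytest.fixture(scope="session")
def truth(landscape):
    env, land, fine = landscape
    return syn.gen_species(env, land, fine, seed=11)


def make_layer(grid, values, **kw):
    return RasterLayer(grid, np.asarray(values), **kw)
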