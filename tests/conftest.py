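import numpy as np
import pytest

from ecorisk.geodata import LandUseRaster, build_evaluation_grid
from ecorisk.presets import default_class_table
from ecorisk.synthetic import SyntheticSpec, generate_fixture_set


@pytest.fixture(scope="session")
def class_table():
    return default_class_table()


@pytest.fixture(scope="session")
def landscape_100():
    """Deterministic 100x100 patchy landscape with all five classes."""
    spec = SyntheticSpec(shape=(100, 100), smoothness=6.0, seed=11)
    fx = generate_fixture_set(spec)
    return fx


@pytest.fixture(scope="session")
def raster_100(landscape_100):
    return landscape_100["rasters"][0]


@pytest.fixture(scope="session")
def grid_100(raster_100):
    return build_evaluation_grid(raster_100, 10)


def random_raster(shape, seed, cell_size=1000.0, codes=(1, 2, 3, 4, 5)):
    rng = np.random.default_rng(seed)
    grid = rng.choice(codes, size=shape).astype(np.int32)
    return LandUseRaster(grid=grid, cell_size=cell_size, class_codes=frozenset(codes))
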