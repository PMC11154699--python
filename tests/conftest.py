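import numpy as np
import pytest

from vprmsif import (
    CompositeCalendar,
    Grid,
    GriddedField,
    SceneConfig,
    VegMap,
    VPRMParams,
    generate_scene,
)


@pytest.fixture(scope="session")
def scene_clean():
    """Noiseless synthetic scene: every fit has an exactly recoverable target."""
    return generate_scene(SceneConfig(sif_noise=0.0, reco_noise=0.0, seed=7))


@pytest.fixture(scope="session")
def scene_noisy():
    """Default study conditions: SIF noise 0.1, respiration noise 0.1."""
    return generate_scene(SceneConfig(seed=7))


@pytest.fixture(scope="session")
def tropical_params():
    return VPRMParams.packaged("tropical")


@pytest.fixture
def one_cell():
    """A single-cell, single-time field factory."""
    grid = Grid.regular(20.0, 75.0, 1, 1, 0.1)
    times = np.array(["2019-01-01"], dtype="datetime64[D]")

    def make(value, units="1", name="x"):
        return GriddedField(grid, times, np.full((1, 1, 1), float(value)), units, name)

    make.grid = grid
    make.times = times
    return make


@pytest.fixture
def calendar():
    return CompositeCalendar(2019)


def build_field(values, units="1", name="x", lat0=20.0, lon0=75.0, res=0.1):
    """Field from a (time, lat, lon) or (lat, lon) array, grid inferred."""
    values = np.ma.asarray(values, dtype=float)
    if values.ndim == 2:
        ny, nx = values.shape
        grid = Grid.regular(lat0, lon0, ny, nx, res)
        return GriddedField(grid, None, values, units, name)
    nt, ny, nx = values.shape
    grid = Grid.regular(lat0, lon0, ny, nx, res)
    times = np.datetime64("2019-01-01", "D") + 8 * np.arange(nt)
    return GriddedField(grid, times, values, units, name)


def uniform_vegmap(field_or_grid, label):
    grid = field_or_grid.grid if isinstance(field_or_grid, GriddedField) else field_or_grid
    return VegMap.uniform(grid, label)
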