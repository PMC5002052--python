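import numpy as np
import pytest

from agbcompare import (BiomassRaster, CategoricalRaster, GridSpec, MaskRaster,
                        MapSpec, ScenarioConfig, make_scenario,
                        preset_map_specs)


@pytest.fixture
def grid2():
    return GridSpec(0.0, 0.0, 100.0, 2, 2)


@pytest.fixture
def grid4():
    return GridSpec(0.0, 0.0, 100.0, 4, 4)


@pytest.fixture
def small_raster(grid2):
    return BiomassRaster(grid2, [[1.0, 2.0], [3.0, 4.0]],
                         np.ones((2, 2), dtype=bool), label="small")


def make_raster(values, valid=None, cell_size=100.0, **kw):
    values = np.asarray(values, dtype=float)
    grid = GridSpec(0.0, 0.0, cell_size, *values.shape)
    if valid is None:
        valid = np.ones(values.shape, dtype=bool)
    return BiomassRaster(grid, values, np.asarray(valid, dtype=bool), **kw)


def make_partition(codes, cell_size=100.0):
    codes = np.asarray(codes, dtype=np.int64)
    grid = GridSpec(0.0, 0.0, cell_size, *codes.shape)
    return CategoricalRaster(grid, codes)


@pytest.fixture(scope="session")
def preset_scenario():
    """Moderate-size four-archetype scenario shared across tests."""
    cfg = ScenarioConfig(grid=GridSpec(0.0, 0.0, 240.0, 100, 100),
                         maps=preset_map_specs(), n_regions=9, seed=42)
    return make_scenario(cfg)


@pytest.fixture(scope="session")
def null_scenario():
    """All maps identical to the truth; noiseless reference."""
    maps = (
        MapSpec("A", (), nominal_year=2000, sensor="active",
                technique="parametric", allometry="crm"),
        MapSpec("B", (), nominal_year=2005, sensor="passive",
                technique="nonparametric", allometry="regional"),
        MapSpec("C", (), sensor="active", technique="nonparametric",
                allometry="regional"),
    )
    cfg = ScenarioConfig(grid=GridSpec(0.0, 0.0, 240.0, 60, 60),
                         maps=maps, n_regions=6, seed=3,
                         reference_noise_sd=0.0)
    return make_scenario(cfg)
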