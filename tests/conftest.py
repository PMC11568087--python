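import numpy as np
import pytest

from equiscape.landscape_io import LandscapeGrid
from equiscape.synthetic_landscape import GeneratorConfig, generate_study_area


@pytest.fixture(scope="session")
def coarse_config() -> GeneratorConfig:
    """Default study conditions with a coarse raster (500 m cells) so the
    multi-stage tests stay fast; features are unaffected by cell size."""
    return GeneratorConfig(seed=1, grid_cell_m=500.0)


@pytest.fixture(scope="session")
def study_area(coarse_config):
    return generate_study_area(coarse_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_grid(classes, zones=None, cell_size_m=100.0, legend=None, zone_legend=None):
    classes = np.asarray(classes, dtype=np.int32)
    if zones is None:
        zones = np.ones_like(classes)
    if legend is None:
        legend = {int(c): f"class_{int(c)}" for c in np.unique(classes) if c != -1}
    if zone_legend is None:
        zone_legend = {int(z): f"K{int(z):02d}" for z in np.unique(zones) if z != -1}
    return LandscapeGrid(
        classes=classes,
        zones=np.asarray(zones, dtype=np.int32),
        cell_size_m=cell_size_m,
        legend=legend,
        zone_legend=zone_legend,
        nodata=-1,
    )
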