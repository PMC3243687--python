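import numpy as np
import pytest

from rspfit.landscape import (
    CLASS_CODES,
    HabitatGrid,
    LandscapeConfig,
    generate_landscape,
)
from rspfit.survey import SurveyDesign, generate_survey_design


@pytest.fixture(scope="session")
def small_config():
    return LandscapeConfig(
        extent_m=(9_000.0, 9_000.0), cell_m=30.0, park_fraction=0.25,
        n_quadrats=2, quadrat_size_m=3_000.0, n_rivers=2, n_roads=3,
        n_main_roads=1, n_springs=8, seed=11)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def small_design(small_landscape):
    return generate_survey_design(small_landscape, transects_per_quadrat=2,
                                  mean_transect_m=2_400.0, seed=11)


@pytest.fixture()
def straight_design():
    """One straight 3-km transect along y = 500 in a 4 x 1 km extent."""
    xs = np.arange(0.0, 3000.0 + 1, 30.0)
    wp = np.column_stack([xs + 200.0, np.full_like(xs, 500.0)])
    return SurveyDesign(quadrats=[(0.0, 0.0, 4000.0, 1000.0)], transects=[wp],
                        quadrat_of=[0], extent=(0.0, 0.0, 4000.0, 1000.0))


def make_grid(codes, cell_m=30.0):
    codes = np.asarray(codes, dtype=np.int16)
    return HabitatGrid(codes, origin=(0.0, codes.shape[0] * cell_m), cell_m=cell_m)


@pytest.fixture()
def uniform_grassland_grid():
    return make_grid(np.full((20, 20), CLASS_CODES["grassland"]))
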