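import numpy as np
import pytest

from morphowrap import BodyParams, GroupEffect, build_grid, make_population
from morphowrap.synthetic import default_grid_bbox

#: Fixed seed used by every seeded fixture and study in the suite.
STUDY_SEED = 1


@pytest.fixture(scope="session")
def body_params() -> BodyParams:
    return BodyParams()


@pytest.fixture(scope="session")
def small_grid(body_params):
    """A coarse 60x48 template grid over the default body."""
    return build_grid(60, 48, default_grid_bbox(body_params))


@pytest.fixture(scope="session")
def small_study(small_grid, body_params):
    """A small two-group population (5 vs 4) with the default effect."""
    return make_population(
        small_grid, body_params, GroupEffect(), n_control=5, n_treated=4, seed=STUDY_SEED
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(STUDY_SEED)
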