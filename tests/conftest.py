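import numpy as np
import pytest

from splinemap import connectivity as cn
from splinemap import simulate as sim
from splinemap import tprs

#: population scale used for inference-grade synthetic data; the default
#: median of 2e4 persons yields ~50 events over 150 areas, which is too
#: little information for any variance-attribution test to be meaningful.
INFORMATIVE_POP = 2e5


@pytest.fixture(scope="session")
def geography150():
    geog, flows = sim.synthetic_geography(150, seed=1, pop_median=INFORMATIVE_POP)
    return geog, flows


@pytest.fixture(scope="session")
def coords150(geography150):
    geog, _ = geography150
    return cn.scale_coordinates(geog.centroids, "distance")


@pytest.fixture(scope="session")
def basis150(coords150):
    return tprs.build_tprs_basis(coords150, K=30)


@pytest.fixture(scope="session")
def movement150(geography150):
    geog, _ = geography150
    return sim.abstract_coordinates(geog.n, seed=7777, source_label="movement")


@pytest.fixture(scope="session")
def small_geog():
    return sim.synthetic_geography(60, seed=11, pop_median=INFORMATIVE_POP)[0]


def random_coords(n, seed, label="distance"):
    rng = np.random.default_rng(seed)
    return cn.scale_coordinates(rng.uniform(size=(n, 2)), label)
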