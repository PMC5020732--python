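import numpy as np
import pytest

import lurcity as L


@pytest.fixture(scope="session")
def small_scene():
    """A 2 km x 2 km city at 20 m cells, shared across tests."""
    return L.generate_city(L.CityConfig(cell_size=20.0), seed=7)


@pytest.fixture(scope="session")
def catalog(small_scene):
    return L.build_catalog(small_scene)


@pytest.fixture(scope="session")
def ppv_rasters(small_scene, catalog):
    return L.PPVComputer(small_scene).compute_all(catalog)


@pytest.fixture(scope="session")
def stations(small_scene):
    return L.place_stations(small_scene, 23, seed=8)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
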