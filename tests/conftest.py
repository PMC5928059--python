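import numpy as np
import pytest

from ossify.fuzzy import default_controller
from ossify.geometry import GeometryParams, build_geometry
from ossify.materials import TissueLibrary
from ossify.mesh import generate_mesh
from ossify.oracles import make_fixture_mesh


@pytest.fixture(scope="session")
def lib():
    return TissueLibrary()


@pytest.fixture(scope="session")
def controller():
    return default_controller()


@pytest.fixture(scope="session")
def coarse_mesh():
    """Small but complete callus mesh (a few hundred elements)."""
    geom = build_geometry(GeometryParams())
    return generate_mesh(geom, target_h=1.6, n_theta=4)


@pytest.fixture()
def single_hex():
    return make_fixture_mesh("single_hex")


@pytest.fixture()
def column10():
    return make_fixture_mesh("column", n=10, height=10.0)


@pytest.fixture()
def two_region():
    return make_fixture_mesh("two_region")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240214)
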