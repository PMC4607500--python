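import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rumbasd.kernel import (
    DiffusivityProfile,
    build_dictionary,
    make_sphere_grid,
)
from rumbasd.phantoms import default_scheme

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme():
    """Single-shell scheme: one b = 0 plus 70 directions at b = 3000 s/mm^2."""
    return default_scheme()


@pytest.fixture(scope="session")
def profile():
    return DiffusivityProfile()


@pytest.fixture(scope="session")
def grid724():
    return make_sphere_grid(724)


@pytest.fixture(scope="session")
def small_grid():
    """Coarse grid for cheap solver tests."""
    return make_sphere_grid(162)


@pytest.fixture(scope="session")
def dictionary724(scheme, grid724, profile):
    return build_dictionary(scheme, grid724, profile)


@pytest.fixture(scope="session")
def small_dictionary(scheme, small_grid, profile):
    return build_dictionary(scheme, small_grid, profile)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
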