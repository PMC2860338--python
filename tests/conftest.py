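import numpy as np
import pytest

from sparsart import FanBeamGeometry, build_system_matrix, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom32():
    return generate_phantom(32)


@pytest.fixture(scope="session")
def geom_small():
    return FanBeamGeometry(n_views=20, n_detectors=32)


@pytest.fixture(scope="session")
def system_small(geom_small):
    """20-view, 32-detector projector on a 32x32 grid (shared, ~1 s to build)."""
    return build_system_matrix(geom_small, 32)
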