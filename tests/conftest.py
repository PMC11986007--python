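import numpy as np
import pytest

from hgiscan.hgi import build_forward_operator, hg_basis
from hgiscan.optics import OpticsConfig


@pytest.fixture(scope="session")
def optics():
    return OpticsConfig()


@pytest.fixture(scope="session")
def basis():
    """Full 441-mode basis at the default mode width."""
    return hg_basis(20, 30.0)


@pytest.fixture(scope="session")
def small_basis():
    """Cheap basis for quadrature-oracle tests."""
    return hg_basis(4, 12.0)


@pytest.fixture(scope="session")
def widefield_operator(basis, optics):
    return build_forward_operator(basis, optics, 50, frame_px=210)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
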