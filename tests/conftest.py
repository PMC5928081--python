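import numpy as np
import pytest

from destreak.phantoms import EllipsePhantom, EllipseSpec, make_shepp_logan
from destreak.projector import FanBeamGeometry

FOV = 170.0  # mm, comfortably inside the default fan coverage (~175.7 mm)


@pytest.fixture(scope="session")
def shepp():
    return make_shepp_logan(FOV)


@pytest.fixture()
def disk_phantom():
    """Centered disk, radius 40 mm, attenuation 1.0."""
    return EllipsePhantom((EllipseSpec(0.0, 0.0, 40.0, 40.0, 0.0, 1.0),), FOV)


@pytest.fixture()
def offset_disk_phantom():
    return EllipsePhantom((EllipseSpec(25.0, -10.0, 15.0, 15.0, 0.0, 0.7),), FOV)


@pytest.fixture()
def small_geometry():
    """Coarse geometry for fast projector tests."""
    return FanBeamGeometry(n_detector_bins=185, n_views=90)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
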