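import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from patrecon import acoustics as ac


@pytest.fixture(scope="session")
def geom8():
    return ac.AcousticGeometry(m=8)


@pytest.fixture(scope="session")
def A8(geom8):
    return ac.assemble_forward_matrix(geom8, precision="float64")


@pytest.fixture(scope="session")
def geom16():
    return ac.AcousticGeometry(m=16)


@pytest.fixture(scope="session")
def A16(geom16):
    return ac.assemble_forward_matrix(geom16, precision="float64")


@pytest.fixture(scope="session")
def geom32():
    return ac.AcousticGeometry(m=32)


@pytest.fixture(scope="session")
def A32(geom32):
    return ac.assemble_forward_matrix(geom32, precision="float64")


@pytest.fixture(scope="session")
def geom64():
    return ac.AcousticGeometry(m=64)


def smooth_blob(m: int, center, radius: float, sigma: float) -> np.ndarray:
    """Compactly supported smooth phantom (blurred disc, peak 1)."""
    y, x = np.mgrid[:m, :m]
    img = gaussian_filter(
        (((y - center[0]) ** 2 + (x - center[1]) ** 2) <= radius ** 2
         ).astype(float), sigma)
    return np.clip(img / img.max(), 0.0, 1.0)


@pytest.fixture(scope="session")
def blob64(geom64):
    """Canonical central smooth phantom at m=64 with noiseless data."""
    img = smooth_blob(64, (28, 32), 10.0, 2.5)
    return img, ac.propagate(img, geom64)


@pytest.fixture(scope="session")
def blob32(geom32):
    """Canonical central smooth phantom at m=32 with noiseless data."""
    img = smooth_blob(32, (16, 16), 5.0, 1.5)
    return img, ac.propagate(img, geom32)


def rel_l2(a, b, region=slice(None)) -> float:
    a = np.asarray(a)[region]
    b = np.asarray(b)[region]
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))
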