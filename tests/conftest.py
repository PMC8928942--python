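import numpy as np
import pytest

from freqalign.synthetic import make_phantom


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom(64, n_blobs=8, seed=3)


@pytest.fixture(scope="session")
def phantom128():
    return make_phantom(128, n_blobs=10, seed=5)


@pytest.fixture(scope="session")
def phantom256():
    return make_phantom(256, n_blobs=12, seed=0)


@pytest.fixture(scope="session")
def smooth_gaussian_128():
    """Radially symmetric 2-D Gaussian centered on the rotation center."""
    m = 128
    c = m // 2
    yy, xx = np.indices((m, m), dtype=float)
    return np.exp(-((xx - c) ** 2 + (yy - c) ** 2) / (2.0 * (m / 8.0) ** 2))


def disc_mask(m: int, margin: float = 1.0) -> np.ndarray:
    """Boolean mask of the inscribed disc (radius m/2 - margin)."""
    c = m // 2
    yy, xx = np.indices((m, m), dtype=float)
    return (xx - c) ** 2 + (yy - c) ** 2 <= (m / 2.0 - margin) ** 2
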