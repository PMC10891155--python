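import numpy as np
import pytest

from registain import phantom as ph


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240223)


@pytest.fixture(scope="session")
def small_phantom():
    """128x128 phantom with 20 non-overlapping nuclei, reused read-only."""
    spec = ph.PhantomSpec(height=128, width=128, n_nuclei=20, seed=3)
    return ph.generate_phantom(spec)


@pytest.fixture()
def textured_pair(rng):
    """A pair of smooth random textures on [0, 1], 40x40."""
    from scipy.ndimage import gaussian_filter

    a = gaussian_filter(rng.random((40, 40)), 2.0)
    b = gaussian_filter(rng.random((40, 40)), 2.0)
    for x in (a, b):
        x -= x.min()
        x /= x.max()
    return a, b
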