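import numpy as np
import pytest

from destreak.collaborative_filter import FilterConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """Filter config sized for small test images."""
    return FilterConfig(block_size=4, step=2, search=15, max_group=8)


@pytest.fixture(scope="session")
def phantom():
    from destreak.phantom_sim import make_phantom_sinogram

    return make_phantom_sinogram()


@pytest.fixture
def toy_sinogram():
    """Small structured sinogram, streaks-vertical orientation."""
    m, n = 48, 96
    xx = np.linspace(0, 1, n)
    aa = np.linspace(0, 1, m)[:, None]
    return np.sin(2 * np.pi * (xx * 3 + aa)) + 0.3 * np.cos(2 * np.pi * xx * 5)[None, :]
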