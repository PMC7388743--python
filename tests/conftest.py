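import numpy as np
import pytest

from waveshrink import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def phantom():
    """Default 256x256 brain-like phantom (session-cached; read-only)."""
    img = make_phantom(PhantomSpec())
    img.setflags(write=False)
    return img


@pytest.fixture(scope="session")
def small_phantom():
    img = make_phantom(PhantomSpec(size=(64, 64), seed=3))
    img.setflags(write=False)
    return img


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
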