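import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return np.hypot(rr - center[0], cc - center[1]) <= radius
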