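import numpy as np
import pytest

from ctsnet.network import NetworkSpec
from ctsnet.phantoms import PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def smoke_phantom_spec():
    """Noise-free 64x64 phantom used by the desk-scale learning checks."""
    return PhantomSpec(h=64, w=64, mean_depths=(10, 24, 36, 48, 60),
                       amplitude=2.0, smoothness=8.0, speckle_sigma=0.0)


@pytest.fixture
def tiny_net_spec():
    """Reduced network that still exercises every stage."""
    return NetworkSpec(base_channels=16, heads=(2, 4, 8), stripe_widths=(1, 2, 4))
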