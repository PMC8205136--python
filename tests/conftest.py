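import numpy as np
import pytest

from echoseg.model import ArchitectureConfig, ExpandedUNet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_arch():
    """A small architecture for fast forward/backward tests."""
    return ArchitectureConfig(depth=2, base_channels=2, dropout_rate=0.0,
                              input_size=(8, 8))


@pytest.fixture
def tiny_model(tiny_arch):
    return ExpandedUNet(tiny_arch, seed=3)
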