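import numpy as np
import pytest

from biofilmvol import ExperimentConfig, MultiChannelStack
from biofilmvol.io import stack_from_channels


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_channel_config():
    return ExperimentConfig(channel_labels=["A", "B"])


def make_control(k: float, brightness: float = 200.0, shape=(6, 32, 32), slab=4):
    """Noise-free single-label control: species A slab, B = k * A."""
    a = np.zeros(shape)
    a[:slab] = brightness
    b = k * a
    return stack_from_channels([a, b], ["A", "B"])


@pytest.fixture
def exact_mixing_control():
    return make_control(0.10)
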