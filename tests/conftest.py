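import numpy as np
import pytest

from coopgate.presets import get_gating_preset, get_signal_preset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sparklet_gating():
    return get_gating_preset("cav13s_sparklet")


@pytest.fixture
def sparklet_signal():
    return get_signal_preset("sparklet_default")
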