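import numpy as np
import pytest

import meanet.tensor as T
from meanet.network import NetworkConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    """Smallest practical network for structural tests."""
    return NetworkConfig(input_channels=1, stage_widths=(4, 8, 12, 16),
                         attention_maps=4, se_reduction=2)


@pytest.fixture
def float64_mode(monkeypatch):
    """Run the autodiff core in float64 for tight finite-difference checks."""
    monkeypatch.setattr(T, "DEFAULT_DTYPE", np.float64)
    yield
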