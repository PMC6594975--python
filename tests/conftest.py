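import numpy as np
import pytest

from freqtag.simulate import SimulationConfig


@pytest.fixture
def noiseless_cfg():
    """Default design with noise and drift switched off."""
    return SimulationConfig(noise_sd=0.0, drift_coefficients=(0.0, 0.0, 0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
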