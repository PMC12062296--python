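import numpy as np
import pytest

from saccvis import MainSequence, ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def main_sequence():
    return MainSequence()


@pytest.fixture
def coarse_params():
    """Model parameters at simulation (not display) resolution."""
    return ModelParams(dx=0.1, dt=2.0, runs_per_condition=10, trials_per_sample=100)
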