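import numpy as np
import pytest

from rtentropy import ExGaussian, Exponential

BASELINE = (400.0, 30.0, 60.0)


@pytest.fixture
def exg_baseline():
    return ExGaussian(*BASELINE)


@pytest.fixture
def exp_half():
    return Exponential(0.5)


@pytest.fixture
def grid_ms():
    """1 ms grid over [0, 2500] ms, the default ex-Gaussian tabulation."""
    return np.arange(0.0, 2501.0, 1.0)
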