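import numpy as np
import pytest

from circadia import LightSchedule, Regime


@pytest.fixture
def rng():
    return np.random.default_rng(20180759)


@pytest.fixture
def ld():
    return LightSchedule(regime=Regime.LD)


@pytest.fixture
def dd():
    return LightSchedule(regime=Regime.DD)
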