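import numpy as np
import pytest

from dyadvigor import (EffortCostParams, SessionConfig, SubjectProfile,
                       WristDynamics)
from dyadvigor.params import (AD_LAW_AVERAGE, COST_OF_TIME_AVERAGE,
                              COST_OF_TIME_FAST, COST_OF_TIME_SLOW,
                              TARGET_AMPLITUDES_RAD)
from dyadvigor.solo_oc import CostOfTime


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def dyn():
    return WristDynamics()


@pytest.fixture
def effort():
    return EffortCostParams()


@pytest.fixture
def amplitudes():
    return np.asarray(TARGET_AMPLITUDES_RAD)


@pytest.fixture
def G_average():
    return CostOfTime(*COST_OF_TIME_AVERAGE)


@pytest.fixture
def G_fast():
    return CostOfTime(*COST_OF_TIME_FAST)


@pytest.fixture
def G_slow():
    return CostOfTime(*COST_OF_TIME_SLOW)


@pytest.fixture
def average_profile():
    return SubjectProfile("avg", *AD_LAW_AVERAGE, duration_cv=0.0, noise_sd=0.0)


@pytest.fixture
def small_solo_config():
    return SessionConfig(trials_per_target_per_direction=2, quantize=False, seed=7)
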