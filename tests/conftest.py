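import numpy as np
import pytest

from clustrack.sim import AcquisitionSchedule, make_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def basal():
    return make_scenario("basal")


@pytest.fixture
def schedule_200ms():
    return AcquisitionSchedule(t_exp=0.2, t_int=0.2, n_frames=300)
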