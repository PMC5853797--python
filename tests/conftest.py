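import numpy as np
import pytest

import chloroquench as cq


@pytest.fixture(scope="session")
def wt():
    return cq.get_profile("WT")


@pytest.fixture(scope="session")
def large():
    return cq.get_profile("large")


@pytest.fixture(scope="session")
def single_day():
    return cq.build_single_fluctuating_day()


@pytest.fixture(scope="session")
def ladder_regime():
    return cq.build_photorelocation_regime()


@pytest.fixture(scope="session")
def wt_noiseless(single_day, wt):
    """Noiseless WT experiment on the fluctuating day, with observed pulses."""
    trace, truth = cq.simulate_experiment(single_day, wt, noise_sd=0.0,
                                          seed=0, m_true=1.0)
    pulses = cq.render_observed_pulses(truth, trace, m=1.0, cv_noise=0.0)
    return trace, truth, pulses


@pytest.fixture(scope="session")
def large_noiseless(single_day, large):
    trace, truth = cq.simulate_experiment(single_day, large, noise_sd=0.0,
                                          seed=0, m_true=1.0)
    pulses = cq.render_observed_pulses(truth, trace, m=1.0, cv_noise=0.0)
    return trace, truth, pulses


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
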