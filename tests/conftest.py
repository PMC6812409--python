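import dataclasses

import pytest

from ditcalc.preprocess import bin_trace
from ditcalc.simulate import SimConfig, simulate_mouse


@pytest.fixture(scope="session")
def config():
    return SimConfig()


@pytest.fixture(scope="session")
def noiseless_config():
    return dataclasses.replace(SimConfig(), noise_sd=0.0)


@pytest.fixture(scope="session")
def sim_pair(config):
    """One simulated animal at default (noisy) settings."""
    return simulate_mouse(config, 12345, "m01")


@pytest.fixture(scope="session")
def noiseless_pair(noiseless_config):
    return simulate_mouse(noiseless_config, 7, "m01")


@pytest.fixture(scope="session")
def binned_pair(sim_pair):
    fasted, fed, truth = sim_pair
    return bin_trace(fasted), bin_trace(fed), truth
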