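import numpy as np
import pytest

from pingnet import config, network

SEED = 12345


@pytest.fixture(scope="session")
def rsp_params():
    return config.RSPParams()


@pytest.fixture(scope="session")
def fs_params():
    return config.FSParams()


@pytest.fixture(scope="session")
def control_instance():
    """Control (all-low-conductance) network, wired and DC-calibrated."""
    return network.build_network(config.NetworkConfig(), seed=SEED)


@pytest.fixture(scope="session")
def noise_scale(control_instance):
    """OU fluctuation multiplier calibrated to the 2.56 mV RSP V_m SD."""
    return network.calibrate_noise_scale(
        control_instance, noise_seed=777, initial_scale=20.0
    )


@pytest.fixture(scope="session")
def control_run(control_instance, noise_scale):
    """One 10-s realization of the calibrated control network."""
    return network.run_simulation(
        control_instance, noise_seed=2024, duration=10_000.0, noise_scale=noise_scale
    )
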