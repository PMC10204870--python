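import numpy as np
import pytest

import aptamelt as am


@pytest.fixture(scope="session")
def noise_free_protocol():
    return am.ScanProtocol(noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def balanced_system():
    """A system where free and bound peaks carry comparable signal."""
    return am.BindingSystem(aptamer_conc=20.0, target_conc=20.0, kd=5.0)


@pytest.fixture(scope="session")
def noise_free_plate(balanced_system, noise_free_protocol):
    return am.simulate_plate(balanced_system, noise_free_protocol)


@pytest.fixture(scope="session")
def gradient_plate_noise_free(noise_free_protocol):
    return am.simulate_gradient(
        am.STANDARD_GRADIENT_NM, am.STANDARD_TARGET_NM, protocol=noise_free_protocol
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
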