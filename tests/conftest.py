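import numpy as np
import pytest

from sqbold.fitting import build_design, fit_weights
from sqbold.model import AcquisitionProtocol
from sqbold.phantom import PhantomSpec, generate_phantom, simulate_tau_series


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def default_design(protocol):
    return build_design(protocol.long_taus)


@pytest.fixture(scope="session")
def default_weights(protocol):
    taus = (0.0,) + protocol.long_taus
    return fit_weights(np.asarray(taus), "inverse_tau")


@pytest.fixture(scope="session")
def small_truth():
    """Reduced-grid phantom reused across read-only tests."""
    return generate_phantom(PhantomSpec(grid_shape=(48, 48, 9), seed=7))


@pytest.fixture(scope="session")
def noise_free_series(small_truth):
    return simulate_tau_series(small_truth, snr=np.inf)
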