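import numpy as np
import pytest

from fluorbind.decay import DecayCurve, convolve_model
from fluorbind.simulate import AnisotropyConfig, DecayConfig, gen_anisotropy_pair, gen_decay


@pytest.fixture(scope="session")
def bsa_decay_config():
    """Biexponential study conditions: 2.62/1.11 ns, 22.8/77.2%, 1e4 peak."""
    return DecayConfig()


@pytest.fixture(scope="session")
def noisefree_decay():
    return gen_decay(DecayConfig(poisson=False), seed=0)


@pytest.fixture(scope="session")
def noisy_decay():
    return gen_decay(DecayConfig(), seed=1)


@pytest.fixture(scope="session")
def noisefree_anisotropy_pair():
    cfg = AnisotropyConfig(theta_c_ns=5.0, r0=0.3, decay=DecayConfig(poisson=False))
    return gen_anisotropy_pair(cfg, seed=0)


@pytest.fixture
def delta_irf_curve():
    """Single-exponential decay with a delta-function IRF (tau = 1 ns)."""
    t = np.arange(512) * 0.05
    irf = np.zeros(512)
    irf[0] = 1.0
    counts = convolve_model([1.0], [10_000.0], irf, 0.05)
    return DecayCurve(time=t, counts=counts, irf_counts=irf)
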