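import numpy as np
import pytest

from spikecoding import Network, make_smooth_noise


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_balanced_net():
    """20-neuron network in the analytically balanced state Ω = -F Fᵀ,
    thresholds T_i = ‖F_i‖²/2."""
    rng = np.random.default_rng(1)
    N, M = 20, 2
    F = rng.standard_normal((N, M))
    F /= np.linalg.norm(F, axis=1, keepdims=True)
    Omega = -F @ F.T
    T = 0.5 * np.sum(F**2, axis=1)
    return Network(F=F, Omega=Omega, T=T, dt=1e-3)


@pytest.fixture(scope="session")
def noise_signal():
    return make_smooth_noise(2, 20.0, 1e-3, seed=2).scaled(1.5)
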