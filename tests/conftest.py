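import numpy as np
import pytest

from icreach import lqg
from icreach.plant import (
    NOMINAL_DAMPING_IM,
    NOMINAL_MASS_IM,
    PlantParams,
    Q_INF_NOMINAL,
    R_INF,
    build_plant,
)


@pytest.fixture(scope="session")
def internal_model():
    """Nominal internal model: m = 2 kg, gamma = 8 N s/m, nominal noise."""
    return build_plant(PlantParams(m=NOMINAL_MASS_IM, gamma=NOMINAL_DAMPING_IM))


@pytest.fixture(scope="session")
def nominal_gains(internal_model):
    """Stationary LQG gains designed from the nominal internal model."""
    return lqg.design_lti_gains(internal_model, Q_INF_NOMINAL, R_INF)


@pytest.fixture(scope="session")
def quiet_internal_model():
    """Internal model with tenfold-reduced measurement noise (V = V0/10)."""
    return build_plant(
        PlantParams(m=NOMINAL_MASS_IM, gamma=NOMINAL_DAMPING_IM), noise_scale=0.1
    )


@pytest.fixture(scope="session")
def quiet_gains(quiet_internal_model):
    return lqg.design_lti_gains(quiet_internal_model, Q_INF_NOMINAL, R_INF)


def random_stable_system(rng: np.random.Generator, n: int = 4, q: int = 2):
    """A random detectable/stabilizable LTI system with modest gains.

    Used to cross-validate the monodromy constructions against their oracles
    on systems unrelated to the hand model.
    """
    A = rng.normal(scale=1.0, size=(n, n)) - 1.5 * np.eye(n)
    A_bar = A + 0.3 * rng.normal(size=(n, n))
    B = rng.normal(size=(n, 1))
    C = rng.normal(size=(q, n))
    K = rng.normal(scale=0.5, size=(1, n))
    L = rng.normal(scale=0.5, size=(n, q))
    return A_bar, A, B, C, K, L
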