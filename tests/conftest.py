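import numpy as np
import pytest

from spinacarb import DEFAULT_PARAMETERS, equifinal_state


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMETERS


@pytest.fixture(scope="session")
def equilibrium(params):
    return equifinal_state(params)


def random_parameter_sets(n, seed):
    """Log-normal perturbations of the reference set (valid by construction)."""
    rng = np.random.default_rng(seed)
    base = DEFAULT_PARAMETERS
    for _ in range(n):
        yield base.replace(
            G_R=base.G_R * rng.lognormal(0, 0.4),
            G_beta=base.G_beta * rng.lognormal(0, 0.4),
            D_beta=base.D_beta * rng.lognormal(0, 0.2),
            D_R=base.D_R * rng.lognormal(0, 0.2),
            G_E=base.G_E * rng.lognormal(0, 0.2),
            P=base.P * rng.lognormal(0, 0.2),
            alpha_G=base.alpha_G * rng.lognormal(0, 0.1),
            beta_G=base.beta_G * rng.lognormal(0, 0.1),
            alpha_I=base.alpha_I * rng.lognormal(0, 0.1),
            beta_I=base.beta_I * rng.lognormal(0, 0.1),
        )
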