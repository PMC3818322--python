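import numpy as np
import pytest
from hypothesis import settings

from oikofeed import DEFAULT_PARAMETERS, Environment, Scenario, simulate

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

#: Canonical fitted values of the four estimated parameters (i, ki, a, ka).
THETA_TRUE = np.array([1.2232, 0.0282, 0.4818, 0.0029])


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMETERS


@pytest.fixture(scope="session")
def standard_run():
    """Constant-food reference run: FC=100 µgC/l, 15 °C, 1 µgC organism,
    four house cycles from an all-zero initial state."""
    scenario = Scenario(
        environment=Environment.constant_food(15.0, 100.0, 1.0),
        n_house_cycles=4,
    )
    return simulate(scenario)
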