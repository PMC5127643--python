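import pytest
from hypothesis import settings

from heatshock import (
    DEFAULT_INITIAL,
    DEFAULT_PARAMS,
    heat_shock,
    integrate_fixed_rk4,
    up_from_temperature,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def init39():
    """Basal initial state with the unfolded-protein load of a 39 C shock."""
    return DEFAULT_INITIAL.replace(up_free=up_from_temperature(39.0))


@pytest.fixture(scope="session")
def shock39(params):
    """Reference 25->39 C upshift trajectory, 120 min, production tolerances."""
    return heat_shock(params, 39.0, 120.0)


@pytest.fixture(scope="session")
def rk4_oracle(params, init39):
    """Fixed-step RK4 solution of the same scenario (independent integrator)."""
    return integrate_fixed_rk4(params, init39, 120.0, step=1e-3)
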