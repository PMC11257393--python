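import pytest
from hypothesis import settings, HealthCheck

import qsmemory as qs

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return qs.circuit_defaults()


@pytest.fixture(scope="session")
def reference(params):
    """ON/OFF steady states grown from 1 cell/ml — shared across the suite."""
    return qs.characterize_states(params)


@pytest.fixture(scope="session")
def deact_traj(params, reference):
    """Canonical deactivation trace: ON culture diluted 1e11 -> 1e6 cell/ml."""
    return qs.deactivation_trajectory(params, reference, N_0=1e6, t_end=400.0)


@pytest.fixture(scope="session")
def analytical_params():
    return qs.analytical_defaults()
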