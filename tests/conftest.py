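"""Shared fixtures.

The expensive simulations (resting state, 60 s and 600 s anoxia runs) are
session-scoped: every test that needs the standard oxygen-glucose
deprivation trace sees the identical deterministic object.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import anoxwave as aw

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return aw.ModelParameters()


@pytest.fixture(scope="session")
def rest_state(params):
    return aw.find_resting_state(params)


@pytest.fixture(scope="session")
def ogd_trace(params, rest_state):
    """Standard 60 s oxygen-glucose-deprivation run."""
    return aw.run_ogd(params, rest_state, 60.0)


@pytest.fixture(scope="session")
def ogd_trace_long(params, rest_state):
    """600 s run, long enough to reach the final voltage asymptote."""
    return aw.run_ogd(params, rest_state, 600.0)


@pytest.fixture(scope="session")
def ogd_report(ogd_trace):
    return aw.analyze_trace(ogd_trace)


@pytest.fixture(scope="session")
def rest_trace(params, rest_state):
    """10 s physiological run from the resting state."""
    return aw.run_rest(params, rest_state, 10.0)


@pytest.fixture(scope="session")
def random_states():
    """Physiologically plausible random states for algebraic checks."""
    rng = np.random.default_rng(20260923)
    n = 1000
    return np.column_stack([
        rng.uniform(-90.0, 50.0, n),     # V
        rng.uniform(0.0, 1.0, n),        # h
        rng.uniform(0.0, 1.0, n),        # n
        rng.uniform(5.0, 60.0, n),       # Na_i
        rng.uniform(90.0, 160.0, n),     # Na_o
        rng.uniform(80.0, 160.0, n),     # K_i
        rng.uniform(1.0, 50.0, n),       # K_o
        rng.uniform(3.0, 40.0, n),       # Cl_i
        rng.uniform(80.0, 150.0, n),     # Cl_o
    ])
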