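import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def fast_scenario():
    from semifate.scenarios import BUILTIN_SCENARIOS

    return BUILTIN_SCENARIOS["fast"]


@pytest.fixture
def slow_scenario():
    from semifate.scenarios import BUILTIN_SCENARIOS

    return BUILTIN_SCENARIOS["slow"]


@pytest.fixture
def exp_series():
    """Noise-free single-exponential decay: k = 5e-4 s^-1, 16 points / 900 s."""
    from semifate.chamber_kinetics import DecaySeries

    t = np.linspace(0.0, 900.0, 16)
    return DecaySeries("clean", t, 5e13 * np.exp(-5e-4 * t))
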