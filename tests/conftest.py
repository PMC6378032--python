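import pytest
from hypothesis import HealthCheck, settings

from adcascade import preset, simulate_risk_pair

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def early_pair():
    return simulate_risk_pair(preset("early_onset"))


@pytest.fixture(scope="session")
def amyloid_first_pair():
    return simulate_risk_pair(preset("late_amyloid_first"))


@pytest.fixture(scope="session")
def tau_first_pair():
    return simulate_risk_pair(preset("late_tau_first"))


@pytest.fixture(scope="session")
def rx_pair():
    return simulate_risk_pair(preset("late_amyloid_first_rx"))
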