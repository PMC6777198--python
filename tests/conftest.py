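import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def calc_config():
    from aortadose.dosecalc import CalculatorConfig

    return CalculatorConfig()


@pytest.fixture(scope="session")
def sim_config():
    from aortadose.imaging import SimulationConfig

    return SimulationConfig()
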