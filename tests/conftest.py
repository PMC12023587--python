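import pytest

from ecsubtype import CallerConfig, generate_cohort, load_fixture
from ecsubtype.simulate import SimulationConfig


@pytest.fixture(scope="session")
def config():
    return CallerConfig()


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def fig4():
    return load_fixture("fig4")


@pytest.fixture(scope="session")
def small_cohort():
    """Reusable 40-sample synthetic cohort."""
    return generate_cohort(SimulationConfig(n_samples=40), seed=11)
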