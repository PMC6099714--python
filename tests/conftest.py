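import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ephscore import load_fixture


@pytest.fixture(scope="session")
def activities():
    return load_fixture("table1_activities")


@pytest.fixture(scope="session")
def levels():
    return load_fixture("table2_levels")


@pytest.fixture(scope="session")
def components():
    return load_fixture("table2_components")


@pytest.fixture(scope="session")
def solvation():
    return load_fixture("table3_solvation")


@pytest.fixture(scope="session")
def reference_sds():
    return load_fixture("table4_reference_sds")
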