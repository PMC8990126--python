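import pytest
from hypothesis import HealthCheck, settings

from vus_triage.cohort_io import load_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2")


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3")


@pytest.fixture(scope="session")
def table4():
    return load_fixture("table4")
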