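import pytest
from hypothesis import HealthCheck, settings

from dialapp import build_fixture_cohort, run_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_records():
    return build_fixture_cohort()


@pytest.fixture(scope="session")
def fixture_run(fixture_records):
    traces, summary = run_cohort(fixture_records)
    return fixture_records, traces, summary
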