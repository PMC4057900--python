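import pytest
from hypothesis import HealthCheck, settings

import mdevqspr as m

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def paper_records():
    return m.load_paper_dataset()


@pytest.fixture(scope="session")
def group_i(paper_records):
    return m.group_records(paper_records, "I")


@pytest.fixture(scope="session")
def group_ii(paper_records):
    return m.group_records(paper_records, "II")


@pytest.fixture(scope="session")
def published():
    return m.published_predictions()
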