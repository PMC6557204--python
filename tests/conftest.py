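import pytest

from oligoclone.fixture import build_paper_fixture
from oligoclone.timeline import call_timeline, summarize_series


@pytest.fixture(scope="session")
def paper_fixture():
    return build_paper_fixture()


@pytest.fixture(scope="session")
def fixture_observations(paper_fixture):
    return paper_fixture.observations()


@pytest.fixture(scope="session")
def fixture_timeline(fixture_observations):
    assignments, never_present = call_timeline(fixture_observations)
    return assignments, never_present


@pytest.fixture(scope="session")
def fixture_summary(fixture_timeline):
    assignments, _ = fixture_timeline
    return summarize_series(assignments)
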