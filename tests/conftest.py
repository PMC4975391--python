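import pytest

from secondhit.pipeline import PipelineConfig, fixture_report
from secondhit.tsc_status import classify_fixture_statuses
from secondhit.variant_io import load_fixtures


@pytest.fixture(scope="session")
def bundle():
    return load_fixtures()


@pytest.fixture(scope="session")
def statuses(bundle):
    return classify_fixture_statuses(bundle)


@pytest.fixture(scope="session")
def report():
    return fixture_report()


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()
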