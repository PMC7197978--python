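import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from mshrna import (
    DesignConfig,
    design_from_mrna,
    load_default_table,
    make_fixture_transcript,
)


@pytest.fixture(scope="session")
def nn_table():
    return load_default_table()


@pytest.fixture(scope="session")
def default_config():
    return DesignConfig()


@pytest.fixture(scope="session")
def fixture_300():
    """A 300-nt balanced synthetic transcript used across tests."""
    return make_fixture_transcript(length=300, gc_fraction=0.5, seed=7)


@pytest.fixture(scope="session")
def trivalent_design(fixture_300, default_config):
    """(winners, template) for the default trivalent design."""
    return design_from_mrna(fixture_300, 3, default_config)
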