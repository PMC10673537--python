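import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from dipa.cohort import default_config, generate
from dipa.mme import load_conversion_table
from dipa.scoring import annotate_visits


@pytest.fixture(scope="session")
def table():
    return load_conversion_table()


@pytest.fixture(scope="session")
def default_visits(table):
    """The study-default synthetic cohort at a fixed seed."""
    return generate(default_config(seed=1976), table=table)


@pytest.fixture(scope="session")
def annotated_visits(default_visits, table):
    return annotate_visits(list(default_visits), table)
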