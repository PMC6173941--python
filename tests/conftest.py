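import logging

import pytest
from hypothesis import settings

from rarescreen.fixtures import fixture_from_tables

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(autouse=True)
def _quiet_warnings(caplog):
    # expected per-variant warnings (absent modifiers etc.) stay out of output
    logging.getLogger("rarescreen").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def paper_fixture():
    return fixture_from_tables()
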