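import pytest

from liquidpanel import default_panel
from liquidpanel.io import load_table1_fixture, table1_metadata


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_meta():
    return table1_metadata()
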