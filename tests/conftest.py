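import pytest

from sulfurox import Conditions, ThermoTable


@pytest.fixture(scope="session")
def table():
    return ThermoTable.default()


@pytest.fixture(scope="session")
def standard():
    return Conditions.standard()
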