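import pytest

from chalqsar.pipeline import model_table
from chalqsar.registry import load_registry


@pytest.fixture(scope="session")
def registry_records():
    return load_registry()


@pytest.fixture(scope="session")
def fixture_table():
    """Descriptor/pIC50 table for the 15 packaged compounds."""
    return model_table()
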