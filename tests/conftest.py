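import pytest

from iplome.annotate import default_rules_path, read_rules
from iplome.database import (
    generate_database,
    read_component_table,
    read_unique_component_table,
    starter_component_path,
    starter_unique_component_path,
)


@pytest.fixture(scope="session")
def components():
    return read_component_table(starter_component_path())


@pytest.fixture(scope="session")
def unique_defs():
    return read_unique_component_table(starter_unique_component_path())


@pytest.fixture(scope="session")
def full_db(components, unique_defs):
    """The full starter database under default chain constraints."""
    return generate_database(components, unique_defs)


@pytest.fixture(scope="session")
def rules():
    return read_rules(default_rules_path())
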