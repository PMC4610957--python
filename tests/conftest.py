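import pytest

from dtec import load_table1


@pytest.fixture(scope="session")
def table1():
    """The packaged 14-row docetaxel reference table."""
    return load_table1()


@pytest.fixture(scope="session")
def by_id(table1):
    return {r.treatment_id: r for r in table1}
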