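import pytest

from daceclone import load_table1_summary


@pytest.fixture(scope="session")
def summary():
    """The embedded 51-site survey summary."""
    return load_table1_summary()
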