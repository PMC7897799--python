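import pytest
from hypothesis import settings

from dlwcalc import load_table1, load_table2

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table2():
    return load_table2()
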