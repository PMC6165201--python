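import pytest

from peptaibiome import io as pio
from peptaibiome.annotate import load_database
from peptaibiome.chem import default_library, trikoningin_ka_v


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def tkv():
    return trikoningin_ka_v()


@pytest.fixture(scope="session")
def table1():
    return pio.load_table1()


@pytest.fixture(scope="session")
def table2():
    return pio.load_table2()


@pytest.fixture(scope="session")
def all_compounds(table1, table2):
    return table1 + table2


@pytest.fixture(scope="session")
def db():
    return load_database()
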