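import pytest

from oatpep import (
    gi_panel,
    load_enzyme,
    load_known_peptides,
    load_oat_proteins,
)


@pytest.fixture(scope="session")
def oat_proteins():
    return load_oat_proteins()


@pytest.fixture(scope="session")
def known_db():
    return load_known_peptides()


@pytest.fixture(scope="session")
def trypsin():
    return load_enzyme("trypsin")


@pytest.fixture(scope="session")
def papain():
    return load_enzyme("papain")


@pytest.fixture(scope="session")
def ficin():
    return load_enzyme("ficin")


@pytest.fixture(scope="session")
def panel():
    return gi_panel()


@pytest.fixture(scope="session")
def all_enzymes():
    names = ("papain", "ficin", "trypsin", "chymotrypsin_high",
             "chymotrypsin_low", "pepsin_ph1_3", "pepsin_ph2")
    return [load_enzyme(n) for n in names]
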