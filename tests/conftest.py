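import pytest

from comaprime import builtin_catalog, gen_template


@pytest.fixture(scope="session")
def catalog():
    return builtin_catalog()


@pytest.fixture(scope="session")
def clade_a_pair(catalog):
    return catalog[0]


@pytest.fixture(scope="session")
def clade_b_pair(catalog):
    return catalog[1]


@pytest.fixture(scope="session")
def clade_a_mix(catalog):
    return catalog[2]


@pytest.fixture(scope="session")
def clade_b_mix(catalog):
    return catalog[3]


@pytest.fixture(scope="session")
def default_template():
    return gen_template()
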