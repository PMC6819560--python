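import pytest

from mitoburden.annotation import make_annotator
from mitoburden.haplogroups import load_tree
from mitoburden.reference import load_reference
from mitoburden.workflow import (
    load_demo_frequency_table,
    load_demo_pathogenicity_table,
)


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def tree():
    return load_tree()


@pytest.fixture(scope="session")
def freqs():
    return load_demo_frequency_table()


@pytest.fixture(scope="session")
def path_table():
    return load_demo_pathogenicity_table()


@pytest.fixture(scope="session")
def annotator(reference):
    return make_annotator(reference)
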