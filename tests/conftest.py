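import pytest

from oboowl.fixtures import FixtureParams, generate_document, table2_corpus
from oboowl.ids import registry_from_header
from oboowl.io import parse_obo


@pytest.fixture(scope="session")
def corpus():
    """The four printed OBO/OWL golden pairs."""
    return table2_corpus()


@pytest.fixture(scope="session")
def go_registry():
    """Registry with the GO ID space declared as in the worked example."""
    return registry_from_header(parse_obo("idspace: GO http://www.go.org/owl#\n"))


@pytest.fixture
def small_doc():
    """A small but construct-rich synthetic document."""
    return generate_document(FixtureParams(n_terms=20, n_typedefs=3, p_logical=0.2, seed=1))
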