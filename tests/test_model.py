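"""Document model: layer classification, validation, canonicalization."""

import random

import pytest

from oboowl.model import (
    Layer,
    OBODocument,
    Severity,
    Stanza,
    StanzaKind,
    canonicalize,
    classify_tag,
    validate_document,
)
from oboowl.io import parse_obo, serialize_obo

# the published layer-cake assignment of OBO constructs (the `relationship`
# tag is listed under both Core and Ontology Extensions; Core wins)
LAYER_TABLE = {
    Layer.CORE: ["id", "idspace", "relationship"],
    Layer.VOCABULARY: ["name", "definition", "def", "comment", "is_a", "domain", "range"],
    Layer.EXTENSIONS: [
        "format-version", "version", "date", "saved-by", "auto-generated-by",
        "namespace", "default-namespace", "subsetdef", "alt_id", "subset",
        "synonym", "is_obsolete", "is_cyclic", "is_transitive", "is_symmetric",
        "import", "synonymtypedef", "intersection_of", "union_of",
        "disjoint_from", "replaced_by", "consider", "inverse_of",
        "transitive_over",
    ],
}


@pytest.mark.parametrize(
    "tag,layer",
    [(t, layer) for layer, tags in LAYER_TABLE.items() for t in tags],
)
def test_classify_tag_matches_layer_cake(tag, layer):
    assert classify_tag(tag) is layer


@pytest.mark.parametrize("tag", ["frobnicate", "", "xref", "ID", "is_A"])
def test_classify_tag_is_total_and_case_sensitive(tag):
    assert classify_tag(tag) is Layer.UNKNOWN


def _errors(issues):
    return [i for i in issues if i.severity is Severity.ERROR]


class TestValidation:
    def test_obsolete_stanza_with_relational_clause_is_rejected(self):
        doc = parse_obo("[Term]\nid: X:1\nis_obsolete: true\nis_a: X:2\n")
        issues = validate_document(doc)
        assert [i.code for i in _errors(issues)] == ["E_OBSOLETE_REL"]

    def test_obsolete_with_relationship_is_rejected(self):
        doc = parse_obo("[Term]\nid: X:1\nis_obsolete: true\nrelationship: part_of X:2\n")
        assert any(i.code == "E_OBSOLETE_REL" for i in validate_document(doc))

    def test_wellformed_printed_stanza_is_clean(self, corpus):
        example_b = next(e for e in corpus if e.label == "B")
        assert validate_document(example_b.document) == []

    def test_undeclared_subset_is_warned(self):
        doc = parse_obo("[Term]\nid: X:1\nsubset: slim\n")
        issues = validate_document(doc)
        assert [(i.severity, i.code) for i in issues] == [
            (Severity.WARNING, "W_UNDECLARED_SUBSET")
        ]

    def test_declared_subset_is_clean(self):
        doc = parse_obo('subsetdef: slim "a slim"\n\n[Term]\nid: X:1\nsubset: slim\n')
        assert validate_document(doc) == []

    def test_undeclared_synonym_type_is_warned(self):
        doc = parse_obo('[Term]\nid: X:1\nsynonym: "s" EXACT mytype []\n')
        assert [i.code for i in validate_document(doc)] == ["W_UNDECLARED_SYNTYPE"]

    def test_duplicate_stanza_id_is_an_error(self):
        doc = parse_obo("[Term]\nid: X:1\n\n[Term]\nid: X:1\n")
        assert [i.code for i in _errors(validate_document(doc))] == ["E_DUP_ID"]

    def test_same_id_for_term_and_typedef_is_allowed(self):
        doc = parse_obo("[Term]\nid: X:1\n\n[Typedef]\nid: X:1\n")
        assert _errors(validate_document(doc)) == []

    def test_malformed_boolean_is_an_error(self):
        doc = parse_obo("[Typedef]\nid: r\nis_transitive: yes\n")
        assert [i.code for i in _errors(validate_document(doc))] == ["E_BAD_BOOLEAN"]


class TestCanonicalize:
    def test_idempotent(self, small_doc):
        once = canonicalize(small_doc)
        assert canonicalize(once) == once

    def test_stanza_order_is_not_knowledge(self, small_doc):
        shuffled = OBODocument(header=list(small_doc.header), stanzas=list(small_doc.stanzas))
        random.Random(0).shuffle(shuffled.stanzas)
        assert canonicalize(shuffled) == canonicalize(small_doc)

    def test_clause_order_is_not_knowledge(self, small_doc):
        rng = random.Random(1)
        shuffled_stanzas = []
        for stanza in small_doc.stanzas:
            clauses = list(stanza.clauses)
            rng.shuffle(clauses)
            shuffled_stanzas.append(Stanza(stanza.kind, stanza.id, clauses))
        shuffled = OBODocument(header=list(small_doc.header), stanzas=shuffled_stanzas)
        assert canonicalize(shuffled) == canonicalize(small_doc)

    def test_header_order_is_not_knowledge(self, small_doc):
        shuffled = OBODocument(header=list(small_doc.header), stanzas=list(small_doc.stanzas))
        random.Random(2).shuffle(shuffled.header)
        assert canonicalize(shuffled) == canonicalize(small_doc)

    def test_three_stanza_document_against_hand_ordering(self):
        # oracle: the expected canonical order written out by hand
        text = (
            "[Typedef]\nid: part_of\nname: part of\n\n"
            "[Term]\nid: B:2\nis_a: B:1\nname: two\n\n"
            "[Term]\nid: B:1\nname: one\n"
        )
        doc = canonicalize(parse_obo(text))
        assert [(s.kind, s.id.render()) for s in doc.stanzas] == [
            (StanzaKind.TERM, "B:1"),
            (StanzaKind.TERM, "B:2"),
            (StanzaKind.TYPEDEF, "part_of"),
        ]
        # name sorts before is_a in the fixed tag order
        assert [c.tag for c in doc.stanzas[1].clauses] == ["name", "is_a"]

    def test_canonical_serialization_is_deterministic(self, small_doc):
        a = serialize_obo(small_doc, canonical=True)
        shuffled = OBODocument(header=list(small_doc.header), stanzas=list(small_doc.stanzas))
        random.Random(3).shuffle(shuffled.stanzas)
        assert serialize_obo(shuffled, canonical=True) == a
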