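"""Reverse translation and the OBO-expressibility validator."""

import pytest
from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from oboowl.fixtures import FixtureParams, generate_document
from oboowl.forward import translate_document
from oboowl.io import parse_obo, serialize_obo
from oboowl.model import OboError, canonicalize
from oboowl.reverse import ViolationCode, translate_graph, validate_subset
from oboowl.roundtrip import count_entities, count_owl_entities, roundtrip_check

EX = "http://example.org/ns#"


def _restriction_graph(filler_predicate) -> Graph:
    g = Graph()
    c, r = URIRef(EX + "C"), BNode("r")
    g.add((c, RDF.type, OWL.Class))
    g.add((c, RDFS.subClassOf, r))
    g.add((r, RDF.type, OWL.Restriction))
    g.add((r, OWL.onProperty, URIRef(EX + "p")))
    g.add((r, filler_predicate, URIRef(EX + "D")))
    return g


class TestValidateSubset:
    def test_somevaluesfrom_restriction_is_clean(self):
        assert validate_subset(_restriction_graph(OWL.someValuesFrom)) == []

    def test_allvaluesfrom_is_flagged_exactly(self):
        violations = validate_subset(_restriction_graph(OWL.allValuesFrom))
        assert [v.code for v in violations] == [ViolationCode.E_ALLVALUES]

    def test_owl_deprecation_is_flagged_exactly(self):
        g = Graph()
        g.add((URIRef(EX + "C"), RDF.type, OWL.DeprecatedClass))
        violations = validate_subset(g)
        assert [v.code for v in violations] == [ViolationCode.E_DEPRECATION]

    def test_datatype_property_is_flagged_exactly(self):
        g = Graph()
        g.add((URIRef(EX + "p"), RDF.type, OWL.DatatypeProperty))
        violations = validate_subset(g)
        assert [v.code for v in violations] == [ViolationCode.E_DATATYPE_PROP]

    def test_class_property_punning_is_flagged_exactly(self):
        g = Graph()
        g.add((URIRef(EX + "x"), RDF.type, OWL.Class))
        g.add((URIRef(EX + "x"), RDF.type, OWL.ObjectProperty))
        violations = validate_subset(g)
        assert [v.code for v in violations] == [ViolationCode.E_PUNNING]

    def test_individual_assertion_is_flagged_as_punning(self):
        g = Graph()
        g.add((URIRef(EX + "C"), RDF.type, OWL.Class))
        g.add((URIRef(EX + "i"), RDF.type, URIRef(EX + "C")))
        assert ViolationCode.E_PUNNING in {v.code for v in validate_subset(g)}

    def test_cardinality_restriction_is_a_complex_class(self):
        g = _restriction_graph(OWL.someValuesFrom)
        r = next(g.subjects(RDF.type, OWL.Restriction))
        g.add((r, OWL.minCardinality, Literal(2)))
        assert ViolationCode.E_COMPLEX_CLASS in {v.code for v in validate_subset(g)}

    def test_complement_expression_is_a_complex_class(self):
        g = Graph()
        c, e = URIRef(EX + "C"), BNode("e")
        g.add((c, OWL.equivalentClass, e))
        g.add((e, OWL.complementOf, URIRef(EX + "D")))
        assert ViolationCode.E_COMPLEX_CLASS in {v.code for v in validate_subset(g)}

    def test_functional_property_is_foreign(self):
        g = Graph()
        g.add((URIRef(EX + "p"), RDF.type, OWL.FunctionalProperty))
        assert {v.code for v in validate_subset(g)} == {ViolationCode.E_FOREIGN_CONSTRUCT}

    @pytest.mark.parametrize("seed", range(8))
    def test_forward_outputs_always_validate_clean(self, seed):
        doc = generate_document(FixtureParams(p_logical=0.2, p_obsolete=0.1, seed=seed))
        graph, _ = translate_document(doc)
        assert validate_subset(graph) == []


class TestTranslateGraph:
    def test_printed_fragments_invert_to_canonical_stanzas(self, corpus):
        for example in corpus:
            back = translate_graph(example.graph)
            assert back == canonicalize(example.document), (
                f"example {example.label}:\n{serialize_obo(back)}"
            )

    def test_ontology_only_graph_gives_empty_bodied_document(self):
        g = Graph()
        g.add((URIRef(EX.rstrip("#")), RDF.type, OWL.Ontology))
        doc = translate_graph(g)
        assert doc.stanzas == []

    def test_untranslatable_graph_is_rejected(self):
        with pytest.raises(OboError, match="E_UNTRANSLATABLE"):
            translate_graph(_restriction_graph(OWL.allValuesFrom))

    @pytest.mark.parametrize("seed", range(25))
    def test_roundtrip_restores_canonical_document(self, seed):
        doc = generate_document(
            FixtureParams(
                n_terms=4 + seed,
                n_typedefs=seed % 5,
                p_logical=0.15,
                p_obsolete=0.08,
                p_flat_id=0.15,
                seed=seed,
            )
        )
        report = roundtrip_check(doc, via_text=(seed % 5 == 0))
        assert report.equal, report.diffs[:5]
        assert report.counts_in == report.counts_owl == report.counts_out

    def test_mutated_roundtrip_is_detected(self, small_doc):
        graph, _ = translate_document(small_doc)
        # remove one label: the roundtrip loses that name clause
        victim = next(graph.triples((None, RDFS.label, None)))
        graph.remove(victim)
        back = translate_graph(graph)
        assert back != canonicalize(small_doc)

    def test_unknown_tags_survive_the_roundtrip(self):
        doc = parse_obo(
            "my-header-extension: kept\n\n[Term]\nid: X:1\nfrobnicate: hello\n"
        )
        report = roundtrip_check(doc)
        assert report.equal, report.diffs

    def test_header_metadata_survives_the_roundtrip(self):
        doc = parse_obo(
            "format-version: 1.2\n"
            "date: 07:03:2011 12:00\n"
            "saved-by: curator\n"
            "auto-generated-by: tool 1.0\n"
            "default-namespace: anatomy\n"
            "idspace: GO http://www.go.org/owl#\n"
            'subsetdef: slim "a slim"\n'
            'synonymtypedef: plural "plural form" EXACT\n'
        )
        report = roundtrip_check(doc, via_text=True)
        assert report.equal, report.diffs

    def test_counts_match_on_both_sides(self, small_doc):
        graph, _ = translate_document(small_doc)
        back = translate_graph(graph)
        assert count_entities(back) == count_owl_entities(graph) == count_entities(small_doc)
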