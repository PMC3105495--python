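"""Forward translation: OBO → OWL-DL."""

import pytest
from rdflib import BNode, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from oboowl.fixtures import FixtureParams, generate_document
from oboowl.forward import (
    TranslationOptions,
    translate_document,
    translate_term,
    translate_typedef,
)
from oboowl.graph import OBOINOWL, describe, graphs_isomorphic
from oboowl.ids import iri_to_obo_id, obo_id_to_iri, registry_from_header
from oboowl.io import parse_obo
from oboowl.model import OboError
from oboowl.reverse import validate_subset
from oboowl.roundtrip import count_entities, count_owl_entities


def _entity_subgraph(document):
    """Forward-translate a one-stanza document and cut out its entity."""
    graph, _ = translate_document(document)
    registry = registry_from_header(document)
    entity = URIRef(obo_id_to_iri(registry, document.stanzas[0].id))
    return describe(graph, entity)


def test_printed_fragments_are_reproduced(corpus):
    for example in corpus:
        assert graphs_isomorphic(_entity_subgraph(example.document), example.graph), (
            f"example {example.label} does not match its printed OWL fragment"
        )


class TestHeader:
    def test_subsetdef_becomes_subset_resource(self):
        doc = parse_obo('subsetdef: gross "gross anatomy slim"\n')
        graph, _ = translate_document(doc)
        subsets = list(graph.subjects(RDF.type, OBOINOWL.Subset))
        assert len(subsets) == 1
        assert (subsets[0], RDFS.comment, Literal("gross anatomy slim")) in graph

    def test_two_subsetdefs_are_distinct_resources(self):
        doc = parse_obo('subsetdef: a "one"\nsubsetdef: b "two"\n')
        graph, _ = translate_document(doc)
        assert len(set(graph.subjects(RDF.type, OBOINOWL.Subset))) == 2

    def test_empty_document_yields_single_ontology_node(self):
        graph, _ = translate_document(parse_obo(""))
        ontologies = list(graph.subjects(RDF.type, OWL.Ontology))
        assert len(ontologies) == 1
        # everything else on the node is ancillary roundtrip bookkeeping
        assert set(graph.subjects()) == {ontologies[0]}

    def test_import_becomes_owl_imports(self):
        doc = parse_obo("import: http://example.org/other.owl\n")
        graph, _ = translate_document(doc)
        onto = next(graph.subjects(RDF.type, OWL.Ontology))
        assert (onto, OWL.imports, URIRef("http://example.org/other.owl")) in graph

    def test_metadata_tags_become_ontology_annotations(self):
        doc = parse_obo("format-version: 1.2\ndate: 07:03:2011 12:00\nsaved-by: me\n")
        graph, _ = translate_document(doc)
        onto = next(graph.subjects(RDF.type, OWL.Ontology))
        assert (onto, OBOINOWL.hasFormatVersion, Literal("1.2")) in graph
        assert (onto, OBOINOWL.hasDate, Literal("07:03:2011 12:00")) in graph
        assert (onto, OBOINOWL.savedBy, Literal("me")) in graph


class TestTerm:
    def test_printed_is_a_example(self, corpus):
        doc = next(e for e in corpus if e.label == "B").document
        graph, _ = translate_document(doc)
        base = "http://purl.org/obo/owl/obo#"
        c = URIRef(base + "ZFA_0000434")
        assert (c, RDF.type, OWL.Class) in graph
        assert (c, RDFS.label, Literal("skeletal system")) in graph
        assert (c, RDFS.subClassOf, URIRef(base + "ZFA_0001439")) in graph

    def test_obsolete_term_subclasses_the_obsolete_helper(self, corpus):
        doc = next(e for e in corpus if e.label == "D").document
        graph, _ = translate_document(doc)
        c = URIRef("http://purl.org/obo/owl/obo#ZFA_0000437")
        assert (c, RDFS.subClassOf, OBOINOWL.ObsoleteClass) in graph
        assert (OBOINOWL.ObsoleteClass, RDF.type, OWL.Class) in graph

    def test_bare_term_is_a_single_typed_class(self):
        doc = parse_obo("[Term]\nid: X:1\n")
        graph = translate_term(doc.stanzas[0])
        assert list(graph) == [
            (URIRef("http://purl.org/obo/owl/obo#X_1"), RDF.type, OWL.Class)
        ]

    def test_relationship_becomes_existential_restriction(self, corpus):
        doc = next(e for e in corpus if e.label == "C").document
        graph, _ = translate_document(doc)
        base = "http://purl.org/obo/owl/obo#"
        c = URIRef(base + "ZFA_0001439")
        restrictions = [o for o in graph.objects(c, RDFS.subClassOf) if isinstance(o, BNode)]
        assert len(restrictions) == 1
        r = restrictions[0]
        assert (r, RDF.type, OWL.Restriction) in graph
        assert (r, OWL.onProperty, URIRef(base + "UNDEFINED_part_of")) in graph
        assert (r, OWL.someValuesFrom, URIRef(base + "ZFA_0001094")) in graph

    def test_two_relationships_make_two_distinct_restrictions(self):
        doc = parse_obo(
            "[Term]\nid: X:1\nrelationship: part_of X:2\nrelationship: part_of X:3\n"
        )
        graph = translate_term(doc.stanzas[0])
        # class-type triple + 2 × (subClassOf + 3 restriction triples)
        assert len(graph) == 1 + 2 * 4
        restrictions = set(graph.subjects(RDF.type, OWL.Restriction))
        assert len(restrictions) == 2

    def test_self_relationship_is_not_special_cased(self):
        doc = parse_obo("[Term]\nid: X:1\nrelationship: part_of X:1\n")
        graph = translate_term(doc.stanzas[0])
        x1 = URIRef("http://purl.org/obo/owl/obo#X_1")
        r = next(graph.subjects(RDF.type, OWL.Restriction))
        assert (r, OWL.someValuesFrom, x1) in graph

    def test_obsolete_with_relational_clause_raises_when_unvalidated(self):
        doc = parse_obo("[Term]\nid: X:1\nis_obsolete: true\nis_a: X:2\n")
        with pytest.raises(OboError, match="E_OBSOLETE_REL"):
            translate_term(doc.stanzas[0])

    def test_intersection_of_builds_equivalent_class(self):
        doc = parse_obo(
            "[Term]\nid: X:3\nintersection_of: X:1\nintersection_of: part_of X:2\n"
        )
        graph = translate_term(doc.stanzas[0])
        x3 = URIRef("http://purl.org/obo/owl/obo#X_3")
        expr = next(o for o in graph.objects(x3, OWL.equivalentClass))
        lst = next(graph.objects(expr, OWL.intersectionOf))
        from rdflib.collection import Collection

        items = list(Collection(graph, lst))
        assert items[0] == URIRef("http://purl.org/obo/owl/obo#X_1")
        assert (items[1], OWL.someValuesFrom, URIRef("http://purl.org/obo/owl/obo#X_2")) in graph


class TestTypedef:
    def test_printed_transitive_example(self, corpus):
        doc = next(e for e in corpus if e.label == "A").document
        graph = translate_typedef(doc.stanzas[0])
        p = URIRef("http://purl.org/obo/owl/obo#UNDEFINED_part_of")
        assert (p, RDF.type, OWL.TransitiveProperty) in graph
        assert (p, RDFS.label, Literal("part of")) in graph
        # the transitive type entails object-property-ness; no redundant triple
        assert (p, RDF.type, OWL.ObjectProperty) not in graph

    def test_is_cyclic_false_is_a_boolean_literal(self):
        doc = parse_obo("[Typedef]\nid: r\nis_cyclic: false\n")
        graph = translate_typedef(doc.stanzas[0])
        p = URIRef("http://purl.org/obo/owl/obo#UNDEFINED_r")
        assert (p, OBOINOWL.isCyclic, Literal(False, datatype=XSD.boolean)) in graph

    def test_domain_and_range_map_to_rdfs(self):
        doc = parse_obo("[Typedef]\nid: r\ndomain: X:1\nrange: X:2\n")
        graph = translate_typedef(doc.stanzas[0])
        p = URIRef("http://purl.org/obo/owl/obo#UNDEFINED_r")
        base = "http://purl.org/obo/owl/obo#"
        assert (p, RDFS.domain, URIRef(base + "X_1")) in graph
        assert (p, RDFS.range, URIRef(base + "X_2")) in graph

    def test_obsolete_typedef_subproperty_of_obsolete_helper(self):
        doc = parse_obo("[Typedef]\nid: r\nis_obsolete: true\n")
        graph = translate_typedef(doc.stanzas[0])
        p = URIRef("http://purl.org/obo/owl/obo#UNDEFINED_r")
        assert (p, RDFS.subPropertyOf, OBOINOWL.ObsoleteProperty) in graph


class TestInvariants:
    @pytest.mark.parametrize("seed", range(10))
    def test_count_preservation(self, seed):
        doc = generate_document(FixtureParams(n_terms=5 + 3 * seed, n_typedefs=seed % 5, seed=seed))
        graph, report = translate_document(doc)
        terms, typedefs = count_entities(doc)
        assert (report.n_terms, report.n_typedefs) == (terms, typedefs)
        assert (report.n_classes_emitted, report.n_properties_emitted) == (terms, typedefs)
        assert count_owl_entities(graph) == (terms, typedefs)

    @pytest.mark.parametrize("seed", range(10))
    def test_output_stays_in_the_obo_expressible_subset(self, seed):
        doc = generate_document(FixtureParams(p_logical=0.3, p_obsolete=0.1, seed=seed))
        graph, _ = translate_document(doc)
        assert validate_subset(graph) == []

    def test_every_entity_iri_resolves_back_to_its_id(self, small_doc):
        graph, _ = translate_document(small_doc)
        registry = registry_from_header(small_doc)
        ids = {s.id.render() for s in small_doc.stanzas}
        for t in (OWL.Class, OWL.ObjectProperty, OWL.TransitiveProperty, OWL.SymmetricProperty):
            for s in graph.subjects(RDF.type, t):
                if isinstance(s, URIRef) and not OBOINOWL.is_meta(s):
                    assert iri_to_obo_id(registry, str(s)).render() in ids

    def test_strict_mode_rejects_unknown_tags(self):
        doc = parse_obo("[Term]\nid: X:1\nfrobnicate: hello\n")
        with pytest.raises(OboError, match="E_UNKNOWN_TAG"):
            translate_document(doc, opts=TranslationOptions(strict=True))

    def test_unknown_tags_preserved_and_reported(self):
        doc = parse_obo("[Term]\nid: X:1\nfrobnicate: hello\n")
        graph, report = translate_document(doc)
        assert report.unknown_tags_preserved == ["frobnicate"]
        x1 = URIRef("http://purl.org/obo/owl/obo#X_1")
        assert (x1, OBOINOWL.term("frobnicate"), Literal("hello")) in graph
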