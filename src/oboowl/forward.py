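"""Forward translation: OBO document → OWL-DL triple graph.

The mapping follows the community "common mapping":

* ``[Term]`` → ``owl:Class``; ``[Typedef]`` → an object property
  (``owl:TransitiveProperty`` / ``owl:SymmetricProperty`` when the
  corresponding boolean tags are true, plain ``owl:ObjectProperty``
  otherwise — those OWL property types entail object-property-ness, so a
  separate ``owl:ObjectProperty`` triple would be redundant);
* ``name``/``comment`` → ``rdfs:label``/``rdfs:comment``; ``is_a`` →
  ``rdfs:subClassOf`` (terms) or ``rdfs:subPropertyOf`` (typedefs);
* ``relationship: R T`` → an anonymous existential restriction
  ``rdfs:subClassOf [owl:Restriction; owl:onProperty R;
  owl:someValuesFrom T]`` — existential semantics only;
* ``is_obsolete: true`` → subclass of ``oboInOwl:ObsoleteClass`` /
  subproperty of ``oboInOwl:ObsoleteProperty`` (deliberately *not* OWL
  deprecation, whose semantics differ);
* definitions and synonyms are reified as anonymous annotation nodes so
  their cross-references and synonym types survive the roundtrip;
* subsets become ``oboInOwl:Subset``-typed resources plus ``inSubset``
  annotations;
* ``intersection_of``/``union_of`` become equivalent-class axioms over
  anonymous ``owl:intersectionOf``/``owl:unionOf`` class expressions;
* unknown tags are preserved as oboInOwl annotation properties named after
  the tag (errors in strict mode), keeping the translation lossless.

Ancillary information (the base IRI and the idspace declarations) is
recorded on the ontology node so the reverse direction is self-contained.
The output stays inside OWL-DL: no ``owl:allValuesFrom``, no datatype
properties, no punning, no OWL deprecation vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from rdflib import BNode, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from . import io as obo_io
from .graph import OBOINOWL_NAMESPACE, OboInOwl, TripleGraph, new_graph
from .ids import IdSpaceRegistry, obo_id_to_iri, registry_from_header
from .model import (
    DefClause,
    HeaderClause,
    IdSpaceDecl,
    ImportRef,
    LogicalClause,
    OboError,
    OBODocument,
    RelationshipClause,
    RELATIONAL_TAGS,
    Stanza,
    StanzaKind,
    SubsetDef,
    SynonymClause,
    SynonymScope,
    SynonymTypeDef,
    TagValue,
)

__all__ = [
    "TranslationOptions",
    "TranslationReport",
    "translate_document",
    "translate_header",
    "translate_term",
    "translate_typedef",
    "translate_relationship",
    "SCOPE_TO_SYNONYM_PROPERTY",
]

#: synonym scope → oboInOwl annotation property local name
SCOPE_TO_SYNONYM_PROPERTY = {
    SynonymScope.EXACT: "hasExactSynonym",
    SynonymScope.BROAD: "hasBroadSynonym",
    SynonymScope.NARROW: "hasNarrowSynonym",
    SynonymScope.RELATED: "hasRelatedSynonym",
    SynonymScope.UNSPECIFIED: "hasSynonym",
}

_HEADER_ANNOTATIONS = {
    "format-version": "hasFormatVersion",
    "version": "hasVersion",
    "date": "hasDate",
    "saved-by": "savedBy",
    "auto-generated-by": "autoGeneratedBy",
    "default-namespace": "hasDefaultNamespace",
    "namespace": "hasOBONamespace",
}


@dataclass
class TranslationOptions:
    base_iri: Optional[str] = None  # None: derive from the registry
    strict: bool = False
    keep_unknown_tags: bool = True
    oboinowl_namespace: str = OBOINOWL_NAMESPACE


@dataclass
class TranslationReport:
    n_terms: int = 0
    n_typedefs: int = 0
    n_classes_emitted: int = 0
    n_properties_emitted: int = 0
    warnings: list[str] = field(default_factory=list)
    unknown_tags_preserved: list[str] = field(default_factory=list)


class _Translator:
    def __init__(self, registry: IdSpaceRegistry, opts: TranslationOptions):
        self.opts = opts
        if opts.base_iri:
            registry = replace(registry, default_base_iri=opts.base_iri)
        self.registry = registry
        self.base_iri = registry.default_base_iri
        self.oio = OboInOwl(opts.oboinowl_namespace)
        self.graph: TripleGraph = new_graph(self.base_iri, self.oio)
        self.report = TranslationReport()
        self._bnodes = 0
        self._declared_obsolete_class = False
        self._declared_obsolete_property = False
        self.ontology_node = URIRef(self.base_iri.rstrip("#/"))

    # -- small helpers ----------------------------------------------------

    def bnode(self) -> BNode:
        self._bnodes += 1
        return BNode(f"n{self._bnodes}")

    def iri(self, oid) -> URIRef:
        return URIRef(obo_id_to_iri(self.registry, oid))

    def resource(self, name: str) -> URIRef:
        """Document-local resource (subset / synonym-type name)."""
        return URIRef(self.base_iri + name)

    def problem(self, code: str, message: str):
        if self.opts.strict:
            raise OboError(code, message)
        self.report.warnings.append(f"{code}: {message}")

    def rdf_list(self, items) -> BNode:
        head = cur = self.bnode()
        items = list(items)
        for i, item in enumerate(items):
            self.graph.add((cur, RDF.first, item))
            if i == len(items) - 1:
                self.graph.add((cur, RDF.rest, RDF.nil))
            else:
                nxt = self.bnode()
                self.graph.add((cur, RDF.rest, nxt))
                cur = nxt
        return head

    def passthrough(self, subject: URIRef, clause: TagValue, unknown: bool = False):
        """Preserve a clause as an annotation-property triple whose literal
        is the clause's escaped OBO value text (lossless)."""
        if unknown:
            if not self.opts.keep_unknown_tags:
                self.problem("W_UNKNOWN_TAG", f"dropping unknown tag {clause.tag!r}")
                return
            if self.opts.strict:
                raise OboError("E_UNKNOWN_TAG", f"unknown tag {clause.tag!r}")
            self.report.unknown_tags_preserved.append(clause.tag)
        payload = obo_io.serialize_clause_value(clause.tag, clause.value)
        self.graph.add((subject, self.oio.term(clause.tag), Literal(payload)))

    def check_dropped_extras(self, clause: TagValue, where: str):
        if clause.qualifiers:
            self.problem(
                "W_QUALIFIERS_DROPPED",
                f"trailing modifiers on {clause.tag!r} in {where} are not carried to OWL",
            )
        if clause.inline_comment is not None:
            self.problem(
                "W_COMMENT_DROPPED",
                f"inline comment on {clause.tag!r} in {where} is not carried to OWL",
            )

    # -- annotation payloads ----------------------------------------------

    def add_reified(self, subject, prop: URIRef, text: str, xrefs, type_name=None):
        node = self.bnode()
        self.graph.add((subject, prop, node))
        self.graph.add((node, RDFS.label, Literal(text)))
        if type_name:
            self.graph.add((node, self.oio.hasSynonymType, self.resource(type_name)))
        for x in xrefs:
            self.graph.add((node, self.oio.hasDbXref, Literal(obo_io.serialize_xref(x))))

    def obsolete_class_marker(self) -> URIRef:
        if not self._declared_obsolete_class:
            self.graph.add((self.oio.ObsoleteClass, RDF.type, OWL.Class))
            self._declared_obsolete_class = True
        return self.oio.ObsoleteClass

    def obsolete_property_marker(self) -> URIRef:
        if not self._declared_obsolete_property:
            self.graph.add((self.oio.ObsoleteProperty, RDF.type, OWL.ObjectProperty))
            self._declared_obsolete_property = True
        return self.oio.ObsoleteProperty

    # -- header ------------------------------------------------------------

    def translate_header(self, header: list[HeaderClause]):
        g = self.graph
        onto = self.ontology_node
        g.add((onto, RDF.type, OWL.Ontology))
        g.add((onto, self.oio.hasBaseIRI, Literal(self.base_iri)))
        for clause in header:
            tag, parsed = clause.tag, clause.parsed
            if tag in _HEADER_ANNOTATIONS:
                g.add((onto, getattr(self.oio, _HEADER_ANNOTATIONS[tag]), Literal(clause.value)))
            elif isinstance(parsed, IdSpaceDecl):
                g.add((onto, self.oio.hasIdSpace, Literal(obo_io.serialize_header_value(clause))))
            elif isinstance(parsed, ImportRef):
                g.add((onto, OWL.imports, URIRef(parsed.target)))
            elif isinstance(parsed, SubsetDef):
                node = self.resource(parsed.name)
                g.add((node, RDF.type, self.oio.Subset))
                g.add((node, RDFS.comment, Literal(parsed.description)))
            elif isinstance(parsed, SynonymTypeDef):
                node = self.resource(parsed.name)
                g.add((node, RDF.type, self.oio.SynonymType))
                g.add((node, RDFS.comment, Literal(parsed.description)))
                if parsed.default_scope is not None:
                    g.add((node, self.oio.hasScope, Literal(parsed.default_scope.name)))
            elif tag == obo_io.COMMENT_TAG:
                self.problem("W_COMMENT_DROPPED", "header comment line is not carried to OWL")
            else:
                self.passthrough(onto, TagValue(tag, clause.value), unknown=True)

    # -- stanzas -----------------------------------------------------------

    def _shared_clause(self, subject: URIRef, clause: TagValue, stanza: Stanza) -> bool:
        """Clauses handled identically for terms and typedefs."""
        g, oio = self.graph, self.oio
        tag, value = clause.tag, clause.value
        if tag == "name":
            g.add((subject, RDFS.label, Literal(value)))
        elif tag == "comment":
            g.add((subject, RDFS.comment, Literal(value)))
        elif tag == "def" and isinstance(value, DefClause):
            self.add_reified(subject, oio.hasDefinition, value.text, value.xrefs)
        elif tag == "synonym" and isinstance(value, SynonymClause):
            prop = getattr(oio, SCOPE_TO_SYNONYM_PROPERTY[value.scope])
            self.add_reified(subject, prop, value.text, value.xrefs, value.type_name)
        elif tag == "subset":
            g.add((subject, oio.inSubset, self.resource(str(value))))
        elif tag == "alt_id":
            g.add((subject, oio.hasAlternativeId,
                   Literal(obo_io.serialize_clause_value(tag, value))))
        elif tag == "namespace":
            g.add((subject, oio.hasOBONamespace, Literal(value)))
        elif tag == "replaced_by":
            g.add((subject, oio.replacedBy, self.iri(value)))
        elif tag == "consider":
            g.add((subject, oio.consider, self.iri(value)))
        else:
            return False
        return True

    def _guard_obsolete(self, stanza: Stanza):
        if stanza.is_obsolete:
            bad = sorted({c.tag for c in stanza.clauses if c.tag in RELATIONAL_TAGS})
            if bad:
                raise OboError(
                    "E_OBSOLETE_REL",
                    f"obsolete stanza {stanza.id.render()} carries relational clauses {bad}",
                )

    def translate_term(self, stanza: Stanza):
        self._guard_obsolete(stanza)
        g, oio = self.graph, self.oio
        subject = self.iri(stanza.id)
        g.add((subject, RDF.type, OWL.Class))
        intersections: list[LogicalClause] = []
        unions: list[LogicalClause] = []
        where = f"[Term] {stanza.id.render()}"
        for clause in stanza.clauses:
            self.check_dropped_extras(clause, where)
            tag, value = clause.tag, clause.value
            if self._shared_clause(subject, clause, stanza):
                continue
            if tag == "is_a":
                g.add((subject, RDFS.subClassOf, self.iri(value)))
            elif tag == "relationship" and isinstance(value, RelationshipClause):
                self.add_relationship(subject, value)
            elif tag == "is_obsolete":
                if value is True:
                    g.add((subject, RDFS.subClassOf, self.obsolete_class_marker()))
                else:
                    self.passthrough(subject, clause)
            elif tag == "intersection_of" and isinstance(value, LogicalClause):
                intersections.append(value)
            elif tag == "union_of" and isinstance(value, LogicalClause):
                unions.append(value)
            elif tag == "disjoint_from" and isinstance(value, LogicalClause):
                g.add((subject, OWL.disjointWith, self.iri(value.operand_class)))
            elif tag == obo_io.COMMENT_TAG:
                self.problem("W_COMMENT_DROPPED", f"comment line in {where} not carried to OWL")
            else:
                self.passthrough(subject, clause, unknown=True)
        self._emit_logical(subject, intersections, unions, where)
        return subject

    def _emit_logical(self, subject, intersections, unions, where):
        g = self.graph
        if len(intersections) == 1:
            self.problem(
                "W_DEGENERATE_LOGICAL",
                f"single intersection_of operand in {where}; preserved as annotation",
            )
            self.passthrough(subject, TagValue("intersection_of", intersections[0]))
        elif intersections:
            items = []
            for lc in intersections:
                if lc.operand_relation is None:
                    items.append(self.iri(lc.operand_class))
                else:
                    items.append(
                        self._restriction(lc.operand_relation, lc.operand_class)
                    )
            expr = self.bnode()
            g.add((subject, OWL.equivalentClass, expr))
            g.add((expr, RDF.type, OWL.Class))
            g.add((expr, OWL.intersectionOf, self.rdf_list(items)))
        if len(unions) == 1:
            self.problem(
                "W_DEGENERATE_LOGICAL",
                f"single union_of operand in {where}; preserved as annotation",
            )
            self.passthrough(subject, TagValue("union_of", unions[0]))
        elif unions:
            expr = self.bnode()
            g.add((subject, OWL.equivalentClass, expr))
            g.add((expr, RDF.type, OWL.Class))
            g.add((expr, OWL.unionOf, self.rdf_list([self.iri(u.operand_class) for u in unions])))

    def _restriction(self, type_id, target_id) -> BNode:
        node = self.bnode()
        self.graph.add((node, RDF.type, OWL.Restriction))
        self.graph.add((node, OWL.onProperty, self.iri(type_id)))
        self.graph.add((node, OWL.someValuesFrom, self.iri(target_id)))
        return node

    def add_relationship(self, subject: URIRef, rel: RelationshipClause):
        """Existential-restriction encoding of one relationship clause."""
        self.graph.add((subject, RDFS.subClassOf, self._restriction(rel.type_id, rel.target_id)))

    def translate_typedef(self, stanza: Stanza):
        self._guard_obsolete(stanza)
        g, oio = self.graph, self.oio
        subject = self.iri(stanza.id)
        types = []
        if stanza.boolean("is_transitive"):
            types.append(OWL.TransitiveProperty)
        if stanza.boolean("is_symmetric"):
            types.append(OWL.SymmetricProperty)
        if not types:
            types.append(OWL.ObjectProperty)
        for t in types:
            g.add((subject, RDF.type, t))
        where = f"[Typedef] {stanza.id.render()}"
        for clause in stanza.clauses:
            self.check_dropped_extras(clause, where)
            tag, value = clause.tag, clause.value
            if self._shared_clause(subject, clause, stanza):
                continue
            if tag == "is_a":
                g.add((subject, RDFS.subPropertyOf, self.iri(value)))
            elif tag == "domain":
                g.add((subject, RDFS.domain, self.iri(value)))
            elif tag == "range":
                g.add((subject, RDFS.range, self.iri(value)))
            elif tag == "inverse_of":
                g.add((subject, OWL.inverseOf, self.iri(value)))
            elif tag == "transitive_over":
                g.add((subject, oio.transitiveOver, self.iri(value)))
            elif tag == "is_cyclic":
                if isinstance(value, bool):
                    g.add((subject, oio.isCyclic, Literal(value, datatype=XSD.boolean)))
                else:
                    self.passthrough(subject, clause)
            elif tag in ("is_transitive", "is_symmetric"):
                if value is not True:
                    # false is indistinguishable from absence in OWL; preserve
                    self.passthrough(subject, clause)
            elif tag == "is_obsolete":
                if value is True:
                    g.add((subject, RDFS.subPropertyOf, self.obsolete_property_marker()))
                else:
                    self.passthrough(subject, clause)
            elif tag == obo_io.COMMENT_TAG:
                self.problem("W_COMMENT_DROPPED", f"comment line in {where} not carried to OWL")
            else:
                self.passthrough(subject, clause, unknown=True)
        return subject


# --------------------------------------------------------------------------
# public operations


def translate_document(
    doc: OBODocument,
    registry: Optional[IdSpaceRegistry] = None,
    opts: Optional[TranslationOptions] = None,
) -> tuple[TripleGraph, TranslationReport]:
    """Translate a validated OBO document to an OWL-DL triple graph.

    Returns the graph together with a :class:`TranslationReport` whose
    emitted-entity counts equal the stanza counts (the count-preservation
    protocol used to evaluate the roundtrip).
    """
    opts = opts or TranslationOptions()
    registry = registry or registry_from_header(doc, opts.base_iri)
    tr = _Translator(registry, opts)
    tr.translate_header(doc.header)
    classes, properties = set(), set()
    for stanza in doc.stanzas:
        try:
            if stanza.kind is StanzaKind.TERM:
                tr.report.n_terms += 1
                classes.add(tr.translate_term(stanza))
            else:
                tr.report.n_typedefs += 1
                properties.add(tr.translate_typedef(stanza))
        except OboError as exc:
            raise OboError(exc.code, f"in stanza {stanza.id.render()}: {exc.args[0]}") from exc
    tr.report.n_classes_emitted = len(classes)
    tr.report.n_properties_emitted = len(properties)
    return tr.graph, tr.report


def _fragment(registry, opts, emit) -> TripleGraph:
    tr = _Translator(registry or IdSpaceRegistry(), opts or TranslationOptions())
    emit(tr)
    return tr.graph


def translate_header(header, registry=None, opts=None) -> TripleGraph:
    """Triples for the header alone (ontology node, subsets, synonym types)."""
    return _fragment(registry, opts, lambda tr: tr.translate_header(header))


def translate_term(stanza: Stanza, registry=None, opts=None) -> TripleGraph:
    """Triples for a single ``[Term]`` stanza."""
    return _fragment(registry, opts, lambda tr: tr.translate_term(stanza))


def translate_typedef(stanza: Stanza, registry=None, opts=None) -> TripleGraph:
    """Triples for a single ``[Typedef]`` stanza."""
    return _fragment(registry, opts, lambda tr: tr.translate_typedef(stanza))


def translate_relationship(subject_iri: str, rel: RelationshipClause, registry=None) -> TripleGraph:
    """The three-triple existential restriction for one relationship clause."""
    return _fragment(
        registry, None, lambda tr: tr.add_relationship(URIRef(subject_iri), rel)
    )
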