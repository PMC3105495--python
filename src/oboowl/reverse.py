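"""Reverse translation: OWL triple graph → OBO document, plus the
OBO-expressibility validator.

OBO is a strict subset of OWL-DL, so an OWL document edited by general OWL
tooling may leave the translatable subset.  :func:`validate_subset` checks
a graph against that subset and returns coded violations; an empty list
guarantees :func:`translate_graph` succeeds, which lets the translator
serve double duty as a validator for ontologies updated in OWL.

Rejected constructs:

* ``owl:allValuesFrom`` restrictions — OBO relationships carry existential
  (``someValuesFrom``) semantics only;
* OWL deprecation vocabulary — OBO obsolescence is encoded via the
  ``oboInOwl:ObsoleteClass``/``ObsoleteProperty`` helpers, whose semantics
  differ from ``owl:DeprecatedClass``/``owl:DeprecatedProperty``;
* datatype properties, punning (one node used as both class and property,
  or as an individual) and class expressions beyond named classes,
  existential restrictions and intersections/unions of those.

The rebuilt document is returned in canonical form: clause and stanza
order is presentation, not knowledge, under the roundtrip equality.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from rdflib import BNode, Literal, URIRef
from rdflib.collection import Collection
from rdflib.namespace import OWL, RDF, RDFS

from . import io as obo_io
from .graph import OBOINOWL, OboInOwl, TripleGraph
from .ids import FALLBACK_BASE_IRI, IdSpaceRegistry, iri_to_obo_id
from .model import (
    DbXref,
    DefClause,
    HeaderClause,
    LogicalClause,
    LogicalKind,
    OboError,
    OBODocument,
    RelationshipClause,
    Stanza,
    StanzaKind,
    SubsetDef,
    SynonymClause,
    SynonymScope,
    SynonymTypeDef,
    TagValue,
    canonicalize,
)

__all__ = ["ViolationCode", "SubsetViolation", "validate_subset", "translate_graph"]


class ViolationCode(enum.Enum):
    E_ALLVALUES = "E_ALLVALUES"
    E_DEPRECATION = "E_DEPRECATION"
    E_DATATYPE_PROP = "E_DATATYPE_PROP"
    E_COMPLEX_CLASS = "E_COMPLEX_CLASS"
    E_PUNNING = "E_PUNNING"
    E_FOREIGN_CONSTRUCT = "E_FOREIGN_CONSTRUCT"


_REMEDIATION = {
    ViolationCode.E_ALLVALUES: "use owl:someValuesFrom; OBO relationships are existential",
    ViolationCode.E_DEPRECATION: "use oboInOwl:ObsoleteClass/ObsoleteProperty for obsolescence",
    ViolationCode.E_DATATYPE_PROP: "OBO typedefs map to object properties only",
    ViolationCode.E_COMPLEX_CLASS: "only named classes, existential restrictions and "
    "intersections/unions of those are OBO-expressible",
    ViolationCode.E_PUNNING: "a node must be exactly one of class, property or helper resource",
    ViolationCode.E_FOREIGN_CONSTRUCT: "construct has no OBO equivalent",
}


@dataclass(frozen=True)
class SubsetViolation:
    code: ViolationCode
    node: object
    message: str

    @property
    def remediation(self) -> str:
        return _REMEDIATION[self.code]


_PROPERTY_TYPES = (OWL.ObjectProperty, OWL.TransitiveProperty, OWL.SymmetricProperty)
_ALLOWED_TYPE_OBJECTS = frozenset(
    (OWL.Class, OWL.Ontology, OWL.Restriction, OWL.AnnotationProperty) + _PROPERTY_TYPES
)
_FOREIGN_OWL_TYPES = frozenset(
    {OWL.FunctionalProperty, OWL.InverseFunctionalProperty, OWL.NamedIndividual}
)


def validate_subset(graph: TripleGraph, oio: OboInOwl = OBOINOWL) -> list[SubsetViolation]:
    """Check that *graph* lies within the OBO-expressible subset of OWL-DL.

    Returns every violation found (empty list ⇒ translatable); never raises.
    """
    violations: list[SubsetViolation] = []

    def flag(code, node, message):
        violations.append(SubsetViolation(code, node, message))

    for s, _, _ in graph.triples((None, OWL.allValuesFrom, None)):
        flag(ViolationCode.E_ALLVALUES, s, "owl:allValuesFrom restriction")

    deprecation_nodes = {OWL.DeprecatedClass, OWL.DeprecatedProperty}
    for s, p, o in graph:
        if o in deprecation_nodes or s in deprecation_nodes:
            flag(ViolationCode.E_DEPRECATION, s, f"OWL deprecation construct in ({s}, {p}, {o})")
        elif p == OWL.deprecated:
            flag(ViolationCode.E_DEPRECATION, s, "owl:deprecated annotation")

    for s in graph.subjects(RDF.type, OWL.DatatypeProperty):
        flag(ViolationCode.E_DATATYPE_PROP, s, f"datatype property declaration on {s}")

    # punning / individuals
    for s in set(graph.subjects(RDF.type, None)):
        types = set(graph.objects(s, RDF.type))
        is_class = OWL.Class in types
        is_property = any(t in types for t in _PROPERTY_TYPES)
        if isinstance(s, URIRef) and is_class and is_property:
            flag(ViolationCode.E_PUNNING, s, f"{s} is typed both class and object property")
        for t in types:
            if isinstance(t, URIRef):
                if t in deprecation_nodes or t == OWL.DatatypeProperty:
                    continue  # already flagged under their own codes
                if t in _FOREIGN_OWL_TYPES:
                    flag(ViolationCode.E_FOREIGN_CONSTRUCT, s, f"unsupported type {t} on {s}")
                elif (
                    t not in _ALLOWED_TYPE_OBJECTS
                    and not oio.is_meta(t)
                    and str(t).startswith(str(OWL))
                ):
                    flag(ViolationCode.E_FOREIGN_CONSTRUCT, s, f"unsupported type {t} on {s}")
                elif t not in _ALLOWED_TYPE_OBJECTS and not oio.is_meta(t) and not str(
                    t
                ).startswith(str(OWL)):
                    # rdf:type to an ordinary named class: an individual assertion
                    flag(
                        ViolationCode.E_PUNNING,
                        s,
                        f"{s} is used as an individual of {t}",
                    )

    # class-expression shapes, checked by position so that a clean graph is
    # guaranteed to translate
    allowed_restriction = {RDF.type, OWL.onProperty, OWL.someValuesFrom}
    allowed_combination = {RDF.type, OWL.intersectionOf, OWL.unionOf}

    def check_restriction(node) -> bool:
        preds = set(graph.predicates(node, None))
        types = set(graph.objects(node, RDF.type))
        if OWL.Restriction not in types:
            flag(ViolationCode.E_COMPLEX_CLASS, node, "anonymous superclass is not a restriction")
            return False
        extra = preds - allowed_restriction
        extra.discard(OWL.allValuesFrom)  # already flagged specifically
        if extra:
            flag(
                ViolationCode.E_COMPLEX_CLASS,
                node,
                f"restriction uses unsupported facets {sorted(map(str, extra))}",
            )
            return False
        on_prop = list(graph.objects(node, OWL.onProperty))
        filler = list(graph.objects(node, OWL.someValuesFrom))
        if len(on_prop) != 1 or not isinstance(on_prop[0], URIRef):
            flag(ViolationCode.E_COMPLEX_CLASS, node, "restriction needs one named onProperty")
            return False
        if OWL.allValuesFrom not in preds and (
            len(filler) != 1 or not isinstance(filler[0], URIRef)
        ):
            flag(ViolationCode.E_COMPLEX_CLASS, node, "restriction needs one named filler class")
            return False
        return True

    for s, _, o in graph.triples((None, RDFS.subClassOf, None)):
        if isinstance(s, BNode):
            flag(ViolationCode.E_COMPLEX_CLASS, s, "anonymous subclass axiom")
        if isinstance(o, BNode):
            check_restriction(o)
    for s, _, o in graph.triples((None, OWL.equivalentClass, None)):
        if isinstance(s, BNode):
            flag(ViolationCode.E_COMPLEX_CLASS, s, "anonymous equivalent-class subject")
        if not isinstance(o, BNode):
            flag(
                ViolationCode.E_COMPLEX_CLASS,
                s,
                "equivalence to a named class has no OBO form",
            )
            continue
        preds = set(graph.predicates(o, None))
        if not (preds <= allowed_combination) or not (
            OWL.intersectionOf in preds or OWL.unionOf in preds
        ):
            flag(
                ViolationCode.E_COMPLEX_CLASS,
                o,
                f"anonymous class expression with predicates {sorted(map(str, preds))}",
            )
            continue
        for combinator in (OWL.intersectionOf, OWL.unionOf):
            for lst in graph.objects(o, combinator):
                for item in Collection(graph, lst):
                    if isinstance(item, BNode):
                        check_restriction(item)
    for s, _, o in graph.triples((None, OWL.disjointWith, None)):
        if isinstance(s, BNode) or isinstance(o, BNode):
            flag(ViolationCode.E_COMPLEX_CLASS, s, "disjointness must relate named classes")
    return violations


# --------------------------------------------------------------------------
# reverse translation

_HEADER_FROM_ANNOTATION = {
    "hasFormatVersion": "format-version",
    "hasVersion": "version",
    "hasDate": "date",
    "savedBy": "saved-by",
    "autoGeneratedBy": "auto-generated-by",
    "hasDefaultNamespace": "default-namespace",
    "hasOBONamespace": "namespace",
}

_SYNONYM_SCOPE_FROM_PROPERTY = {
    "hasExactSynonym": SynonymScope.EXACT,
    "hasBroadSynonym": SynonymScope.BROAD,
    "hasNarrowSynonym": SynonymScope.NARROW,
    "hasRelatedSynonym": SynonymScope.RELATED,
    "hasSynonym": SynonymScope.UNSPECIFIED,
}


class _Reverser:
    def __init__(self, graph: TripleGraph, registry: Optional[IdSpaceRegistry], oio: OboInOwl):
        self.graph = graph
        self.oio = oio
        self.registry = self._build_registry(registry)

    def _build_registry(self, provided: Optional[IdSpaceRegistry]) -> IdSpaceRegistry:
        """Embedded registry annotations win; then the caller's registry;
        then the fixed default base with first-underscore splitting."""
        g, oio = self.graph, self.oio
        base = None
        mappings: dict[str, str] = {}
        for onto in sorted(g.subjects(RDF.type, OWL.Ontology)):
            for lit in g.objects(onto, oio.hasBaseIRI):
                base = str(lit)
            for lit in g.objects(onto, oio.hasIdSpace):
                _, decl = obo_io.parse_header_value("idspace", str(lit))
                mappings[decl.prefix] = decl.base_iri
        if base is None and not mappings and provided is not None:
            return provided
        if base is None:
            base = provided.default_base_iri if provided else FALLBACK_BASE_IRI
        return IdSpaceRegistry(mappings=mappings, default_base_iri=base)

    # -- helpers -----------------------------------------------------------

    def obo_id(self, iri: URIRef):
        return iri_to_obo_id(self.registry, str(iri))

    def local_resource_name(self, iri: URIRef) -> str:
        """Name of a document-local resource (subset / synonym type)."""
        s = str(iri)
        bases = [self.registry.default_base_iri, *self.registry.effective_mappings().values()]
        for base in sorted(set(bases), key=len, reverse=True):
            if s.startswith(base):
                return s[len(base) :]
        if "#" in s:
            return s.rsplit("#", 1)[1]
        return s.rsplit("/", 1)[-1]

    def predicate_tag(self, predicate: URIRef) -> str:
        local = self.oio.local_name(predicate)
        if local is not None:
            return local
        s = str(predicate)
        if "#" in s:
            return s.rsplit("#", 1)[1]
        return s.rsplit("/", 1)[-1]

    def xrefs_of(self, node) -> tuple[DbXref, ...]:
        xs = [obo_io.parse_xref(str(lit)) for lit in self.graph.objects(node, self.oio.hasDbXref)]
        return tuple(sorted(xs, key=lambda x: (x.id, x.description or "")))

    def label_of(self, node) -> str:
        for lit in self.graph.objects(node, RDFS.label):
            return str(lit)
        return ""

    # -- header ------------------------------------------------------------

    def rebuild_header(self) -> list[HeaderClause]:
        g, oio = self.graph, self.oio
        header: list[HeaderClause] = []
        consumed = {RDF.type, oio.hasBaseIRI, oio.hasIdSpace}
        for onto in sorted(g.subjects(RDF.type, OWL.Ontology)):
            for lit in g.objects(onto, oio.hasIdSpace):
                value, parsed = obo_io.parse_header_value("idspace", str(lit))
                header.append(HeaderClause("idspace", value, parsed))
            for p, o in g.predicate_objects(onto):
                if p in consumed:
                    continue
                local = oio.local_name(p)
                if local in _HEADER_FROM_ANNOTATION:
                    header.append(HeaderClause(_HEADER_FROM_ANNOTATION[local], str(o)))
                elif p == OWL.imports:
                    value, parsed = obo_io.parse_header_value("import", str(o))
                    header.append(HeaderClause("import", value, parsed))
                else:
                    tag = self.predicate_tag(p)
                    value, parsed = obo_io.parse_header_value(tag, str(o))
                    header.append(HeaderClause(tag, value, parsed))
        for node in sorted(g.subjects(RDF.type, oio.Subset)):
            sd = SubsetDef(
                name=self.local_resource_name(node),
                description=str(next(g.objects(node, RDFS.comment), Literal(""))),
            )
            header.append(
                HeaderClause("subsetdef", obo_io.render_header_value("subsetdef", sd), sd)
            )
        for node in sorted(g.subjects(RDF.type, oio.SynonymType)):
            scope = None
            for lit in g.objects(node, oio.hasScope):
                scope = SynonymScope[str(lit)]
            st = SynonymTypeDef(
                name=self.local_resource_name(node),
                description=str(next(g.objects(node, RDFS.comment), Literal(""))),
                default_scope=scope,
            )
            header.append(
                HeaderClause(
                    "synonymtypedef", obo_io.render_header_value("synonymtypedef", st), st
                )
            )
        return header

    # -- entities ----------------------------------------------------------

    def entity_subjects(self) -> tuple[list[URIRef], list[URIRef]]:
        g, oio = self.graph, self.oio
        classes = sorted(
            s
            for s in set(g.subjects(RDF.type, OWL.Class))
            if isinstance(s, URIRef) and not oio.is_meta(s)
        )
        props: set = set()
        for t in _PROPERTY_TYPES:
            props.update(
                s
                for s in g.subjects(RDF.type, t)
                if isinstance(s, URIRef) and not oio.is_meta(s)
            )
        return classes, sorted(props)

    def _synonym_clause(self, node, scope: SynonymScope) -> TagValue:
        type_name = None
        for t in self.graph.objects(node, self.oio.hasSynonymType):
            type_name = self.local_resource_name(t)
        return TagValue(
            "synonym",
            SynonymClause(
                text=self.label_of(node),
                scope=scope,
                type_name=type_name,
                xrefs=self.xrefs_of(node),
            ),
        )

    def _restriction_clause(self, node) -> TagValue:
        on_prop = next(self.graph.objects(node, OWL.onProperty))
        target = next(self.graph.objects(node, OWL.someValuesFrom))
        return TagValue(
            "relationship",
            RelationshipClause(type_id=self.obo_id(on_prop), target_id=self.obo_id(target)),
        )

    def _logical_clauses(self, expr) -> list[TagValue]:
        g = self.graph
        clauses: list[TagValue] = []
        for lst in g.objects(expr, OWL.intersectionOf):
            for item in Collection(g, lst):
                if isinstance(item, URIRef):
                    clauses.append(
                        TagValue(
                            "intersection_of",
                            LogicalClause(LogicalKind.INTERSECTION_OF, self.obo_id(item)),
                        )
                    )
                else:
                    on_prop = next(g.objects(item, OWL.onProperty))
                    target = next(g.objects(item, OWL.someValuesFrom))
                    clauses.append(
                        TagValue(
                            "intersection_of",
                            LogicalClause(
                                LogicalKind.INTERSECTION_OF,
                                operand_class=self.obo_id(target),
                                operand_relation=self.obo_id(on_prop),
                            ),
                        )
                    )
        for lst in g.objects(expr, OWL.unionOf):
            for item in Collection(g, lst):
                clauses.append(
                    TagValue("union_of", LogicalClause(LogicalKind.UNION_OF, self.obo_id(item)))
                )
        return clauses

    def _unknown_clause(self, predicate: URIRef, obj) -> TagValue:
        tag = self.predicate_tag(predicate)
        raw = str(obj)
        try:
            value = obo_io.parse_clause_value(tag, raw)
        except OboError:
            # foreign annotation whose literal is not OBO-escaped text
            value = raw
        return TagValue(tag, value)

    def rebuild_term(self, subject: URIRef) -> Stanza:
        g, oio = self.graph, self.oio
        stanza = Stanza(StanzaKind.TERM, self.obo_id(subject))
        add = stanza.clauses.append
        for p, o in g.predicate_objects(subject):
            if p == RDF.type:
                continue
            if p == RDFS.label:
                add(TagValue("name", str(o)))
            elif p == RDFS.comment:
                add(TagValue("comment", str(o)))
            elif p == RDFS.subClassOf:
                if o == oio.ObsoleteClass:
                    add(TagValue("is_obsolete", True))
                elif isinstance(o, BNode):
                    add(self._restriction_clause(o))
                else:
                    add(TagValue("is_a", self.obo_id(o)))
            elif p == OWL.equivalentClass and isinstance(o, BNode):
                stanza.clauses.extend(self._logical_clauses(o))
            elif p == OWL.disjointWith:
                add(
                    TagValue(
                        "disjoint_from",
                        LogicalClause(LogicalKind.DISJOINT_FROM, self.obo_id(o)),
                    )
                )
            elif p == oio.hasDefinition:
                add(
                    TagValue(
                        "def", DefClause(text=self.label_of(o), xrefs=self.xrefs_of(o))
                    )
                )
            elif oio.local_name(p) in _SYNONYM_SCOPE_FROM_PROPERTY:
                add(self._synonym_clause(o, _SYNONYM_SCOPE_FROM_PROPERTY[oio.local_name(p)]))
            elif p == oio.inSubset:
                add(TagValue("subset", self.local_resource_name(o)))
            elif p == oio.hasAlternativeId:
                add(TagValue("alt_id", obo_io.parse_id(str(o))))
            elif p == oio.hasOBONamespace:
                add(TagValue("namespace", str(o)))
            elif p == oio.replacedBy:
                add(TagValue("replaced_by", self.obo_id(o)))
            elif p == oio.consider:
                add(TagValue("consider", self.obo_id(o)))
            else:
                add(self._unknown_clause(p, o))
        return stanza

    def rebuild_typedef(self, subject: URIRef) -> Stanza:
        g, oio = self.graph, self.oio
        stanza = Stanza(StanzaKind.TYPEDEF, self.obo_id(subject))
        add = stanza.clauses.append
        for p, o in g.predicate_objects(subject):
            if p == RDF.type:
                if o == OWL.TransitiveProperty:
                    add(TagValue("is_transitive", True))
                elif o == OWL.SymmetricProperty:
                    add(TagValue("is_symmetric", True))
                continue
            if p == RDFS.label:
                add(TagValue("name", str(o)))
            elif p == RDFS.comment:
                add(TagValue("comment", str(o)))
            elif p == RDFS.subPropertyOf:
                if o == oio.ObsoleteProperty:
                    add(TagValue("is_obsolete", True))
                else:
                    add(TagValue("is_a", self.obo_id(o)))
            elif p == RDFS.domain:
                add(TagValue("domain", self.obo_id(o)))
            elif p == RDFS.range:
                add(TagValue("range", self.obo_id(o)))
            elif p == OWL.inverseOf:
                add(TagValue("inverse_of", self.obo_id(o)))
            elif p == oio.transitiveOver:
                add(TagValue("transitive_over", self.obo_id(o)))
            elif p == oio.isCyclic:
                add(TagValue("is_cyclic", bool(o.toPython())))
            elif p == oio.hasDefinition:
                add(
                    TagValue(
                        "def", DefClause(text=self.label_of(o), xrefs=self.xrefs_of(o))
                    )
                )
            elif oio.local_name(p) in _SYNONYM_SCOPE_FROM_PROPERTY:
                add(self._synonym_clause(o, _SYNONYM_SCOPE_FROM_PROPERTY[oio.local_name(p)]))
            elif p == oio.inSubset:
                add(TagValue("subset", self.local_resource_name(o)))
            elif p == oio.hasAlternativeId:
                add(TagValue("alt_id", obo_io.parse_id(str(o))))
            elif p == oio.hasOBONamespace:
                add(TagValue("namespace", str(o)))
            elif p == oio.replacedBy:
                add(TagValue("replaced_by", self.obo_id(o)))
            elif p == oio.consider:
                add(TagValue("consider", self.obo_id(o)))
            else:
                add(self._unknown_clause(p, o))
        return stanza


def translate_graph(
    graph: TripleGraph,
    registry: Optional[IdSpaceRegistry] = None,
    oio: OboInOwl = OBOINOWL,
) -> OBODocument:
    """Rebuild an OBO document from an OWL graph produced by (or compatible
    with) the forward mapping; the result is in canonical form.

    Raises ``E_UNTRANSLATABLE`` (wrapping the first subset violation) when
    the graph leaves the OBO-expressible subset, and may raise
    ``E_FOREIGN_IRI`` for entity IRIs outside every known base.
    """
    violations = validate_subset(graph, oio)
    if violations:
        first = violations[0]
        raise OboError(
            "E_UNTRANSLATABLE",
            f"graph is outside the OBO-expressible subset: "
            f"{first.code.value} at {first.node}: {first.message}",
        )
    rv = _Reverser(graph, registry, oio)
    header = rv.rebuild_header()
    classes, props = rv.entity_subjects()
    stanzas = [rv.rebuild_term(s) for s in classes]
    stanzas.extend(rv.rebuild_typedef(s) for s in props)
    return canonicalize(OBODocument(header=header, stanzas=stanzas))
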