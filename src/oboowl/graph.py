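"""Triple-graph layer: oboInOwl vocabulary, RDF/XML I/O, graph comparison.

The OWL side of the translation is an RDF triple graph.  This module is a
thin, deterministic layer over :mod:`rdflib`: ``TripleGraph`` *is* an
``rdflib.Graph`` (IRIs are ``URIRef``, anonymous nodes ``BNode``, literals
``Literal``), and the module adds

* the **oboInOwl** meta-vocabulary — annotation properties and helper
  classes for OBO constructs with no native OWL equivalent (ObsoleteClass,
  Subset, inSubset, hasDefinition, synonym scopes, …),
* byte-deterministic RDF/XML serialization (canonical triple ordering and
  anonymous-node relabelling before handing off to rdflib), and
* blank-node-aware graph isomorphism, the equality used by golden tests.
"""

from __future__ import annotations

from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.compare import isomorphic
from rdflib.namespace import OWL, RDF, RDFS, XSD

from .model import OboError

__all__ = [
    "TripleGraph",
    "OBOINOWL_NAMESPACE",
    "OBOINOWL",
    "OboInOwl",
    "new_graph",
    "write_rdfxml",
    "read_rdfxml",
    "graphs_isomorphic",
    "describe",
    "OWL",
    "RDF",
    "RDFS",
    "XSD",
    "URIRef",
    "BNode",
    "Literal",
]

#: the OWL-side graph container (rdflib semantics: a set of triples)
TripleGraph = Graph

#: community-conventional namespace of the oboInOwl meta-vocabulary;
#: pass a different namespace to the vocabulary constructor to override.
OBOINOWL_NAMESPACE = "http://www.geneontology.org/formats/oboInOwl#"


class OboInOwl:
    """The oboInOwl meta-vocabulary under a configurable namespace."""

    _NAMES = (
        # helper classes
        "ObsoleteClass",
        "ObsoleteProperty",
        "Subset",
        "SynonymType",
        # term/typedef annotations
        "inSubset",
        "hasDefinition",
        "hasSynonym",
        "hasExactSynonym",
        "hasBroadSynonym",
        "hasNarrowSynonym",
        "hasRelatedSynonym",
        "hasSynonymType",
        "hasDbXref",
        "hasAlternativeId",
        "hasOBONamespace",
        "isCyclic",
        "transitiveOver",
        "replacedBy",
        "consider",
        # header annotations
        "hasDefaultNamespace",
        "hasDate",
        "savedBy",
        "autoGeneratedBy",
        "hasFormatVersion",
        "hasVersion",
        "hasSubsetDef",  # reserved
        "hasScope",
        # roundtrip bookkeeping
        "hasBaseIRI",
        "hasIdSpace",
    )

    def __init__(self, namespace: str = OBOINOWL_NAMESPACE):
        self.namespace = namespace
        ns = Namespace(namespace)
        for name in self._NAMES:
            setattr(self, name, ns[name])

    def term(self, local: str) -> URIRef:
        return URIRef(self.namespace + local)

    def local_name(self, iri: URIRef) -> str | None:
        s = str(iri)
        if s.startswith(self.namespace):
            return s[len(self.namespace) :]
        return None

    def is_meta(self, node) -> bool:
        return isinstance(node, URIRef) and str(node).startswith(self.namespace)

    @property
    def known_iris(self) -> frozenset[URIRef]:
        return frozenset(getattr(self, n) for n in self._NAMES)


#: default vocabulary instance
OBOINOWL = OboInOwl()


def new_graph(base_iri: str | None = None, oio: OboInOwl = OBOINOWL) -> TripleGraph:
    """Fresh graph with the conventional namespace bindings."""
    g = Graph()
    g.bind("owl", OWL)
    g.bind("oboInOwl", Namespace(oio.namespace))
    from .ids import OBO_REL_BASE_IRI  # local import to avoid a cycle

    g.bind("oboRel", Namespace(OBO_REL_BASE_IRI))
    if base_iri:
        g.bind("obo", Namespace(base_iri))
    return g


# --------------------------------------------------------------------------
# deterministic RDF/XML

# fixed predicate order: declarations first, then labelling, then axioms
_PREDICATE_ORDER = [RDF.type, RDFS.label, RDFS.comment, RDFS.subClassOf, RDFS.subPropertyOf]
_PREDICATE_RANK = {p: i for i, p in enumerate(_PREDICATE_ORDER)}


def _term_key(t):
    if isinstance(t, URIRef):
        return (0, str(t), "", "")
    if isinstance(t, BNode):
        return (1, str(t), "", "")
    return (2, str(t), str(t.datatype or ""), t.language or "")


def _triple_key(triple):
    s, p, o = triple
    return (_term_key(s), (_PREDICATE_RANK.get(p, len(_PREDICATE_ORDER)), str(p)), _term_key(o))


def write_rdfxml(graph: TripleGraph) -> str:
    """Serialize to standards-conformant RDF/XML.

    Triples are sorted by a canonical key and anonymous nodes relabelled in
    first-appearance order, so the output is byte-identical for equally
    labelled graphs.  Raises ``E_SERIALIZE`` on a literal in subject
    position.
    """
    ordered = sorted(graph, key=_triple_key)
    relabel: dict[BNode, BNode] = {}

    def rename(term):
        if isinstance(term, BNode):
            if term not in relabel:
                relabel[term] = BNode(f"N{len(relabel)}")
            return relabel[term]
        return term

    out = Graph()
    for prefix, ns in graph.namespaces():
        out.bind(prefix, ns, replace=True)
    for s, p, o in ordered:
        if isinstance(s, Literal):
            raise OboError("E_SERIALIZE", f"literal in subject position: {s!r}")
        out.add((rename(s), p, rename(o)))
    return out.serialize(format="xml")


def read_rdfxml(text: str) -> TripleGraph:
    """Parse RDF/XML into a graph; raises ``E_XML`` on malformed input."""
    g = Graph()
    try:
        g.parse(data=text, format="xml")
    except Exception as exc:  # rdflib raises SAXParseException and friends
        raise OboError("E_XML", f"malformed RDF/XML: {exc}") from exc
    return g


def graphs_isomorphic(a: TripleGraph, b: TripleGraph) -> bool:
    """True iff some bijection of anonymous nodes makes the triple sets
    equal (namespace bindings are ignored)."""
    return isomorphic(a, b)


def describe(graph: TripleGraph, root: URIRef, oio: OboInOwl = OBOINOWL) -> TripleGraph:
    """Concise-bounded-style subgraph of *root*: its own triples, the
    closure over anonymous objects (including RDF lists), and the
    declaration triples of any oboInOwl helper class it references."""
    out = Graph()
    seen: set = set()
    frontier = [root]
    while frontier:
        node = frontier.pop()
        if node in seen:
            continue
        seen.add(node)
        for p, o in graph.predicate_objects(node):
            out.add((node, p, o))
            if isinstance(o, BNode):
                frontier.append(o)
            elif isinstance(o, URIRef) and oio.is_meta(o):
                for p2, o2 in graph.predicate_objects(o):
                    out.add((o, p2, o2))
    return out
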