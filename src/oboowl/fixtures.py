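"""Seeded synthetic OBO documents and the printed golden corpus.

:func:`generate_document` builds a deterministic synthetic ontology that
exercises every supported construct: prefixed and flat identifiers,
registered and unregistered ID spaces, an acyclic ``is_a`` hierarchy,
relationships, genus-differentia (``intersection_of``) and ``union_of``
definitions, disjointness, definitions and synonyms with cross-references,
subsets, synonym types, and obsolete stanzas.  Every generated document
passes structural validation with zero errors and roundtrips exactly.

:func:`table2_corpus` returns the four worked translation examples that
accompany the mapping (name/transitivity, is-a, relationship, obsolete
term) as parsed OBO/OWL golden pairs.  The OWL fragments instantiate the
elided "…#" base of the published snippets with the default base IRI; the
flat typedef id ``part_of`` follows the flat-identifier rule and therefore
appears as ``UNDEFINED_part_of`` in the IRIs (the identifier rules, not
the typography of the worked example, are normative for this package).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import OBOINOWL_NAMESPACE, TripleGraph, read_rdfxml
from .ids import FALLBACK_BASE_IRI
from .io import parse_obo, render_header_value
from .model import (
    DbXref,
    DefClause,
    HeaderClause,
    IdSpaceDecl,
    LogicalClause,
    LogicalKind,
    OBODocument,
    OBOId,
    RelationshipClause,
    Stanza,
    StanzaKind,
    SubsetDef,
    SynonymClause,
    SynonymScope,
    SynonymTypeDef,
    TagValue,
)

__all__ = ["FixtureParams", "generate_document", "Table2Example", "table2_corpus"]


@dataclass(frozen=True)
class FixtureParams:
    """Shape parameters of a synthetic document; a pure function of these
    (seed included) determines the output."""

    n_terms: int = 50
    n_typedefs: int = 4
    p_obsolete: float = 0.05
    n_subsets: int = 2
    n_synonym_types: int = 2
    p_synonym: float = 0.3
    p_def: float = 0.6
    mean_relationships: float = 1.0
    p_logical: float = 0.1
    idspaces: tuple[tuple[str, str], ...] = (("ZFA", "http://purl.org/obo/owl/ZFA#"),)
    p_flat_id: float = 0.05
    seed: int = 0

    def validate(self):
        for name in ("p_obsolete", "p_synonym", "p_def", "p_logical", "p_flat_id"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_terms", "n_typedefs", "n_subsets", "n_synonym_types"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if self.mean_relationships < 0:
            raise ValueError("mean_relationships must be ≥ 0")


def _header_clause(tag: str, parsed) -> HeaderClause:
    return HeaderClause(tag, render_header_value(tag, parsed), parsed)


def generate_document(params: FixtureParams = FixtureParams()) -> OBODocument:
    """Deterministically generate a valid synthetic OBO document.

    The ``is_a`` edges attach each stanza to a uniformly chosen earlier one,
    so the hierarchy is acyclic by construction; obsolete stanzas carry no
    relational clauses; every subset and synonym-type reference is declared
    in the header.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    subsets = [f"subset_{i}" for i in range(params.n_subsets)]
    syntypes = [f"syntype_{i}" for i in range(params.n_synonym_types)]
    scopes = list(SynonymScope)

    header = [
        HeaderClause("format-version", "1.2"),
        HeaderClause("date", "07:03:2011 12:00"),
        HeaderClause("saved-by", "fixture-generator"),
        HeaderClause("auto-generated-by", "oboowl"),
        HeaderClause("default-namespace", "synthetic_ontology"),
    ]
    for prefix, base in params.idspaces:
        header.append(_header_clause("idspace", IdSpaceDecl(prefix, base)))
    for i, name in enumerate(subsets):
        header.append(_header_clause("subsetdef", SubsetDef(name, f"synthetic subset {i}")))
    for i, name in enumerate(syntypes):
        scope = scopes[rng.integers(len(scopes))] if rng.random() < 0.5 else None
        if scope is SynonymScope.UNSPECIFIED:
            scope = None
        header.append(
            _header_clause("synonymtypedef", SynonymTypeDef(name, f"synthetic synonym type {i}", scope))
        )

    prefixes = [p for p, _ in params.idspaces] + ["XX"]  # XX: deliberately unregistered

    def term_id(i: int) -> OBOId:
        if rng.random() < params.p_flat_id:
            return OBOId(local=f"flat_term_{i}")
        return OBOId(idspace=prefixes[rng.integers(len(prefixes))], local=f"{i:07d}")

    def typedef_id(j: int) -> OBOId:
        r = rng.random()
        if r < 0.25:
            return OBOId(idspace="OBO_REL", local=f"rel_{j}")
        if r < 0.5:
            return OBOId(idspace=prefixes[rng.integers(len(prefixes))], local=f"r{j:04d}")
        return OBOId(local=f"rel_{j}")

    term_ids = [term_id(i) for i in range(params.n_terms)]
    typedef_ids = [typedef_id(j) for j in range(params.n_typedefs)]

    def pick(seq):
        return seq[rng.integers(len(seq))]

    def some_xrefs() -> tuple[DbXref, ...]:
        xs = []
        for k in range(rng.integers(0, 3)):
            desc = f"source {k}" if rng.random() < 0.3 else None
            xs.append(DbXref(id=f"PMID:{rng.integers(1, 10_000_000)}", description=desc))
        return tuple(xs)

    stanzas: list[Stanza] = []
    usable_typedefs: list[OBOId] = []

    for j, tid in enumerate(typedef_ids):
        clauses = [TagValue("name", f"relation {j}")]
        obsolete = rng.random() < params.p_obsolete and j > 0
        if rng.random() < params.p_def:
            clauses.append(TagValue("def", DefClause(f"synthetic relation {j}.", some_xrefs())))
        if obsolete:
            clauses.append(TagValue("is_obsolete", True))
            if usable_typedefs and rng.random() < 0.5:
                clauses.append(TagValue("replaced_by", pick(usable_typedefs)))
        else:
            if rng.random() < 0.3:
                clauses.append(TagValue("is_transitive", True))
            if rng.random() < 0.15:
                clauses.append(TagValue("is_symmetric", True))
            if rng.random() < 0.2:
                clauses.append(TagValue("is_cyclic", bool(rng.random() < 0.5)))
            if usable_typedefs and rng.random() < 0.3:
                clauses.append(TagValue("is_a", pick(usable_typedefs)))
            if usable_typedefs and rng.random() < 0.15:
                clauses.append(TagValue("inverse_of", pick(usable_typedefs)))
            if usable_typedefs and rng.random() < 0.15:
                clauses.append(TagValue("transitive_over", pick(usable_typedefs)))
            if term_ids and rng.random() < 0.2:
                clauses.append(TagValue("domain", pick(term_ids)))
            if term_ids and rng.random() < 0.2:
                clauses.append(TagValue("range", pick(term_ids)))
            usable_typedefs.append(tid)
        stanzas.append(Stanza(StanzaKind.TYPEDEF, tid, clauses))

    for i, cid in enumerate(term_ids):
        clauses = [TagValue("name", f"synthetic term {i}")]
        obsolete = rng.random() < params.p_obsolete and i > 0
        if rng.random() < params.p_def:
            clauses.append(TagValue("def", DefClause(f"a synthetic term number {i}.", some_xrefs())))
        if rng.random() < 0.2:
            clauses.append(TagValue("comment", f"autogenerated stanza {i}"))
        if rng.random() < 0.1:
            clauses.append(TagValue("namespace", "synthetic_ontology"))
        if rng.random() < 0.1:
            clauses.append(TagValue("alt_id", OBOId(idspace="ALT", local=f"{i:07d}")))
        if rng.random() < params.p_synonym:
            for _ in range(rng.integers(1, 3)):
                type_name = pick(syntypes) if syntypes and rng.random() < 0.3 else None
                clauses.append(
                    TagValue(
                        "synonym",
                        SynonymClause(
                            text=f"synonym {i}-{rng.integers(100)}",
                            scope=scopes[rng.integers(len(scopes))],
                            type_name=type_name,
                            xrefs=some_xrefs(),
                        ),
                    )
                )
        if subsets and rng.random() < 0.25:
            clauses.append(TagValue("subset", pick(subsets)))
        if obsolete:
            clauses.append(TagValue("is_obsolete", True))
            if rng.random() < 0.5:
                clauses.append(TagValue("replaced_by", term_ids[rng.integers(i)]))
            if rng.random() < 0.2:
                clauses.append(TagValue("consider", term_ids[rng.integers(i)]))
        else:
            if i > 0:
                clauses.append(TagValue("is_a", term_ids[rng.integers(i)]))
            if usable_typedefs:
                for _ in range(min(int(rng.poisson(params.mean_relationships)), 3)):
                    clauses.append(
                        TagValue(
                            "relationship",
                            RelationshipClause(pick(usable_typedefs), pick(term_ids)),
                        )
                    )
            if i > 1 and rng.random() < params.p_logical:
                choice = rng.random()
                if choice < 0.45 and usable_typedefs:
                    genus = term_ids[rng.integers(i)]
                    clauses.append(
                        TagValue(
                            "intersection_of",
                            LogicalClause(LogicalKind.INTERSECTION_OF, genus),
                        )
                    )
                    for _ in range(rng.integers(1, 3)):
                        clauses.append(
                            TagValue(
                                "intersection_of",
                                LogicalClause(
                                    LogicalKind.INTERSECTION_OF,
                                    operand_class=term_ids[rng.integers(i)],
                                    operand_relation=pick(usable_typedefs),
                                ),
                            )
                        )
                elif choice < 0.75:
                    for _ in range(rng.integers(2, 4)):
                        clauses.append(
                            TagValue(
                                "union_of",
                                LogicalClause(LogicalKind.UNION_OF, term_ids[rng.integers(i)]),
                            )
                        )
                else:
                    clauses.append(
                        TagValue(
                            "disjoint_from",
                            LogicalClause(LogicalKind.DISJOINT_FROM, term_ids[rng.integers(i)]),
                        )
                    )
        stanzas.append(Stanza(StanzaKind.TERM, cid, clauses))

    return OBODocument(header=header, stanzas=stanzas)


# --------------------------------------------------------------------------
# golden corpus: the four worked translation examples


@dataclass(frozen=True)
class Table2Example:
    label: str
    obo_text: str
    owl_text: str
    document: OBODocument = field(compare=False)
    graph: TripleGraph = field(compare=False)

    def __iter__(self):
        yield self.document
        yield self.graph


_B = FALLBACK_BASE_IRI
_RDF_OPEN = (
    '<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"\n'
    '         xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"\n'
    '         xmlns:owl="http://www.w3.org/2002/07/owl#"\n'
    f'         xmlns:oboInOwl="{OBOINOWL_NAMESPACE}">\n'
)

_EXAMPLES = [
    (
        "A",  # simple transformations: name, transitivity
        "[Typedef]\nid: part_of\nname: part of\nis_transitive: true\n",
        _RDF_OPEN
        + f'  <owl:TransitiveProperty rdf:about="{_B}UNDEFINED_part_of">\n'
        "    <rdfs:label>part of</rdfs:label>\n"
        "  </owl:TransitiveProperty>\n"
        "</rdf:RDF>\n",
    ),
    (
        "B",  # transformation of is-a
        "[Term]\nid: ZFA:0000434\nname: skeletal system\nis_a: ZFA:0001439\n",
        _RDF_OPEN
        + f'  <owl:Class rdf:about="{_B}ZFA_0000434">\n'
        "    <rdfs:label>skeletal system</rdfs:label>\n"
        f'    <rdfs:subClassOf rdf:resource="{_B}ZFA_0001439"/>\n'
        "  </owl:Class>\n"
        "</rdf:RDF>\n",
    ),
    (
        "C",  # transformation of a relationship
        "[Term]\nid: ZFA:0001439\nname: anatomical system\nrelationship: part_of ZFA:0001094\n",
        _RDF_OPEN
        + f'  <owl:Class rdf:about="{_B}ZFA_0001439">\n'
        "    <rdfs:label>anatomical system</rdfs:label>\n"
        "    <rdfs:subClassOf>\n"
        "      <owl:Restriction>\n"
        f'        <owl:onProperty rdf:resource="{_B}UNDEFINED_part_of"/>\n'
        f'        <owl:someValuesFrom rdf:resource="{_B}ZFA_0001094"/>\n'
        "      </owl:Restriction>\n"
        "    </rdfs:subClassOf>\n"
        "  </owl:Class>\n"
        "</rdf:RDF>\n",
    ),
    (
        "D",  # transformation of an obsolete term
        "[Term]\nid: ZFA:0000437\nname: stomach\nis_obsolete: true\n",
        _RDF_OPEN
        + f'  <owl:Class rdf:about="{OBOINOWL_NAMESPACE}ObsoleteClass"/>\n'
        f'  <owl:Class rdf:about="{_B}ZFA_0000437">\n'
        "    <rdfs:label>stomach</rdfs:label>\n"
        f'    <rdfs:subClassOf rdf:resource="{OBOINOWL_NAMESPACE}ObsoleteClass"/>\n'
        "  </owl:Class>\n"
        "</rdf:RDF>\n",
    ),
]


def table2_corpus() -> list[Table2Example]:
    """The four worked OBO/OWL golden pairs, parsed."""
    out = []
    for label, obo_text, owl_text in _EXAMPLES:
        out.append(
            Table2Example(
                label=label,
                obo_text=obo_text,
                owl_text=owl_text,
                document=parse_obo(obo_text, f"example-{label}.obo"),
                graph=read_rdfxml(owl_text),
            )
        )
    return out
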