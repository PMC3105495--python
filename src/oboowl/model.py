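"""In-memory model for OBO 1.2 documents.

An OBO 1.2 file is a header (tag-value pairs) followed by ``[Term]`` and
``[Typedef]`` stanzas.  This module defines the document model shared by the
parser, the OBO→OWL translator and its inverse, together with:

* the *layer* classification of OBO tags (Core / Vocabulary / Ontology
  Extensions, mirroring the RDF / RDF-S / OWL strata of the Semantic Web
  layer cake),
* structural validation (obsolescence rules, duplicate ids, undeclared
  subsets/synonym types, malformed booleans), and
* :func:`canonicalize`, the normal form that defines document equality for
  the lossless-roundtrip guarantee.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Union

__all__ = [
    "Layer",
    "StanzaKind",
    "SynonymScope",
    "LogicalKind",
    "Severity",
    "OBOId",
    "DbXref",
    "DefClause",
    "SynonymClause",
    "RelationshipClause",
    "LogicalClause",
    "SubsetDef",
    "SynonymTypeDef",
    "IdSpaceDecl",
    "ImportRef",
    "HeaderClause",
    "TagValue",
    "Stanza",
    "OBODocument",
    "Issue",
    "OboError",
    "classify_tag",
    "validate_document",
    "canonicalize",
    "BOOLEAN_TAGS",
    "ID_TAGS",
    "RELATIONAL_TAGS",
    "CANONICAL_TAG_ORDER",
    "HEADER_TAG_ORDER",
]


class OboError(Exception):
    """Error with a machine-readable code and an optional source location."""

    def __init__(self, code: str, message: str, source: str = "", line: int = 0):
        self.code = code
        self.source = source
        self.line = line
        loc = f"{source}:{line}: " if source and line else (f"{source}: " if source else "")
        super().__init__(f"{code}: {loc}{message}")


class Layer(enum.Enum):
    CORE = "core"
    VOCABULARY = "vocabulary"
    EXTENSIONS = "extensions"
    UNKNOWN = "unknown"


class StanzaKind(enum.Enum):
    # enum order fixes canonical stanza order: terms before typedefs
    TERM = "Term"
    TYPEDEF = "Typedef"


class SynonymScope(enum.Enum):
    RELATED = "RELATED"
    NARROW = "NARROW"
    BROAD = "BROAD"
    EXACT = "EXACT"
    UNSPECIFIED = ""


class LogicalKind(enum.Enum):
    INTERSECTION_OF = "intersection_of"
    UNION_OF = "union_of"
    DISJOINT_FROM = "disjoint_from"


class Severity(enum.Enum):
    ERROR = "error"
    WARNING = "warning"


# --------------------------------------------------------------------------
# identifiers and clause payloads


@dataclass(frozen=True)
class OBOId:
    """An OBO identifier: either prefixed (``GO:0000001``) or flat (``foo``)."""

    local: str
    idspace: Optional[str] = None

    @property
    def is_flat(self) -> bool:
        return self.idspace is None

    def render(self) -> str:
        if self.idspace is None:
            return self.local
        return f"{self.idspace}:{self.local}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class DbXref:
    """Database cross-reference attached to a definition or synonym."""

    id: str
    description: Optional[str] = None


@dataclass(frozen=True)
class DefClause:
    text: str
    xrefs: tuple[DbXref, ...] = ()


@dataclass(frozen=True)
class SynonymClause:
    text: str
    scope: SynonymScope = SynonymScope.UNSPECIFIED
    type_name: Optional[str] = None
    xrefs: tuple[DbXref, ...] = ()


@dataclass(frozen=True)
class RelationshipClause:
    type_id: OBOId
    target_id: OBOId


@dataclass(frozen=True)
class LogicalClause:
    kind: LogicalKind
    operand_class: OBOId
    operand_relation: Optional[OBOId] = None  # differentia lines of intersection_of only


# header payloads


@dataclass(frozen=True)
class SubsetDef:
    name: str
    description: str = ""


@dataclass(frozen=True)
class SynonymTypeDef:
    name: str
    description: str = ""
    default_scope: Optional[SynonymScope] = None


@dataclass(frozen=True)
class IdSpaceDecl:
    prefix: str
    base_iri: str
    description: Optional[str] = None


@dataclass(frozen=True)
class ImportRef:
    target: str


HeaderPayload = Union[IdSpaceDecl, SubsetDef, SynonymTypeDef, ImportRef]

ClauseValue = Union[
    str, bool, OBOId, DefClause, SynonymClause, RelationshipClause, LogicalClause
]


@dataclass(frozen=True)
class HeaderClause:
    """One header tag-value line; ``parsed`` holds structure for known tags."""

    tag: str
    value: str
    parsed: Optional[HeaderPayload] = None


@dataclass(frozen=True)
class TagValue:
    """One stanza clause: tag, structured value, trailing qualifiers, comment."""

    tag: str
    value: ClauseValue
    qualifiers: tuple[tuple[str, str], ...] = ()
    inline_comment: Optional[str] = None


@dataclass
class Stanza:
    kind: StanzaKind
    id: OBOId
    clauses: list[TagValue] = field(default_factory=list)

    def find(self, tag: str) -> list[TagValue]:
        return [c for c in self.clauses if c.tag == tag]

    def boolean(self, tag: str) -> bool:
        """True iff the stanza carries ``tag: true``."""
        return any(c.value is True for c in self.find(tag))

    @property
    def is_obsolete(self) -> bool:
        return self.boolean("is_obsolete")


@dataclass
class OBODocument:
    header: list[HeaderClause] = field(default_factory=list)
    stanzas: list[Stanza] = field(default_factory=list)

    def header_value(self, tag: str) -> Optional[str]:
        for clause in self.header:
            if clause.tag == tag:
                return clause.value
        return None

    def terms(self) -> list[Stanza]:
        return [s for s in self.stanzas if s.kind is StanzaKind.TERM]

    def typedefs(self) -> list[Stanza]:
        return [s for s in self.stanzas if s.kind is StanzaKind.TYPEDEF]

    def subset_defs(self) -> list[SubsetDef]:
        return [c.parsed for c in self.header if isinstance(c.parsed, SubsetDef)]

    def synonym_type_defs(self) -> list[SynonymTypeDef]:
        return [c.parsed for c in self.header if isinstance(c.parsed, SynonymTypeDef)]

    def idspace_decls(self) -> list[IdSpaceDecl]:
        return [c.parsed for c in self.header if isinstance(c.parsed, IdSpaceDecl)]


@dataclass(frozen=True)
class Issue:
    severity: Severity
    code: str
    location: str
    message: str


# --------------------------------------------------------------------------
# layer classification

# Layer-cake assignment of OBO constructs.  `relationship` appears in both the
# Core and the Ontology Extensions stratum of the published table; the
# classification returns CORE for it (the duplication is inherent to the
# table, not resolvable here).  The definition tag is listed as "definition"
# but spelled `def` in OBO 1.2 files; both spellings classify identically.
_CORE_TAGS = frozenset({"id", "idspace", "relationship"})
_VOCABULARY_TAGS = frozenset({"name", "definition", "def", "comment", "is_a", "domain", "range"})
_EXTENSION_TAGS = frozenset(
    {
        "format-version",
        "version",
        "date",
        "saved-by",
        "auto-generated-by",
        "namespace",
        "default-namespace",
        "subsetdef",
        "alt_id",
        "subset",
        "synonym",
        "is_obsolete",
        "is_cyclic",
        "is_transitive",
        "is_symmetric",
        "import",
        "synonymtypedef",
        "intersection_of",
        "union_of",
        "disjoint_from",
        "replaced_by",
        "consider",
        "inverse_of",
        "transitive_over",
    }
)


def classify_tag(tag: str) -> Layer:
    """Assign an OBO tag to its layer-cake stratum.

    Total over all strings; tags outside the published inventory map to
    :attr:`Layer.UNKNOWN` (and are preserved verbatim by the translators).
    """
    if tag in _CORE_TAGS:
        return Layer.CORE
    if tag in _VOCABULARY_TAGS:
        return Layer.VOCABULARY
    if tag in _EXTENSION_TAGS:
        return Layer.EXTENSIONS
    return Layer.UNKNOWN


# --------------------------------------------------------------------------
# tag inventories used by parsing, validation and canonical ordering

BOOLEAN_TAGS = frozenset({"is_obsolete", "is_cyclic", "is_transitive", "is_symmetric"})

#: stanza tags whose value is a single OBO identifier
ID_TAGS = frozenset(
    {"is_a", "alt_id", "domain", "range", "inverse_of", "transitive_over", "replaced_by", "consider"}
)

#: clauses an obsolete stanza must not carry
RELATIONAL_TAGS = frozenset(
    {"is_a", "relationship", "inverse_of", "transitive_over", "domain", "range"}
)

#: canonical in-stanza clause order (the order of the OBO 1.2 format
#: documentation); unknown tags sort after all known ones.
CANONICAL_TAG_ORDER = (
    "is_anonymous",
    "name",
    "namespace",
    "alt_id",
    "def",
    "comment",
    "subset",
    "synonym",
    "xref",
    "is_a",
    "intersection_of",
    "union_of",
    "disjoint_from",
    "relationship",
    "is_obsolete",
    "replaced_by",
    "consider",
    "domain",
    "range",
    "inverse_of",
    "transitive_over",
    "is_cyclic",
    "is_transitive",
    "is_symmetric",
)

HEADER_TAG_ORDER = (
    "format-version",
    "version",
    "date",
    "saved-by",
    "auto-generated-by",
    "default-namespace",
    "namespace",
    "idspace",
    "subsetdef",
    "synonymtypedef",
    "import",
)

_TAG_RANK = {t: i for i, t in enumerate(CANONICAL_TAG_ORDER)}
_HEADER_RANK = {t: i for i, t in enumerate(HEADER_TAG_ORDER)}


# --------------------------------------------------------------------------
# validation


def validate_document(doc: OBODocument) -> list[Issue]:
    """Structural validation; returns all violations (never raises).

    Checks: obsolete stanzas carrying relational clauses, duplicate stanza
    ids per kind, malformed boolean values, subset references without a
    ``subsetdef``, and synonym types without a ``synonymtypedef``.
    """
    issues: list[Issue] = []
    declared_subsets = {sd.name for sd in doc.subset_defs()}
    declared_syntypes = {st.name for st in doc.synonym_type_defs()}

    seen: dict[tuple[StanzaKind, str], int] = {}
    for stanza in doc.stanzas:
        loc = f"[{stanza.kind.value}] {stanza.id.render()}"
        if not stanza.id.local:
            issues.append(Issue(Severity.ERROR, "E_NO_ID", loc, "stanza has an empty id"))
        key = (stanza.kind, stanza.id.render())
        if key in seen:
            issues.append(
                Issue(
                    Severity.ERROR,
                    "E_DUP_ID",
                    loc,
                    f"duplicate {stanza.kind.value} id {stanza.id.render()!r}",
                )
            )
        seen[key] = seen.get(key, 0) + 1

        for clause in stanza.clauses:
            if clause.tag in BOOLEAN_TAGS and not isinstance(clause.value, bool):
                issues.append(
                    Issue(
                        Severity.ERROR,
                        "E_BAD_BOOLEAN",
                        loc,
                        f"{clause.tag} must be 'true' or 'false', got {clause.value!r}",
                    )
                )
            if clause.tag == "subset" and clause.value not in declared_subsets:
                issues.append(
                    Issue(
                        Severity.WARNING,
                        "W_UNDECLARED_SUBSET",
                        loc,
                        f"subset {clause.value!r} has no subsetdef in the header",
                    )
                )
            if (
                clause.tag == "synonym"
                and isinstance(clause.value, SynonymClause)
                and clause.value.type_name
                and clause.value.type_name not in declared_syntypes
            ):
                issues.append(
                    Issue(
                        Severity.WARNING,
                        "W_UNDECLARED_SYNTYPE",
                        loc,
                        f"synonym type {clause.value.type_name!r} has no synonymtypedef",
                    )
                )

        if stanza.is_obsolete:
            offending = sorted({c.tag for c in stanza.clauses if c.tag in RELATIONAL_TAGS})
            for tag in offending:
                issues.append(
                    Issue(
                        Severity.ERROR,
                        "E_OBSOLETE_REL",
                        loc,
                        f"obsolete stanza must not carry relational clause {tag!r}",
                    )
                )
    return issues


# --------------------------------------------------------------------------
# canonicalization


def _xref_key(x: DbXref):
    return (x.id, x.description or "")


def _id_key(i: OBOId):
    return (i.idspace or "", i.local)


def _value_key(value: ClauseValue):
    """Deterministic sort key over the clause-value union type."""
    if isinstance(value, bool):
        return ("bool", str(value))
    if isinstance(value, str):
        return ("str", value)
    if isinstance(value, OBOId):
        return ("id",) + _id_key(value)
    if isinstance(value, DefClause):
        return ("def", value.text, tuple(map(_xref_key, value.xrefs)))
    if isinstance(value, SynonymClause):
        return (
            "synonym",
            value.text,
            value.scope.name,
            value.type_name or "",
            tuple(map(_xref_key, value.xrefs)),
        )
    if isinstance(value, RelationshipClause):
        return ("rel", _id_key(value.type_id), _id_key(value.target_id))
    if isinstance(value, LogicalClause):
        return (
            "logical",
            value.kind.value,
            _id_key(value.operand_relation) if value.operand_relation else (),
            _id_key(value.operand_class),
        )
    raise TypeError(f"unexpected clause value {value!r}")  # pragma: no cover


def _clause_key(clause: TagValue):
    rank = _TAG_RANK.get(clause.tag, len(CANONICAL_TAG_ORDER))
    return (rank, clause.tag, _value_key(clause.value), clause.qualifiers)


def _header_payload_key(clause: HeaderClause):
    p = clause.parsed
    if isinstance(p, IdSpaceDecl):
        return (p.prefix, p.base_iri, p.description or "")
    if isinstance(p, SubsetDef):
        return (p.name, p.description)
    if isinstance(p, SynonymTypeDef):
        return (p.name, p.description, p.default_scope.name if p.default_scope else "")
    if isinstance(p, ImportRef):
        return (p.target,)
    return (clause.value,)


def _header_key(clause: HeaderClause):
    rank = _HEADER_RANK.get(clause.tag, len(HEADER_TAG_ORDER))
    return (rank, clause.tag, _header_payload_key(clause))


def _canonical_clause(clause: TagValue) -> TagValue:
    """Normalize order-free collections inside a clause (xrefs, qualifiers)."""
    value = clause.value
    if isinstance(value, DefClause):
        value = replace(value, xrefs=tuple(sorted(value.xrefs, key=_xref_key)))
    elif isinstance(value, SynonymClause):
        value = replace(value, xrefs=tuple(sorted(value.xrefs, key=_xref_key)))
    quals = tuple(sorted(clause.qualifiers))
    return TagValue(clause.tag, value, quals, clause.inline_comment)


def canonicalize(doc: OBODocument) -> OBODocument:
    """Return the canonical form of *doc*: the normal form under which two
    documents are considered equal for roundtrip purposes.

    Stanzas sort by (kind, id); clauses within a stanza by the fixed tag
    order then by value; header clauses by the fixed header-tag order.
    Cross-reference lists and qualifier maps, whose order carries no
    knowledge, are sorted as well.  Idempotent and order-insensitive.
    """
    header = sorted(doc.header, key=_header_key)
    stanzas = []
    for stanza in sorted(doc.stanzas, key=lambda s: (s.kind.value, _id_key(s.id))):
        clauses = sorted((_canonical_clause(c) for c in stanza.clauses), key=_clause_key)
        stanzas.append(Stanza(stanza.kind, stanza.id, clauses))
    return OBODocument(header=header, stanzas=stanzas)
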