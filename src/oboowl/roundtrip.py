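"""Roundtrip checking and the entity-count evaluation protocol.

The evaluation protocol for the translation compares three count pairs:
terms/typedefs of the input OBO document, classes/object properties of the
OWL translation, and terms/typedefs of the roundtripped OBO document.  For
a lossless translation all three pairs are equal.  Counting on the OWL
side excludes the oboInOwl meta-vocabulary (ObsoleteClass,
ObsoleteProperty, Subset, SynonymType, …) and anonymous nodes — the
forward translation necessarily declares ObsoleteClass when obsolete terms
exist, and counting it would break the equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import zip_longest
from typing import Optional

from rdflib import URIRef
from rdflib.namespace import OWL, RDF

from .forward import TranslationOptions, translate_document
from .graph import OBOINOWL, OboInOwl, TripleGraph, read_rdfxml, write_rdfxml
from .ids import IdSpaceRegistry
from .io import serialize_obo
from .model import OBODocument, canonicalize
from .reverse import translate_graph

__all__ = ["RoundtripReport", "count_entities", "count_owl_entities", "roundtrip_check"]

_PROPERTY_TYPES = (OWL.ObjectProperty, OWL.TransitiveProperty, OWL.SymmetricProperty)


def count_entities(doc: OBODocument) -> tuple[int, int]:
    """(term count, typedef count) of a document, obsolete stanzas included."""
    return len(doc.terms()), len(doc.typedefs())


def count_owl_entities(graph: TripleGraph, oio: OboInOwl = OBOINOWL) -> tuple[int, int]:
    """(class count, object-property count) of a graph: distinct named IRIs
    typed ``owl:Class`` resp. object property (including the transitive and
    symmetric property types), excluding the oboInOwl meta-vocabulary."""
    classes = {
        s
        for s in graph.subjects(RDF.type, OWL.Class)
        if isinstance(s, URIRef) and not oio.is_meta(s)
    }
    props: set = set()
    for t in _PROPERTY_TYPES:
        props.update(
            s
            for s in graph.subjects(RDF.type, t)
            if isinstance(s, URIRef) and not oio.is_meta(s)
        )
    return len(classes), len(props)


@dataclass
class RoundtripReport:
    equal: bool
    diffs: list[tuple[str, str, str]] = field(default_factory=list)
    counts_in: tuple[int, int] = (0, 0)
    counts_owl: tuple[int, int] = (0, 0)
    counts_out: tuple[int, int] = (0, 0)


def roundtrip_check(
    doc: OBODocument,
    registry: Optional[IdSpaceRegistry] = None,
    opts: Optional[TranslationOptions] = None,
    via_text: bool = False,
    max_diffs: int = 100,
) -> RoundtripReport:
    """Translate *doc* to OWL and back and compare canonical forms.

    With ``via_text`` the OWL graph additionally passes through RDF/XML
    serialization and reparsing.  ``equal`` means canonical structural
    equality; ``diffs`` pinpoints the first mismatching canonical lines.
    """
    opts = opts or TranslationOptions()
    graph, _ = translate_document(doc, registry, opts)
    if via_text:
        graph = read_rdfxml(write_rdfxml(graph))
    oio = OboInOwl(opts.oboinowl_namespace)
    back = translate_graph(graph, registry, oio)
    original = canonicalize(doc)
    equal = original == back
    diffs: list[tuple[str, str, str]] = []
    if not equal:
        left_lines = serialize_obo(original).splitlines()
        right_lines = serialize_obo(back).splitlines()
        for n, (left, right) in enumerate(zip_longest(left_lines, right_lines, fillvalue=""), 1):
            if left != right:
                diffs.append((f"line {n}", left, right))
                if len(diffs) >= max_diffs:
                    break
    return RoundtripReport(
        equal=equal,
        diffs=diffs,
        counts_in=count_entities(doc),
        counts_owl=count_owl_entities(graph, oio),
        counts_out=count_entities(back),
    )
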