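"""Conversion between OBO identifiers and IRIs.

OBO identifiers are local: ``GO:0000001`` (prefixed) or ``foo`` (flat).
OWL needs globally unique IRIs, so the translator maps identifiers through
an :class:`IdSpaceRegistry` built from the document's ``idspace`` header
clauses:

* a prefixed id whose ID space is registered resolves against that base
  (``GO:0000001`` with ``idspace: GO http://www.go.org/owl#`` becomes
  ``http://www.go.org/owl#GO_0000001``);
* a prefixed id with an unregistered ID space resolves against the default
  base IRI (``SO:0000001`` → ``<default-base>SO_0000001``);
* a flat id is marked with ``UNDEFINED_`` so the reverse direction can
  restore its flatness (``foo`` → ``<default-base>UNDEFINED_foo``).

The ``OBO_REL`` ID space of the OBO Relations Ontology is implicitly
registered in every document so that relation typedefs resolve to the same
IRIs across ontologies.  The reverse direction strips the longest matching
base IRI and re-splits the local name (longest registered prefix first,
then first underscore), which inverts the forward map exactly on its range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model import OboError, OBODocument, OBOId

__all__ = [
    "IdSpaceRegistry",
    "registry_from_header",
    "obo_id_to_iri",
    "iri_to_obo_id",
    "OBO_REL_PREFIX",
    "OBO_REL_BASE_IRI",
    "FALLBACK_BASE_IRI",
    "UNDEFINED_MARKER",
    "default_base_for",
]

logger = logging.getLogger(__name__)

OBO_REL_PREFIX = "OBO_REL"
OBO_REL_BASE_IRI = "http://www.obofoundry.org/ro/ro.owl#"
FALLBACK_BASE_IRI = "http://purl.org/obo/owl/obo#"
UNDEFINED_MARKER = "UNDEFINED_"


@dataclass
class IdSpaceRegistry:
    """Prefix → base-IRI table plus the default base IRI.

    ``OBO_REL`` is implicitly present (Relations Ontology base) unless the
    document overrides it.  With ``strip_obo_rel_prefix`` the OBO_REL prefix
    is dropped from the IRI local name (``...ro.owl#part_of`` instead of the
    uniform ``...ro.owl#OBO_REL_part_of``).
    """

    mappings: dict[str, str] = field(default_factory=dict)
    default_base_iri: str = FALLBACK_BASE_IRI
    strip_obo_rel_prefix: bool = False

    def base_for(self, prefix: str) -> str | None:
        if prefix in self.mappings:
            return self.mappings[prefix]
        if prefix == OBO_REL_PREFIX:
            return OBO_REL_BASE_IRI
        return None

    def effective_mappings(self) -> dict[str, str]:
        out = {OBO_REL_PREFIX: OBO_REL_BASE_IRI}
        out.update(self.mappings)
        return out


def default_base_for(doc: OBODocument) -> str:
    """Default base IRI derived from the ``default-namespace`` header when
    present, else a fixed constant."""
    ns = doc.header_value("default-namespace")
    if ns:
        return f"http://purl.org/obo/owl/{ns}#"
    return FALLBACK_BASE_IRI


def registry_from_header(doc: OBODocument, default_base_iri: str | None = None) -> IdSpaceRegistry:
    """Build the registry from the document's ``idspace`` header clauses.

    Duplicate declarations for one prefix: the last one wins, with a
    warning.  Raises ``E_BAD_IDSPACE`` for clauses lacking a prefix or IRI
    (normally already rejected at parse time).
    """
    registry = IdSpaceRegistry(default_base_iri=default_base_iri or default_base_for(doc))
    for decl in doc.idspace_decls():
        if not decl.prefix or not decl.base_iri:
            raise OboError("E_BAD_IDSPACE", f"idspace clause lacks prefix or IRI: {decl!r}")
        if decl.prefix in registry.mappings:
            logger.warning(
                "duplicate idspace declaration for %r; last one wins (%s)",
                decl.prefix,
                decl.base_iri,
            )
        registry.mappings[decl.prefix] = decl.base_iri
    return registry


def obo_id_to_iri(registry: IdSpaceRegistry, oid: OBOId) -> str:
    """Map a well-formed OBO identifier to an IRI (total function)."""
    if oid.idspace is None:
        return f"{registry.default_base_iri}{UNDEFINED_MARKER}{oid.local}"
    base = registry.base_for(oid.idspace)
    if base is None:
        base = registry.default_base_iri
    if registry.strip_obo_rel_prefix and oid.idspace == OBO_REL_PREFIX:
        return f"{base}{oid.local}"
    return f"{base}{oid.idspace}_{oid.local}"


def iri_to_obo_id(registry: IdSpaceRegistry, iri: str) -> OBOId:
    """Invert :func:`obo_id_to_iri`: strip the longest matching base IRI,
    honour the ``UNDEFINED_`` flat-id marker, then split prefix and local
    part (longest registered prefix first, first ``_`` as fallback).

    Raises ``E_FOREIGN_IRI`` when neither a registered base nor the default
    base is a prefix of *iri*.
    """
    bases = set(registry.effective_mappings().values())
    bases.add(registry.default_base_iri)
    matched = None
    for base in sorted(bases, key=len, reverse=True):
        if iri.startswith(base):
            matched = base
            break
    if matched is None:
        raise OboError("E_FOREIGN_IRI", f"IRI {iri!r} is under no registered base IRI")
    local_name = iri[len(matched) :]
    if local_name.startswith(UNDEFINED_MARKER):
        return OBOId(local=local_name[len(UNDEFINED_MARKER) :])
    prefixes = sorted(registry.effective_mappings(), key=len, reverse=True)
    for prefix in prefixes:
        if local_name.startswith(prefix + "_"):
            return OBOId(idspace=prefix, local=local_name[len(prefix) + 1 :])
    if registry.strip_obo_rel_prefix and matched == OBO_REL_BASE_IRI:
        return OBOId(idspace=OBO_REL_PREFIX, local=local_name)
    cut = local_name.find("_")
    if cut > 0:
        return OBOId(idspace=local_name[:cut], local=local_name[cut + 1 :])
    return OBOId(local=local_name)
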