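"""Identifier ↔ IRI conversion."""

import random
import string

import pytest

from oboowl.ids import (
    FALLBACK_BASE_IRI,
    OBO_REL_BASE_IRI,
    IdSpaceRegistry,
    iri_to_obo_id,
    obo_id_to_iri,
    registry_from_header,
)
from oboowl.io import parse_obo
from oboowl.model import OboError, OBOId


class TestRegistry:
    def test_declared_idspace_is_registered(self, go_registry):
        assert go_registry.mappings == {"GO": "http://www.go.org/owl#"}

    def test_empty_header_has_obo_rel_and_default(self):
        registry = registry_from_header(parse_obo(""))
        assert registry.effective_mappings() == {"OBO_REL": OBO_REL_BASE_IRI}
        assert registry.default_base_iri == FALLBACK_BASE_IRI

    def test_default_base_derived_from_default_namespace(self):
        registry = registry_from_header(parse_obo("default-namespace: zebrafish_anatomy\n"))
        assert registry.default_base_iri == "http://purl.org/obo/owl/zebrafish_anatomy#"

    def test_two_declarations_preserve_order(self):
        registry = registry_from_header(
            parse_obo("idspace: GO http://go/#\nidspace: ZFA http://zfa/#\n")
        )
        assert list(registry.mappings) == ["GO", "ZFA"]

    def test_duplicate_prefix_last_wins(self):
        registry = registry_from_header(
            parse_obo("idspace: GO http://first/#\nidspace: GO http://second/#\n")
        )
        assert registry.mappings["GO"] == "http://second/#"

    def test_obo_rel_can_be_overridden(self):
        registry = registry_from_header(parse_obo("idspace: OBO_REL http://custom/#\n"))
        assert registry.base_for("OBO_REL") == "http://custom/#"


class TestForward:
    def test_registered_prefix(self, go_registry):
        assert (
            obo_id_to_iri(go_registry, OBOId(idspace="GO", local="0000001"))
            == "http://www.go.org/owl#GO_0000001"
        )

    def test_unregistered_prefix_uses_default_base(self, go_registry):
        assert (
            obo_id_to_iri(go_registry, OBOId(idspace="SO", local="0000001"))
            == go_registry.default_base_iri + "SO_0000001"
        )

    def test_flat_id_gets_undefined_marker(self, go_registry):
        assert (
            obo_id_to_iri(go_registry, OBOId(local="foo"))
            == go_registry.default_base_iri + "UNDEFINED_foo"
        )

    def test_obo_rel_maps_to_relations_ontology_base(self):
        registry = IdSpaceRegistry()
        assert (
            obo_id_to_iri(registry, OBOId(idspace="OBO_REL", local="part_of"))
            == OBO_REL_BASE_IRI + "OBO_REL_part_of"
        )

    def test_obo_rel_base_independent_of_other_header_content(self, go_registry):
        iri = obo_id_to_iri(go_registry, OBOId(idspace="OBO_REL", local="part_of"))
        assert iri.startswith(OBO_REL_BASE_IRI)


class TestReverse:
    def test_undefined_marker_restores_flat_id(self, go_registry):
        oid = iri_to_obo_id(go_registry, go_registry.default_base_iri + "UNDEFINED_foo")
        assert oid == OBOId(local="foo")

    def test_registered_base_inverts_printed_example(self, go_registry):
        assert iri_to_obo_id(go_registry, "http://www.go.org/owl#GO_0000001") == OBOId(
            idspace="GO", local="0000001"
        )

    def test_foreign_iri_rejected(self, go_registry):
        with pytest.raises(OboError, match="E_FOREIGN_IRI"):
            iri_to_obo_id(go_registry, "http://example.org/elsewhere#X_1")

    def test_multi_underscore_prefix_resolves_by_longest_match(self):
        registry = IdSpaceRegistry()
        iri = obo_id_to_iri(registry, OBOId(idspace="OBO_REL", local="part_of"))
        assert iri_to_obo_id(registry, iri) == OBOId(idspace="OBO_REL", local="part_of")


def _random_id(rng) -> OBOId:
    letters = string.ascii_uppercase
    local_alphabet = string.ascii_lowercase + string.digits + "_"
    kind = rng.random()
    local = "".join(rng.choice(local_alphabet) for _ in range(rng.randrange(1, 12)))
    if kind < 0.3:
        return OBOId(local=local)  # flat (may contain underscores)
    if kind < 0.6:
        return OBOId(idspace="GO", local=local)  # registered
    if kind < 0.8:
        return OBOId(idspace="OBO_REL", local=local)  # implicit registration
    prefix = "".join(rng.choice(letters) for _ in range(rng.randrange(1, 5)))
    return OBOId(idspace=prefix, local=local)  # unregistered, no underscore


def test_roundtrip_identity_on_seeded_random_ids(go_registry):
    rng = random.Random(42)
    for _ in range(1000):
        oid = _random_id(rng)
        assert iri_to_obo_id(go_registry, obo_id_to_iri(go_registry, oid)) == oid


def test_strip_obo_rel_prefix_switch_roundtrips():
    registry = IdSpaceRegistry(strip_obo_rel_prefix=True)
    oid = OBOId(idspace="OBO_REL", local="part_of")
    iri = obo_id_to_iri(registry, oid)
    assert iri == OBO_REL_BASE_IRI + "part_of"
    assert iri_to_obo_id(registry, iri) == oid
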