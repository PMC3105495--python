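# oboowl

Lossless roundtrip translation between the **OBO 1.2 flat-file format** and
**OWL-DL** (serialized as RDF/XML), for curators and tool builders who keep
biomedical ontologies (Gene Ontology–style anatomies, taxonomies,
phenotype vocabularies, …) in OBO but want to use Semantic Web tooling —
triple stores, SPARQL, DL reasoners — without losing the ability to come
back.

## The mapping

OBO constructs stratify into a layer cake mirroring the Semantic Web's:
**Core** (identifiers, ID spaces, relationship triples ↔ RDF),
**Vocabulary** (names, comments, `is_a`, domains/ranges ↔ RDF-S) and
**Ontology Extensions** (everything else ↔ OWL). The translation maps each
stratum onto its counterpart:

| OBO | OWL |
|---|---|
| `[Term]` | `owl:Class` |
| `[Typedef]` | object property (`owl:ObjectProperty`, or `owl:TransitiveProperty` / `owl:SymmetricProperty`) |
| `name`, `comment` | `rdfs:label`, `rdfs:comment` |
| `is_a` | `rdfs:subClassOf` / `rdfs:subPropertyOf` |
| `relationship: R T` | `rdfs:subClassOf [a owl:Restriction; owl:onProperty R; owl:someValuesFrom T]` |
| `domain`, `range`, `inverse_of` | `rdfs:domain`, `rdfs:range`, `owl:inverseOf` |
| `intersection_of`, `union_of`, `disjoint_from` | `owl:equivalentClass` over `owl:intersectionOf`/`owl:unionOf`; `owl:disjointWith` |
| `is_obsolete: true` | subclass of `oboInOwl:ObsoleteClass` / subproperty of `oboInOwl:ObsoleteProperty` |
| `def`, `synonym`, `subset`, … | reified `oboInOwl` annotations (`hasDefinition`, `hasExactSynonym`, `inSubset`, …) |

Identifiers cross the local/global gap via ID spaces: with
`idspace: GO http://www.go.org/owl#` declared, `GO:0000001` becomes
`http://www.go.org/owl#GO_0000001`; an undeclared prefix falls back to the
default base IRI, and a flat id `foo` becomes
`<default-base>UNDEFINED_foo` so its flatness survives the way back.
Relationship clauses get existential (`someValuesFrom`) semantics —
universal restrictions have no OBO counterpart and are rejected on the
return trip.

Because OBO is a strict subset of OWL-DL, the reverse translator doubles
as a validator: it checks that an OWL document edited elsewhere still lies
in the OBO-expressible subset (no `owl:allValuesFrom`, no OWL deprecation
vocabulary, no datatype properties, no punning, no complex class
expressions) and reports coded violations otherwise.

Losslessness is judged against a canonical form: stanza, clause and header
order (and cross-reference order inside a clause) are presentation, not
knowledge; everything else — identifiers included — must survive
`OBO → OWL → OBO` exactly.

## Worked example

```sh
$ oboowl make-fixture --terms 12 --typedefs 2 --seed 9 -o fixture.obo
wrote fixture.obo: 12 terms, 2 typedefs (seed 9)
$ oboowl obo2owl fixture.obo -o fixture.owl
wrote fixture.owl: 12 classes, 2 object properties
$ oboowl owl2obo fixture.owl -o back.obo
wrote back.obo: 12 terms, 2 typedefs
$ oboowl roundtrip fixture.obo
in: (12, 2)  owl: (12, 2)  out: (12, 2)  equal: True
$ oboowl stats fixture.obo
Terms: 12	Typedefs: 2	Classes: 12	Object Properties: 2	Roundtrip Terms: 12	Roundtrip Typedefs: 2
```

The `stats` row is the evaluation protocol: term/typedef counts of the
input, class/object-property counts of the OWL translation (excluding the
`oboInOwl` meta-vocabulary), and term/typedef counts after the roundtrip.
For a lossless translation all three pairs are equal, and `roundtrip`
additionally checks canonical structural equality clause by clause
(`equal: True`; any mismatch is listed with its line).

Other subcommands: `validate-obo` (structural OBO validation, e.g. an
obsolete term carrying `is_a` is an error) and `validate-owl`
(OBO-expressibility check, nonzero exit on violations). The same
functionality is available as a library (`oboowl.parse_obo`,
`oboowl.translate_document`, `oboowl.translate_graph`,
`oboowl.roundtrip_check`, …).

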