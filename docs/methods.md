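# Methods

This note records the model behind `oboowl`, the choices made where the
mapping between OBO 1.2 and OWL-DL is genuinely open, the numerical and
procedural conventions, what the synthetic-document generator does and
does not emulate, and the known limitations.

## The translation model

An OBO 1.2 document is a header of tag-value clauses followed by `[Term]`
and `[Typedef]` stanzas. The translator treats the format as three strata
mirroring the Semantic Web layer cake — Core (ids, ID spaces,
relationships ↔ RDF), Vocabulary (labels, comments, `is_a`,
domain/range ↔ RDF-S), Ontology Extensions (everything else ↔ OWL) — and
maps each construct onto the corresponding target-language construct. The
classification is exposed as `classify_tag`; `relationship` is listed in
the published table under both Core and Ontology Extensions, and the
function returns Core (the duplication is in the source table and is
documented rather than resolved). The table prints the definition tag as
"definition" while the flat-file tag is `def`; both spellings classify as
Vocabulary.

Losslessness is defined against a **canonical form** (`canonicalize`):
stanzas sort by (kind, id), clauses by a fixed tag order then by value,
header clauses by a fixed header-tag order, and order-free collections
inside a clause (dbxref lists, trailing-modifier maps) sort
lexicographically. Two documents are "the same knowledge" iff their
canonical forms are structurally equal; the roundtrip guarantee is
`owl2obo(obo2owl(D)) = canonicalize(D)`. Order had to be excluded from
the equality because RDF graphs are sets: multiple `hasDbXref` triples on
one annotation node carry no order, so xref order cannot survive any
triple-based encoding.

### Identifiers

The forward rules: a prefix declared by an `idspace` header clause
resolves to its base IRI (`GO:0000001` → `…#GO_0000001`); an undeclared
prefix resolves to the default base IRI; a flat id is prefixed with the
`UNDEFINED_` marker so the reverse direction can restore its flatness.
The `OBO_REL` ID space of the Relations Ontology is implicitly present in
every document so relation typedefs share IRIs across ontologies; its
base is `http://www.obofoundry.org/ro/ro.owl#` (the IRI is used as an XML
namespace, so a fragment separator is required). The reverse rules strip
the longest matching base IRI, honour `UNDEFINED_`, and split the local
name at the longest registered prefix, falling back to the first
underscore. Consequences:

* The map is exactly invertible on every id the generator can produce
  (verified over 1000 seeded random ids per run). Unregistered prefixes
  containing an underscore would defeat the first-underscore fallback;
  registered prefixes of any shape are safe (longest-prefix match).
* The prefix is kept inside the IRI local name uniformly, including
  `OBO_REL` (`…ro.owl#OBO_REL_part_of`); `IdSpaceRegistry(
  strip_obo_rel_prefix=True)` exposes the alternative (`…ro.owl#part_of`),
  which also roundtrips.
* The default base IRI is `http://purl.org/obo/owl/<default-namespace>#`
  when the header declares a default namespace, else a fixed constant
  (`…/obo#`); `--base-uri` overrides both.

The worked translation examples print a flat typedef id `part_of` as the
IRI `…#part_of`, which no single rule can reconcile with the flat-id
marker rule (`foo` → `…#UNDEFINED_foo`): dropping the marker would make
`…#part_of` reverse-split into `part:of`. This package treats the
identifier rules as normative everywhere, so the golden corpus
instantiates that IRI as `…#UNDEFINED_part_of`; the structure of the
fragments (property typing, labels, restriction shape, obsolescence
encoding) is reproduced verbatim.

### Ancillary annotations

To make the reverse direction self-contained, the forward translation
stores the base IRI (`oboInOwl:hasBaseIRI`) and the original `idspace`
declarations (`oboInOwl:hasIdSpace`) as ontology-node annotations; header
metadata (`format-version`, `date`, `saved-by`, …) becomes `oboInOwl`
annotations rather than `owl:versionInfo`-style constructs to avoid
colliding with OWL tooling semantics. A graph lacking the embedded
registry falls back to a caller-provided registry, then to the default
base with first-underscore splitting, which makes the tool usable on
foreign oboInOwl files.

### Choices where the mapping is open

* **Property typing.** A transitive typedef is emitted as an
  `owl:TransitiveProperty` typed node (likewise symmetric), with no
  redundant `owl:ObjectProperty` triple — the typed-node style of the
  worked examples; those OWL types entail object-property-hood. Entity
  counting and the reverse direction accept all three types as
  object-property declarations.
* **Synonyms and definitions** are reified: the annotation points to an
  anonymous node carrying `rdfs:label` (the text), optional
  `hasSynonymType`, and one `hasDbXref` literal per cross-reference.
  A bare-literal encoding would lose the xrefs. Scopes map to
  `hasExactSynonym` / `hasBroadSynonym` / `hasNarrowSynonym` /
  `hasRelatedSynonym`; an unscoped synonym uses plain `hasSynonym`.
* **Unknown tags** (and known tags whose value cannot be encoded
  structurally, e.g. `is_obsolete: false`, which OWL cannot distinguish
  from absence) are preserved as an annotation property named after the
  tag, under the oboInOwl namespace, whose literal is the clause's
  escaped OBO value text. The reverse direction re-parses that literal
  with the ordinary clause grammar, so even structured values survive.
  Strict mode turns unknown tags into errors instead.
* **Degenerate logical definitions** (a single `intersection_of` operand,
  fewer than two `union_of` operands) are not valid class expressions;
  they are preserved through the annotation fallback with a warning
  (error in strict mode).
* **`is_cyclic`** maps to a plain `xsd:boolean` annotation; it has no DL
  semantics, so no logical axiom is emitted. `transitive_over` likewise
  remains an annotation naming the target property IRI (OWL 1 has no
  property chains).
* **Obsolescence** uses the `oboInOwl:ObsoleteClass`/`ObsoleteProperty`
  helpers, never OWL deprecation, whose semantics differ; the validator
  rejects OWL deprecation on the way back. The helper class is declared
  in the output whenever obsolete content exists (as the worked example
  prints), which is why entity counts exclude the oboInOwl
  meta-vocabulary — otherwise the class count would exceed the term
  count by one.
* **Stanza kinds** other than `[Term]`/`[Typedef]` (e.g. `[Instance]`)
  are rejected with `E_BAD_STANZA`: only terms and typedefs have a place
  in the mapping.
* **Duplicate `idspace` declarations** for one prefix: the last wins,
  with a logged warning.
* **Header clause order** cannot be restored from a triple graph; the
  reverse direction emits canonical order, which the equality treats as
  presentation.

### Flat-file conventions

Input accepts LF and CRLF; output is LF, UTF-8. An unescaped `!` starts a
comment running to end of line; unescaped `{…}` at the end of the value
holds trailing modifiers. Both are captured losslessly by the OBO
parser/serializer (inline comments on their clause, full-line comments as
comment pseudo-clauses, modifiers as qualifier maps). The escape table
covers `\n \t \\ \" \: \, \{ \} \[ \] \!`; `escape_value` escapes every
escapable character (making it exactly invertible), while the serializer
escapes per context (e.g. colons only where they would split a tag or an
id). The synonym grammar is fixed as: quoted text, optional scope keyword
(`EXACT|BROAD|NARROW|RELATED`), optional synonym-type name, optional
bracketed xref list — the four scope names are standard; the grammar
around them is convention.

### The validator

`validate_subset` flags, with one code each: `owl:allValuesFrom`
restrictions (`E_ALLVALUES`), OWL deprecation vocabulary
(`E_DEPRECATION`), datatype-property declarations (`E_DATATYPE_PROP`),
class expressions beyond named classes / existential restrictions /
intersections and unions of those (`E_COMPLEX_CLASS`, checked positionally
under `subClassOf`, `equivalentClass` and `disjointWith`), one node typed
as both class and property or used as an individual (`E_PUNNING`), and
other OWL constructs with no OBO counterpart, e.g. functional properties
(`E_FOREIGN_CONSTRUCT`). The checks are designed to be sound with respect
to the reverse translator: an empty violation list guarantees
`translate_graph` succeeds, and every forward-translation output
validates clean by construction.

## Synthetic documents

`generate_document(FixtureParams)` is a pure function of its parameters
(seed included; all randomness flows through one `numpy` generator). It
emits a header with metadata, ID-space declarations, subset and
synonym-type definitions, then typedefs and terms covering: prefixed ids
in registered and unregistered ID spaces, `OBO_REL` ids, flat ids
(probability `p_flat_id`, default 0.05), definitions with dbxrefs
(`p_def`, default 0.6), scoped and typed synonyms (`p_synonym`, 0.3),
subsets, alt-ids, namespaces, comments, an acyclic `is_a` hierarchy
(each stanza attaches to a uniformly chosen earlier one), Poisson-many
relationship clauses (`mean_relationships`, 1.0), genus–differentia and
union/disjoint definitions (`p_logical`, 0.1), and obsolete stanzas
(`p_obsolete`, 0.05) that carry no relational clauses, per the
obsolescence rule. Ids follow the GO/ZFA style `PREFIX:0000000`.

The generator emulates the *construct inventory* of real OBO ontologies,
not their content: labels are synthetic tokens, the `is_a` topology is a
random recursive tree rather than a curated DAG with multiple parents,
and densities are stationary across the document. Passing the roundtrip
suite therefore demonstrates coverage of every supported construct and
scale, not fidelity on any particular curated ontology.

Problem sizes used by the test suite and the acceptance script: 500
documents of 3–30 terms and 0–3 typedefs for the roundtrip protocol
(every 25th additionally passing through RDF/XML text), and one GO-scale
document of 28,667 terms and 5 typedefs — the published evaluation shape —
with a moderately sparse clause profile (`p_def` 0.5, `p_synonym` 0.3,
`mean_relationships` 0.8, `p_logical` 0.02, `p_obsolete` 0.03), roughly
240k triples, chosen once as this package's stress profile.

## Known limitations

* Trailing modifiers and comments survive OBO parse/serialize but are
  *not* carried into the OWL encoding (warning; error in strict mode), so
  a document using them roundtrips through OBO text but not through OWL.
* `is_transitive: false` / `is_symmetric: false` / `is_obsolete: false`
  are indistinguishable from absence in the natural OWL encoding and are
  preserved via the annotation fallback instead of as types.
* Header-line trailing modifiers are parsed and dropped.
* No reasoning is performed over the output; DL conformance is structural
  (the validator's checks), not a proof-theoretic verification.
* General OWL→OBO conversion is out of scope: cardinality restrictions,
  nominals, complements and datatype reasoning are rejected, not
  approximated.
* Flat-id IRIs are unique only within one document's base IRI; the
  mapping enables the roundtrip but does not manufacture global
  uniqueness for flat identifiers.
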