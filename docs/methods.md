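# Methods

## The schema model

`fairschema` implements a three-level semantic metadata schema of the kind
used to harmonize next-generation sequencing (NGS) metadata across
healthcare and research institutes (the FAIR Genomes style):

1. **Root level** — schema metadata (name, description, version, date,
   authors, copyright, license) plus the *global lookup options*: the 16
   HL7 v3/FHIR null flavors (NoInformation … Trace) that express precisely
   *why* a value is missing.
2. **Module level** — logical partitions comparable to database tables or
   UML classes (e.g. *Personal*, *Clinical*, *Material*), each with a
   name, description and ontology annotation.
3. **Element level** — typed attributes with a name, description,
   ontology annotation and a value type.

Value types form a closed set: the scalars `String`, `Text`, `Integer`,
`Decimal`, `Boolean`, `Date`, `DateTime`; `ReferenceOne`/`ReferenceMany`
expressing cardinality towards another module (foreign keys,
relationally); and `LookupOne`/`LookupMany` drawing values from a
TSV-backed controlled vocabulary. Globals are injected automatically into
every `LookupOne`/`LookupMany` element, *appended after* the base list
(stable UI ordering); the `*_NoGlobals` variants suppress the injection.
A value collision between a base list and a global option is a validation
error, never a silent merge. Lookup lists are static copies;
runtime-refreshing ("dynamic") lists are a non-goal.

Lookup lists carry an optional `ofType` annotation giving the collective
semantic type of the options (e.g. a *Medication* element defined as
NCIT C459 whose options are collectively "ATC code", EDAM data_3103);
validation enforces that `ofType` stays distinct from the annotations of
the elements using the list.

Machine names (`technical_name`) are derived deterministically from
human-readable names — lower-cased first word, camel-cased word
boundaries, non-alphanumerics dropped ("Intended insert size" →
`intendedInsertSize`) — because EMX/EMX2 tables and RDF subjects need
stable identifiers and hand-maintained ones drift.

Validation is exhaustive rather than fail-fast: every violated invariant
is reported with a stable location path (`module:Clinical/element:…`,
`lookup:medication/option[2]`), and `ok` means zero error-severity
issues. Unreferenced lookup lists are a warning, not an error. Empty
descriptions are rejected at validation so downstream generators never
have to emit empty literals.

### Statistics conventions

Option counts exclude the global null flavors; a list reused by several
elements counts once per referencing element in the per-element sum and
once overall in the unique sum (so per-element − unique = Σ over reused
lists of (references−1)×size, which a brute-force oracle checks in the
tests). Only lists actually referenced by an element are counted.

## Bundle I/O

A bundle is a directory: `schema.yml`, `lookups/*.tsv` (columns
`value description codesystem code iri`, header case-insensitive, order
fixed) and optionally `terms/*.rdf`. Everything is UTF-8 with LF
endings. TSV fields may not contain tabs or newlines — the format defines
no quoting dialect, so violations are rejected rather than escaped; for
the same reason the TSV reader/writer is a dozen lines of split/join
rather than a `csv` dialect that would silently interpret quotes.
Lookup files are named `<listname>.tsv` with lower-case/underscore names.
`new-terms` is an optional root key carrying the minted-term definitions
so that write→parse is the identity for every schema; round-trip identity
is property-tested over 100 seeds.

## The generator framework

All eight output targets implement one contract: `produce(schema)`
returns `(relative path, bytes)` pairs, is a pure function of the schema
(no clock, no randomness, LF endings, sorted unique paths), and runs only
after validation passes. Re-running is therefore byte-identical and the
manifest (per-file size + SHA-256) digest-stable, which makes generated
trees diffable and safe to regenerate on every schema change. The runner
records what it wrote in a dot-file manifest inside the output directory
and refuses to overwrite any colliding file of foreign origin. The only
date ever emitted is the schema's own `date` field.

## EDC blueprints

**EMX.** The package namespace derives from the schema name
(`fair-genomes`). Import proceeds in three stages — lookup-table
definitions, lookup data, module definitions — because references must
exist before they are used. Circular module references admit no import
order, so cycle-closing reference columns are split into a standalone
patch (`deferred_references.tsv`: entity/attribute/refEntity) applied
after the main import. The deferral rule is greedy and deterministic:
modules import in schema order whenever their dependencies are satisfied;
at a deadlock the first blocked module's missing dependency imports first
and that dependency's own unsatisfied back-references are deferred (in a
Clinical→Material→Clinical cycle, *Material used in diagnosis* stays in
the main definitions and *Belongs to diagnosis* moves to the patch). The
resulting main order is a verified topological order of the non-deferred
graph. Lookup data tables materialize the element-effective options: base
rows, with the 16 globals appended when any referencing element injects
them — a table referenced only by `*_NoGlobals` elements contains exactly
its base rows.

**EMX2.** One `molgenis.csv` defines every module and lookup table; each
table and element row carries its ontology IRI in the `semantics` column,
enabling semantic tagging of records. One CSV of lookup values per unique
list accompanies it; `emx2_zip_bytes` packs the set into an importable
ZIP with fixed timestamps so even the archive is byte-stable.

Column dialects are this package's own, chosen to be minimal and
self-describing (`entity, attribute, dataType, refEntity, description,
ontologyTermIRI`; data rows `value, label, codesystem, code, iri`);
byte-compatibility with any specific MOLGENIS release is a non-goal.

**Codebook.** `INFO.tsv` (name/version/date/description),
`CODEBOOK.tsv` (one row per element, module-major, with type and
ontology reference) and the lookup lists re-headered with
language-suffixed columns (`value_en`, `description_en`) ready for
multi-language extension.

**ART-DECOR.** A simplified dataset rendering — `dataset`, a group
`concept` per module, an item `concept` per element (names and
descriptions tagged `en-US`), a `valueSet` per unique lookup list — with
ids derived from the project OID (default
`2.16.840.1.113883.2.4.3.11.60.120`) plus running indices. The full
DECOR XSD is deliberately out of scope; the output is well-formed XML
meant as an exchange skeleton.

## Application ontology and minted terms

Modules become `owl:Class` (4 triples: type, `rdfs:label`,
`dc:description`, `rdfs:isDefinedBy`) and elements `owl:DatatypeProperty`
(6 triples: type, label, `rdfs:domain`, `rdfs:isDefinedBy`,
`dc:description`, `rdfs:range`), so the core Turtle file carries exactly
`4·m + 6·n` triples — an arithmetic identity the tests verify by
re-parsing the emitted Turtle with rdflib. `dc:` is the Dublin Core
`/terms/` namespace. Scalar ranges map to XSD datatypes; reference
ranges point at the target module's class; lookup ranges at the list's
`ofType` IRI (or, when absent, the list's own minted IRI — a documented
fallback). Each unique lookup list gets its own Turtle file (options: 4
triples each — type via `ofType`, label, description, `isDefinedBy`
pointing at the option's source-ontology IRI); the globals live in a
separate `nullflavors.ttl` that is not counted among the per-list files.

Subjects are always minted under the configurable W3ID-style namespace
(default `https://w3id.org/fair-genomes/resource`) from technical names;
imported ontology IRIs (NCIT, DUO, EDAM, HPO, …) appear only as
`rdfs:isDefinedBy` objects, never as subjects, so their meaning is never
altered. New terms carry `FG_` + seven-digit accessions;
`mint_iri("FG_0000001")` →
`https://w3id.org/fair-genomes/resource/FG_0000001`. Each term is one
RDF-XML fragment: element-kind terms carry type, label, `isDefinedBy`,
`domain`, description and `dc:identifier` (the accession); lookup-kind
terms the same minus the domain. The format prescribes the predicate
set but no `rdf:type` object, so element-terms are typed
`owl:DatatypeProperty` and lookup-terms `owl:NamedIndividual`. All RDF outputs re-parse
graph-isomorphically, including Turtle→RDF-XML conversion.

## Documentation outputs

Markdown (CommonMark, pipe tables): summary statistics exactly equal to
`compute_statistics`, a linked module index with GitHub-style anchors,
one table row per element hyperlinking the annotation IRI and the lookup
TSV. Lookup lists are always linked, never inlined, so a 19k-row gene
list cannot bloat the document. LaTeX: `article` class, UTF-8 input
encoding and no other packages, one `table`/`tabular` per module, all
specials (`# $ % & _ { } ~ ^ \`) escaped; compiles with a stock
latex→dvips→ps2pdf chain (PDF production stays in the user's toolchain).

## Synthetic fixtures

`make_mini_schema()` is the deterministic desk-scale fixture: the nine
v1.1 module names (Study … Analysis), the 16 null flavors as globals, a
3-option *RepresentedBy* list, an ATC-typed *Medication* list, a
phenotype list shared by *Phenotype* and *Unobserved phenotype*,
Clinical↔Material and Study↔Personal circular references, *Valid
from*/*Valid until* consent dates, and four minted FG terms (the three
documented element-terms plus one synthetic lookup-term so the
no-domain fragment shape is exercised). Filler elements are named
`SyntheticElementNN` so nothing invented masquerades as real FAIR
Genomes content; placeholder lookup options are likewise labelled
synthetic. It does **not** reproduce the full release (110 elements,
85,307 options), so passing tests demonstrate structural and contractual
correctness, not content fidelity to the published standard; the
optional release-conformance test covers that when a converted v1.1
bundle is supplied.

`make_random_schema(seed, …)` produces seeded, always-valid schemas:
defaults (4 modules × 4 elements, 3 lookup lists of 2–6 options,
reference probability 0.25, lookup probability 0.3, globals on) are
desk-scale sizes chosen so that lookup reuse, `*_NoGlobals` variants and
reference cycles all occur regularly across seeds while a 100-seed
property run stays in seconds. Every generated list is referenced by at
least one element (so write→parse round-trips are exact), and infeasible
parameter combinations are rejected.

## Numerical and tie-break choices

- Cycle reporting rotates each cycle to start at its lexicographically
  smallest module and sorts the cycle list — deterministic output for
  golden comparisons.
- Statistics min/max lists break size ties lexicographically.
- Multi-valued lookup data serializes as comma-separated strings, so
  option values used by `LookupMany*` elements may not contain commas
  (validated).
- Manifest digests are SHA-256 over a canonical JSON rendering.

## Known limitations

- The YAML key spellings are this package's declared dialect; bundles
  authored for other toolchains need a one-time key mapping.
- ART-DECOR output is a simplified dataset skeleton, not a full DECOR
  instance.
- Only static lookup lists are supported; SKOS cross-version mappings
  and data-value temporality/audit history are out of scope.
- LODE/HTML rendering of the ontology and fragments is left to external
  services; the core Turtle is kept LODE-consumable (plain classes and
  datatype properties, one namespace, language-tagged literals).
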