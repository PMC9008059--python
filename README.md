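# fairschema

A toolkit for three-level semantic metadata schemas of the kind used to
harmonize next-generation sequencing (NGS) metadata in healthcare and
research — the FAIR Genomes style. A schema bundle (one YAML file plus
TSV controlled-vocabulary lookup lists) describes *root* metadata with
HL7 null flavors as global lookup options, *modules* (logical partitions
such as Personal, Clinical, Material) and *elements* (typed,
ontology-annotated attributes). From one bundle, `fairschema`
deterministically generates everything a heterogeneous IT landscape
needs to capture interoperable data "at the source":

| Target | Output |
| --- | --- |
| `emx` | MOLGENIS-EMX blueprint with a three-stage import order and a deferred patch for circular references |
| `emx2` | MOLGENIS-EMX2 `molgenis.csv` (+ one CSV per lookup list) with ontology IRIs in the `semantics` column |
| `codebook` | `INFO.tsv`, `CODEBOOK.tsv` and language-suffixed lookup TSVs |
| `artdecor` | simplified ART-DECOR dataset/valueSet XML under a dotted-decimal project OID |
| `ontology` | application ontology in Turtle: modules as `owl:Class` (4 triples each), elements as `owl:DatatypeProperty` (6 triples each), one TTL per unique lookup list |
| `terms` | RDF-XML fragments for newly minted `FG_…` terms under a W3ID-style namespace |
| `markdown`, `latex` | human-readable documentation |

The model enforces the format's core semantics: lookup elements
automatically gain the 16 HL7 null flavors (unless declared
`*_NoGlobals`), `ofType` keeps a lookup list's collective type separate
from the element's own definition, reference elements may form cycles
that the relational blueprints must defer, and every module/element/
option carries a resolvable ontology IRI. Generation is a pure function
of the schema: two runs produce byte-identical files, so all targets
stay synchronized by construction.

## Worked example

Write the built-in desk-scale schema (nine modules following the FAIR
Genomes v1.1 layout) to disk and inspect it:

```python
from fairschema.fixtures import make_mini_schema
from fairschema.io import write_bundle

write_bundle(make_mini_schema(), "demo/bundle")
```

```
$ fairschema stats demo/bundle
modules: 9
elements: 24
lookup elements: 5
unique lookup lists: 4
lookup options per element (sum): 20
unique lookup options: 15
smallest list: inclusion_criteria (3)
largest list: phenotypes (5)
new terms: 4
```

Nine modules hold 24 elements; five of them draw values from four unique
lookup lists (the phenotype list is shared by two elements, which is why
the per-element sum, 20, exceeds the unique sum, 15 — null flavors are
excluded from both). Generate the ontology and the EMX blueprint:

```
$ fairschema generate demo/bundle --targets ontology,emx --out demo/out
$ ls demo/out/ontology
fair-genomes.ttl  inclusion_criteria.ttl  medication.ttl
nullflavors.ttl   phenotypes.ttl          represented_by.ttl
```

`fair-genomes.ttl` holds 4·9 + 6·24 = 180 triples, e.g.:

```turtle
<https://w3id.org/fair-genomes/resource/analysis/percentageTr20> a owl:DatatypeProperty ;
    rdfs:label "Percentage TR20"@en ;
    dc:description "Percentage of target regions covered at least 20-fold."@en ;
    rdfs:domain <https://w3id.org/fair-genomes/resource/analysis> ;
    rdfs:isDefinedBy <https://w3id.org/fair-genomes/resource/FG_0000003> ;
    rdfs:range xsd:decimal .
```

The subject is minted under the W3ID namespace; the imported ontology
IRI appears only as `rdfs:isDefinedBy`, never as a subject. In
`demo/out/emx`, `import_order.txt` lists a verified topological import
(lookup definitions → lookup data → module definitions), and
`deferred_references.tsv` carries the two cycle-closing columns
(Personal→Study and Material→Clinical) to be patched in after import.

`fairschema validate demo/bundle` exits 0 on a clean bundle, 1 with a
`severity<TAB>path<TAB>message` report on a broken one, and 2 when the
bundle is unreadable.

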