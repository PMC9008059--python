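"""Synthetic schema construction.

``make_mini_schema`` builds a desk-scale nine-module schema following the
FAIR Genomes v1.1 module layout (Study through Analysis) with the
documented structural features: the 16 HL7 null flavors as root-level
global lookup options, lookup reuse, two circular module references, an
ofType-typed medication list and three newly minted FG terms. Elements
beyond the documented ones carry clearly synthetic names so none of the
filler masquerades as real FAIR Genomes content.

``make_random_schema`` produces seeded, always-valid schemas for property
tests.
"""

from __future__ import annotations

import random

from fairschema.model import (
    Element,
    LookupList,
    LookupOption,
    OntologyAnnotation,
    SchemaModule,
    SemanticSchema,
    TermDefinition,
    ValueType,
)

__all__ = ["make_null_flavors", "make_mini_schema", "make_random_schema", "MINI_MODULE_NAMES"]

# HL7 v3 NullFlavor code system: name, code, short description.
_NULL_FLAVORS = [
    ("NoInformation", "NI", "No information whatsoever can be inferred."),
    ("Invalid", "INV", "The value as represented in the instance is not a member of the set of permitted data values."),
    ("Derived", "DER", "An actual value may exist, but it must be derived from the provided information."),
    ("Other", "OTH", "The actual value is not a member of the set of permitted data values."),
    ("Negative infinity", "NINF", "Negative infinity of numbers."),
    ("Positive infinity", "PINF", "Positive infinity of numbers."),
    ("Un-encoded", "UNC", "The actual value has not yet been encoded within the constraints of the coding system."),
    ("Masked", "MSK", "There is information on this item available but it has not been provided for reasons of security or privacy."),
    ("Not applicable", "NA", "No proper value is applicable in this context."),
    ("Unknown", "UNK", "A proper value is applicable, but not known."),
    ("Asked but unknown", "ASKU", "Information was sought but not found."),
    ("Temporarily unavailable", "NAV", "Information is not available at this time but is expected to be available later."),
    ("Not asked", "NASK", "This information has not been sought."),
    ("Not available", "NAVU", "Information is not available at this time; it is unknown if it will ever be available."),
    ("Sufficient quantity", "QS", "The specific quantity is not known, but is known to be non-zero and not specified."),
    ("Trace", "TRC", "The content is greater than zero, but too small to be quantified."),
]

_NULLFLAVOR_IRI_BASE = "https://www.hl7.org/fhir/v3/NullFlavor/cs.html"


def make_null_flavors() -> list[LookupOption]:
    """The 16 HL7 null flavors as global lookup options, in canonical order
    (NoInformation first, Trace last)."""
    return [
        LookupOption(
            value=name,
            description=desc,
            codesystem="NULLFLAVOR",
            code=code,
            iri=f"{_NULLFLAVOR_IRI_BASE}#{code}",
            is_global=True,
        )
        for name, code, desc in _NULL_FLAVORS
    ]


MINI_MODULE_NAMES = [
    "Study",
    "Personal",
    "Leaflet and consent form",
    "Individual consent",
    "Clinical",
    "Material",
    "Sample preparation",
    "Sequencing",
    "Analysis",
]

_FG_NS = "https://w3id.org/fair-genomes/resource"


def _syn_ann(code: int, label: str | None = None) -> OntologyAnnotation:
    """A clearly synthetic NCIT-style annotation with a unique IRI."""
    return OntologyAnnotation(
        codesystem="NCIT",
        code=f"C9{code:05d}",
        iri=f"http://purl.obolibrary.org/obo/NCIT_C9{code:05d}",
        label=label,
    )


def _syn_element(n: int, value_type: ValueType = ValueType.String) -> Element:
    return Element(
        name=f"SyntheticElement{n:02d}",
        description=f"Synthetic filler element number {n:02d}.",
        annotation=_syn_ann(500 + n),
        value_type=value_type,
    )


def make_mini_schema() -> SemanticSchema:
    """A deterministic desk-scale schema with the FAIR Genomes v1.1 module
    layout and structural features; always passes validation."""
    schema = SemanticSchema(
        name="FAIR Genomes",
        description="Metadata schema promoting NGS data reuse in healthcare and research (desk-scale synthetic rendition).",
        version="1.1",
        date="2021-07-20",
        authors=["FAIR Genomes consortium"],
        copyright="FAIR Genomes consortium",
        license="CC-BY-4.0",
        global_lookup_options=make_null_flavors(),
    )

    schema.lookup_lists["represented_by"] = LookupList(
        name="represented_by",
        options=[
            LookupOption(
                value=v,
                description=f"Synthetic representation option: {v}.",
                codesystem="NCIT",
                code=f"C9{400 + i:05d}",
                iri=f"http://purl.obolibrary.org/obo/NCIT_C9{400 + i:05d}",
            )
            for i, v in enumerate(["Self", "Legal guardian", "Authorized representative"])
        ],
    )
    schema.lookup_lists["inclusion_criteria"] = LookupList(
        name="inclusion_criteria",
        options=[
            LookupOption(
                value=v,
                description=f"Synthetic inclusion criterion: {v}.",
                codesystem="OBI",
                code=f"00014{i:02d}",
                iri=f"http://purl.obolibrary.org/obo/OBI_00014{i:02d}",
            )
            for i, v in enumerate(["Clinical diagnosis", "Family member", "Population control"])
        ],
    )
    schema.lookup_lists["phenotypes"] = LookupList(
        name="phenotypes",
        options=[
            LookupOption(
                value=v,
                description=f"Synthetic phenotypic abnormality: {v}.",
                codesystem="HPO",
                code=f"HP:00000{i:02d}",
                iri=f"http://purl.obolibrary.org/obo/HP_00000{i:02d}",
            )
            for i, v in enumerate(
                ["Synthetic phenotype A", "Synthetic phenotype B", "Synthetic phenotype C",
                 "Synthetic phenotype D", "Synthetic phenotype E"], start=1
            )
        ],
    )
    schema.lookup_lists["medication"] = LookupList(
        name="medication",
        options=[
            LookupOption(
                value=v,
                description=f"Synthetic ATC medication group: {v}.",
                codesystem="ATC",
                code=code,
                iri=f"https://www.whocc.no/atc_ddd_index/?code={code}",
            )
            for v, code in [
                ("Synthetic drug alpha", "A01AA01"),
                ("Synthetic drug beta", "B01AB02"),
                ("Synthetic drug gamma", "C01CA03"),
                ("Synthetic drug delta", "D01DD04"),
            ]
        ],
        of_type=OntologyAnnotation(
            codesystem="EDAM",
            code="data_3103",
            iri="http://edamontology.org/data_3103",
            label="ATC code",
        ),
    )

    def module(name: str, code: int, elements: list[Element]) -> None:
        schema.modules.append(
            SchemaModule(
                name=name,
                description=f"The {name} module of the schema.",
                annotation=_syn_ann(100 + code, label=name),
                elements=elements,
            )
        )

    module("Study", 1, [
        Element("Study acronym", "Short study identifier.", _syn_ann(201), ValueType.String),
        Element("People in study", "People participating in this study.",
                _syn_ann(202), ValueType.ReferenceMany, reference_target="Personal"),
        Element("Inclusion criteria", "Criterion for enrolment into the study.",
                _syn_ann(203), ValueType.LookupOne_NoGlobals, lookup_ref="inclusion_criteria"),
    ])
    module("Personal", 2, [
        Element("Date of birth", "Date of birth of the individual.", _syn_ann(204), ValueType.Date),
        Element("Part of studies", "Studies this person participates in.",
                _syn_ann(205), ValueType.ReferenceMany, reference_target="Study"),
        Element("RepresentedBy", "Person legally representing the individual.",
                _syn_ann(206), ValueType.LookupOne, lookup_ref="represented_by"),
    ])
    module("Leaflet and consent form", 3, [
        Element("Leaflet version", "Version of the information leaflet.", _syn_ann(207), ValueType.String),
        _syn_element(1),
    ])
    module("Individual consent", 4, [
        Element("Valid from", "Date from which the consent is valid.", _syn_ann(208), ValueType.Date),
        Element("Valid until", "Date until which the consent is valid.", _syn_ann(209), ValueType.Date),
        Element("Consent form used", "The leaflet and consent form that was signed.",
                _syn_ann(210), ValueType.ReferenceOne, reference_target="Leaflet and consent form"),
    ])
    module("Clinical", 5, [
        Element("Phenotype", "Observed phenotypic abnormality.",
                _syn_ann(211), ValueType.LookupMany, lookup_ref="phenotypes"),
        Element("Unobserved phenotype", "Phenotypic abnormality explicitly ruled out.",
                _syn_ann(212), ValueType.LookupMany, lookup_ref="phenotypes"),
        Element("Medication", "Medication taken by the individual.",
                OntologyAnnotation("NCIT", "C459", "http://purl.obolibrary.org/obo/NCIT_C459", "Medication"),
                ValueType.LookupMany, lookup_ref="medication"),
        Element("Material used in diagnosis", "Sampled materials this diagnosis is based on.",
                _syn_ann(213), ValueType.ReferenceMany, reference_target="Material"),
    ])
    module("Material", 6, [
        Element("Sampling date", "Date the material was sampled.", _syn_ann(214), ValueType.Date),
        Element("Belongs to diagnosis", "Diagnoses established using this material.",
                _syn_ann(215), ValueType.ReferenceMany, reference_target="Clinical"),
    ])
    module("Sample preparation", 7, [
        Element("Input material", "Material this preparation was performed on.",
                _syn_ann(216), ValueType.ReferenceOne, reference_target="Material"),
        _syn_element(2),
    ])
    module("Sequencing", 8, [
        Element("Prepared sample", "The prepared sample that was sequenced.",
                _syn_ann(217), ValueType.ReferenceOne, reference_target="Sample preparation"),
        Element("Intended insert size", "Insert size the library preparation aimed for, in base pairs.",
                OntologyAnnotation("FG", "FG_0000001", f"{_FG_NS}/FG_0000001", "Intended insert size"),
                ValueType.Integer),
        Element("Observed insert size", "Insert size observed after sequencing, in base pairs.",
                OntologyAnnotation("FG", "FG_0000002", f"{_FG_NS}/FG_0000002", "Observed insert size"),
                ValueType.Integer),
    ])
    module("Analysis", 9, [
        Element("Sequencing run", "The sequencing run this analysis is based on.",
                _syn_ann(218), ValueType.ReferenceOne, reference_target="Sequencing"),
        Element("Percentage TR20", "Percentage of target regions covered at least 20-fold.",
                OntologyAnnotation("FG", "FG_0000003", f"{_FG_NS}/FG_0000003", "Percentage TR20"),
                ValueType.Decimal),
    ])

    schema.term_definitions = [
        TermDefinition("FG_0000001", "Intended insert size",
                       "Insert size the library preparation aimed for, in base pairs.",
                       "element-term", domain_module="Sequencing"),
        TermDefinition("FG_0000002", "Observed insert size",
                       "Insert size observed after sequencing, in base pairs.",
                       "element-term", domain_module="Sequencing"),
        TermDefinition("FG_0000003", "Percentage TR20",
                       "Percentage of target regions covered at least 20-fold.",
                       "element-term", domain_module="Analysis"),
        TermDefinition("FG_0000004", "Synthetic sequencer model X1",
                       "A synthetic sequencing instrument model lookup value.",
                       "lookup-term"),
    ]
    return schema


_SCALAR_TYPES = [
    ValueType.String,
    ValueType.Text,
    ValueType.Integer,
    ValueType.Decimal,
    ValueType.Boolean,
    ValueType.Date,
    ValueType.DateTime,
]
_LOOKUP_TYPES = [
    ValueType.LookupOne,
    ValueType.LookupMany,
    ValueType.LookupOne_NoGlobals,
    ValueType.LookupMany_NoGlobals,
]


def make_random_schema(
    seed: int,
    n_modules: int = 4,
    n_elements_per_module: int = 4,
    n_lookup_lists: int = 3,
    list_size_range: tuple[int, int] = (2, 6),
    p_reference: float = 0.25,
    p_lookup: float = 0.3,
    with_globals: bool = True,
) -> SemanticSchema:
    """A seeded random schema that always passes validation.

    Same seed, same schema (bit-stable). Every generated lookup list is
    referenced by at least one element; reference elements may induce
    cycles with probability governed by ``p_reference``.
    """
    if n_modules < 1 or n_elements_per_module < 1 or n_lookup_lists < 0:
        raise ValueError("sizes must be positive")
    if not (0 <= p_reference <= 1 and 0 <= p_lookup <= 1):
        raise ValueError("probabilities must be in [0, 1]")
    if p_lookup > 0 and n_lookup_lists == 0:
        raise ValueError("p_lookup > 0 requires at least one lookup list")
    if n_lookup_lists > 0 and (p_lookup == 0 or n_modules * n_elements_per_module < n_lookup_lists):
        raise ValueError("not enough lookup elements to reference every list")
    lo, hi = list_size_range
    if lo < 1 or hi < lo:
        raise ValueError("bad list size range")

    rng = random.Random(seed)
    schema = SemanticSchema(
        name=f"Random schema {seed}",
        description=f"Randomized synthetic schema for property tests (seed {seed}).",
        version="0.1",
        date="2021-07-20",
        authors=["fixture generator"],
        copyright="none",
        license="CC0-1.0",
        global_lookup_options=make_null_flavors() if with_globals else [],
    )

    iri_seq = iter(range(10**6))

    def ann() -> OntologyAnnotation:
        n = next(iri_seq)
        return OntologyAnnotation("SYN", f"S{n:06d}", f"https://example.org/syn/S{n:06d}")

    for li in range(n_lookup_lists):
        size = rng.randint(lo, hi)
        schema.lookup_lists[f"list_{li:02d}"] = LookupList(
            name=f"list_{li:02d}",
            options=[
                LookupOption(
                    value=f"Option {li:02d}.{oi:03d}",
                    description=f"Synthetic option {oi:03d} of list {li:02d}.",
                    codesystem="SYN",
                    code=f"L{li:02d}O{oi:03d}",
                    iri=f"https://example.org/syn/L{li:02d}O{oi:03d}",
                )
                for oi in range(size)
            ],
        )

    module_names = [f"Module {mi:02d}" for mi in range(n_modules)]
    # Decide element kinds first so every lookup list gets at least one user.
    slots = [(mi, ei) for mi in range(n_modules) for ei in range(n_elements_per_module)]
    lookup_slots = rng.sample(slots, n_lookup_lists) if n_lookup_lists else []
    assigned = {slot: f"list_{li:02d}" for li, slot in enumerate(lookup_slots)}

    for mi in range(n_modules):
        module = SchemaModule(
            name=module_names[mi],
            description=f"Synthetic module {mi:02d}.",
            annotation=ann(),
        )
        for ei in range(n_elements_per_module):
            name = f"Element {mi:02d}.{ei:02d}"
            desc = f"Synthetic element {ei:02d} of module {mi:02d}."
            slot = (mi, ei)
            r = rng.random()
            if slot in assigned:
                vt = rng.choice(_LOOKUP_TYPES)
                el = Element(name, desc, ann(), vt, lookup_ref=assigned[slot])
            elif r < p_reference and n_modules > 1:
                target = rng.choice([m for m in module_names if m != module_names[mi]])
                vt = rng.choice([ValueType.ReferenceOne, ValueType.ReferenceMany])
                el = Element(name, desc, ann(), vt, reference_target=target)
            elif n_lookup_lists and r < p_reference + p_lookup:
                vt = rng.choice(_LOOKUP_TYPES)
                el = Element(name, desc, ann(), vt, lookup_ref=rng.choice(sorted(schema.lookup_lists)))
            else:
                el = Element(name, desc, ann(), rng.choice(_SCALAR_TYPES))
            module.elements.append(el)
        schema.modules.append(module)
    return schema
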