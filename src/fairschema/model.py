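"""In-memory representation of a three-level semantic metadata schema.

The schema has a root level (name, version, authors, ... plus the global
lookup options used for HL7 null flavors), a module level (logical
partitions comparable to database tables or UML classes) and an element
level (typed attributes). Elements may point at other modules through
reference value types (cardinality, i.e. foreign keys) or at controlled
vocabularies through lookup value types.

Everything here is pure and I/O-free; reading and writing bundles lives in
:mod:`fairschema.io`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

import networkx as nx

__all__ = [
    "ValueType",
    "OntologyAnnotation",
    "LookupOption",
    "LookupList",
    "Element",
    "SchemaModule",
    "TermDefinition",
    "SemanticSchema",
    "SchemaStatistics",
    "ValidationIssue",
    "ValidationReport",
    "validate",
    "effective_options",
    "reference_graph",
    "compute_statistics",
    "to_technical_name",
]

ACCESSION_RE = re.compile(r"^FG_\d{7}$")
_IRI_RE = re.compile(r"^https?://\S+$")


class ValueType(str, Enum):
    """Closed vocabulary of element value types.

    ``ReferenceOne``/``ReferenceMany`` express cardinality towards another
    module; ``LookupOne``/``LookupMany`` draw the value from a controlled
    vocabulary and automatically gain the schema's global lookup options
    (null flavors); the ``*_NoGlobals`` variants suppress that injection.
    """

    String = "String"
    Text = "Text"
    Integer = "Integer"
    Decimal = "Decimal"
    Boolean = "Boolean"
    Date = "Date"
    DateTime = "DateTime"
    ReferenceOne = "ReferenceOne"
    ReferenceMany = "ReferenceMany"
    LookupOne = "LookupOne"
    LookupMany = "LookupMany"
    LookupOne_NoGlobals = "LookupOne_NoGlobals"
    LookupMany_NoGlobals = "LookupMany_NoGlobals"

    @property
    def is_reference(self) -> bool:
        return self in (ValueType.ReferenceOne, ValueType.ReferenceMany)

    @property
    def is_lookup(self) -> bool:
        return self in (
            ValueType.LookupOne,
            ValueType.LookupMany,
            ValueType.LookupOne_NoGlobals,
            ValueType.LookupMany_NoGlobals,
        )

    @property
    def includes_globals(self) -> bool:
        """True if global lookup options are injected for this type."""
        return self in (ValueType.LookupOne, ValueType.LookupMany)

    @property
    def is_multi_valued(self) -> bool:
        return self in (
            ValueType.ReferenceMany,
            ValueType.LookupMany,
            ValueType.LookupMany_NoGlobals,
        )


def to_technical_name(name: str) -> str:
    """Derive a machine name from a human-readable name.

    Lower-cases the first word and camel-cases subsequent word boundaries,
    dropping any character that is not alphanumeric:
    ``"Intended insert size"`` -> ``"intendedInsertSize"``.
    """
    words = re.findall(r"[0-9A-Za-z]+", name)
    if not words:
        return ""
    head = words[0].lower()
    tail = [w[:1].upper() + w[1:].lower() for w in words[1:]]
    return head + "".join(tail)


@dataclass
class OntologyAnnotation:
    """A pointer into a code system: short label, code and resolvable IRI."""

    codesystem: str
    code: str
    iri: str
    label: str | None = None


@dataclass
class LookupOption:
    """One selectable row of a controlled vocabulary.

    ``is_global`` marks root-level options (null flavors) that are injected
    into every globals-including lookup element.
    """

    value: str
    description: str
    codesystem: str
    code: str
    iri: str
    is_global: bool = False


@dataclass
class LookupList:
    """A TSV-backed controlled vocabulary.

    ``of_type`` gives the collective semantic type of the options (e.g. a
    medication list whose rows are collectively "ATC code"), kept separate
    from the annotation of the elements that use the list.
    """

    name: str
    options: list[LookupOption] = field(default_factory=list)
    of_type: OntologyAnnotation | None = None


@dataclass
class Element:
    name: str
    description: str
    annotation: OntologyAnnotation
    value_type: ValueType
    reference_target: str | None = None
    lookup_ref: str | None = None

    @property
    def technical_name(self) -> str:
        return to_technical_name(self.name)


@dataclass
class SchemaModule:
    name: str
    description: str
    annotation: OntologyAnnotation
    elements: list[Element] = field(default_factory=list)

    @property
    def technical_name(self) -> str:
        return to_technical_name(self.name)


@dataclass
class TermDefinition:
    """A newly minted ontology term (FG accession).

    ``kind`` is ``"element-term"`` for terms defining new schema elements
    (these carry an ``rdfs:domain`` pointing at their module) or
    ``"lookup-term"`` for new controlled-vocabulary values.
    """

    accession: str
    label: str
    description: str
    kind: str
    domain_module: str | None = None

    @property
    def identifier(self) -> str:
        """The accession repeated as the dc:identifier payload."""
        return self.accession


@dataclass
class SemanticSchema:
    name: str
    description: str
    version: str
    date: str
    authors: list[str] = field(default_factory=list)
    copyright: str = ""
    license: str = ""
    global_lookup_options: list[LookupOption] = field(default_factory=list)
    modules: list[SchemaModule] = field(default_factory=list)
    lookup_lists: dict[str, LookupList] = field(default_factory=dict)
    term_definitions: list[TermDefinition] = field(default_factory=list)

    def iter_elements(self) -> Iterator[tuple[SchemaModule, Element]]:
        for module in self.modules:
            for element in module.elements:
                yield module, element

    def module(self, name: str) -> SchemaModule:
        for m in self.modules:
            if m.name == name:
                return m
        raise KeyError(name)

    def referenced_lookup_names(self) -> list[str]:
        """Names of lookup lists referenced by at least one element, in
        first-reference order."""
        seen: list[str] = []
        for _, el in self.iter_elements():
            if el.lookup_ref and el.lookup_ref not in seen:
                seen.append(el.lookup_ref)
        return seen


@dataclass
class SchemaStatistics:
    """Summary counts over one schema.

    Option counts exclude the global (null-flavor) options; a list reused
    by several elements is counted once per referencing element in
    ``total_lookup_options_per_element_sum`` and once overall in
    ``total_unique_lookup_options``.
    """

    n_modules: int
    n_elements: int
    n_lookup_elements: int
    n_unique_lookup_lists: int
    total_lookup_options_per_element_sum: int
    total_unique_lookup_options: int
    min_list: tuple[str, int] | None
    max_list: tuple[str, int] | None
    n_new_terms: int

    def as_dict(self) -> dict:
        return {
            "n_modules": self.n_modules,
            "n_elements": self.n_elements,
            "n_lookup_elements": self.n_lookup_elements,
            "n_unique_lookup_lists": self.n_unique_lookup_lists,
            "total_lookup_options_per_element_sum": self.total_lookup_options_per_element_sum,
            "total_unique_lookup_options": self.total_unique_lookup_options,
            "min_list": list(self.min_list) if self.min_list else None,
            "max_list": list(self.max_list) if self.max_list else None,
            "n_new_terms": self.n_new_terms,
        }


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    path: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors


_TSV_UNSAFE = re.compile(r"[\t\n\r]")


def _check_annotation(
    ann: OntologyAnnotation, path: str, out: list[ValidationIssue]
) -> None:
    if not ann.codesystem:
        out.append(ValidationIssue("error", path, "annotation codesystem is empty"))
    if not ann.code:
        out.append(ValidationIssue("error", path, "annotation code is empty"))
    if not _IRI_RE.match(ann.iri or ""):
        out.append(
            ValidationIssue(
                "error", path, f"annotation iri is not an absolute http(s) IRI: {ann.iri!r}"
            )
        )


def _check_option(opt: LookupOption, path: str, out: list[ValidationIssue]) -> None:
    for fname in ("value", "description", "codesystem", "code", "iri"):
        val = getattr(opt, fname)
        if _TSV_UNSAFE.search(val or ""):
            out.append(
                ValidationIssue(
                    "error", path, f"option field {fname!r} contains a tab or newline"
                )
            )
    if not opt.value:
        out.append(ValidationIssue("error", path, "option value is empty"))
    if not _IRI_RE.match(opt.iri or ""):
        out.append(
            ValidationIssue(
                "error", path, f"option iri is not an absolute http(s) IRI: {opt.iri!r}"
            )
        )


def validate(schema: SemanticSchema) -> ValidationReport:  # noqa: C901
    """Exhaustively check every structural invariant of a schema.

    Problems are collected into a :class:`ValidationReport` (never raised),
    each with a stable location path, so a bundle author sees all defects in
    one pass. ``report.ok`` is true iff there are no error-severity issues.
    """
    out: list[ValidationIssue] = []

    for key in ("name", "description", "version", "date", "license"):
        if not getattr(schema, key):
            out.append(ValidationIssue("error", "root", f"root field {key!r} is empty"))
    if schema.date and not re.match(r"^\d{4}-\d{2}-\d{2}$", schema.date):
        out.append(
            ValidationIssue("error", "root", f"date is not ISO-8601 (YYYY-MM-DD): {schema.date!r}")
        )

    # Global lookup options: unique values, TSV-safe.
    seen_globals: set[str] = set()
    for i, opt in enumerate(schema.global_lookup_options):
        path = f"root/globals[{i}]"
        _check_option(opt, path, out)
        if not opt.is_global:
            out.append(ValidationIssue("error", path, "root-level option must have is_global=true"))
        if opt.value in seen_globals:
            out.append(
                ValidationIssue("error", path, f"duplicate global option value {opt.value!r}")
            )
        seen_globals.add(opt.value)

    module_names = [m.name for m in schema.modules]
    if not schema.modules:
        out.append(ValidationIssue("error", "root", "schema has no modules"))
    dup_modules = {n for n in module_names if module_names.count(n) > 1}
    for n in sorted(dup_modules):
        out.append(ValidationIssue("error", f"module:{n}", f"duplicate module name {n!r}"))

    # Annotation IRIs must be unique across module and element annotations.
    iri_owners: dict[str, str] = {}

    for module in schema.modules:
        mpath = f"module:{module.name}"
        if not module.name:
            out.append(ValidationIssue("error", mpath, "module name is empty"))
        if not module.description:
            out.append(ValidationIssue("error", mpath, "module description is empty"))
        _check_annotation(module.annotation, mpath, out)
        if module.annotation.iri in iri_owners:
            out.append(
                ValidationIssue(
                    "error",
                    mpath,
                    f"annotation IRI {module.annotation.iri} already used at "
                    f"{iri_owners[module.annotation.iri]}",
                )
            )
        else:
            iri_owners[module.annotation.iri] = mpath
        if not module.elements:
            out.append(ValidationIssue("error", mpath, "module has no elements"))

        el_names = [e.name for e in module.elements]
        tech_names = [e.technical_name for e in module.elements]
        for element in module.elements:
            epath = f"{mpath}/element:{element.name}"
            if not element.name:
                out.append(ValidationIssue("error", epath, "element name is empty"))
            if not element.description:
                out.append(ValidationIssue("error", epath, "element description is empty"))
            if el_names.count(element.name) > 1:
                out.append(
                    ValidationIssue("error", epath, f"duplicate element name {element.name!r}")
                )
            tech = element.technical_name
            if not tech or re.search(r"\s", tech):
                out.append(
                    ValidationIssue("error", epath, f"invalid technical name {tech!r}")
                )
            elif tech_names.count(tech) > 1:
                out.append(
                    ValidationIssue("error", epath, f"duplicate technical name {tech!r}")
                )
            _check_annotation(element.annotation, epath, out)
            if element.annotation.iri in iri_owners:
                out.append(
                    ValidationIssue(
                        "error",
                        epath,
                        f"annotation IRI {element.annotation.iri} already used at "
                        f"{iri_owners[element.annotation.iri]}",
                    )
                )
            else:
                iri_owners[element.annotation.iri] = epath

            vt = element.value_type
            if vt.is_reference:
                if not element.reference_target:
                    out.append(
                        ValidationIssue(
                            "error", epath, f"value type {vt.value} requires a reference target"
                        )
                    )
                elif element.reference_target not in module_names:
                    out.append(
                        ValidationIssue(
                            "error",
                            epath,
                            f"reference target {element.reference_target!r} "
                            "does not name a module",
                        )
                    )
                if element.lookup_ref:
                    out.append(
                        ValidationIssue(
                            "error", epath, f"value type {vt.value} forbids a lookup reference"
                        )
                    )
            elif vt.is_lookup:
                if not element.lookup_ref:
                    out.append(
                        ValidationIssue(
                            "error", epath, f"value type {vt.value} requires a lookup reference"
                        )
                    )
                elif element.lookup_ref not in schema.lookup_lists:
                    out.append(
                        ValidationIssue(
                            "error",
                            epath,
                            f"lookup reference {element.lookup_ref!r} "
                            "does not name a lookup list",
                        )
                    )
                if element.reference_target:
                    out.append(
                        ValidationIssue(
                            "error", epath, f"value type {vt.value} forbids a reference target"
                        )
                    )
            else:
                if element.reference_target or element.lookup_ref:
                    out.append(
                        ValidationIssue(
                            "error",
                            epath,
                            f"value type {vt.value} forbids reference and lookup fields",
                        )
                    )

    # Lookup lists.
    referenced = set(schema.referenced_lookup_names())
    multi_lookup_lists = {
        el.lookup_ref
        for _, el in schema.iter_elements()
        if el.lookup_ref and el.value_type.is_multi_valued
    }
    globals_injected_lists = {
        el.lookup_ref
        for _, el in schema.iter_elements()
        if el.lookup_ref and el.value_type.includes_globals
    }
    for name, lst in schema.lookup_lists.items():
        lpath = f"lookup:{name}"
        if lst.name != name:
            out.append(
                ValidationIssue("error", lpath, f"list registered as {name!r} but named {lst.name!r}")
            )
        if not lst.options:
            out.append(ValidationIssue("error", lpath, "lookup list is empty"))
        seen_vals: set[str] = set()
        for i, opt in enumerate(lst.options):
            opath = f"{lpath}/option[{i}]"
            _check_option(opt, opath, out)
            if opt.value in seen_vals:
                out.append(
                    ValidationIssue("error", opath, f"duplicate option value {opt.value!r}")
                )
            seen_vals.add(opt.value)
            if opt.is_global:
                out.append(
                    ValidationIssue("error", opath, "base-list option must not be marked global")
                )
            if name in multi_lookup_lists and "," in opt.value:
                out.append(
                    ValidationIssue(
                        "error",
                        opath,
                        f"value {opt.value!r} contains a comma but the list is used by a "
                        "multi-valued lookup element (comma-separated serialization)",
                    )
                )
        if name in globals_injected_lists:
            clash = seen_vals & seen_globals
            for v in sorted(clash):
                out.append(
                    ValidationIssue(
                        "error",
                        lpath,
                        f"option value {v!r} collides with a global lookup option",
                    )
                )
        if lst.of_type is not None:
            _check_annotation(lst.of_type, f"{lpath}/ofType", out)
            for module, el in schema.iter_elements():
                if el.lookup_ref == name and el.annotation.iri == lst.of_type.iri:
                    out.append(
                        ValidationIssue(
                            "error",
                            lpath,
                            f"ofType IRI equals the annotation of element {el.name!r}; the "
                            "list's collective type must stay separate from the element "
                            "definition",
                        )
                    )
        if name not in referenced:
            out.append(ValidationIssue("warning", lpath, "lookup list is not referenced by any element"))

    # New term definitions.
    seen_acc: set[str] = set()
    for term in schema.term_definitions:
        tpath = f"term:{term.accession}"
        if not ACCESSION_RE.match(term.accession or ""):
            out.append(
                ValidationIssue(
                    "error", tpath, f"accession {term.accession!r} does not match FG_ + 7 digits"
                )
            )
        if term.accession in seen_acc:
            out.append(ValidationIssue("error", tpath, f"duplicate accession {term.accession!r}"))
        seen_acc.add(term.accession)
        if term.kind not in ("element-term", "lookup-term"):
            out.append(ValidationIssue("error", tpath, f"unknown term kind {term.kind!r}"))
        if term.kind == "element-term":
            if not term.domain_module:
                out.append(
                    ValidationIssue("error", tpath, "element-term requires a domain module")
                )
            elif term.domain_module not in module_names:
                out.append(
                    ValidationIssue(
                        "error", tpath, f"domain module {term.domain_module!r} does not exist"
                    )
                )
        elif term.kind == "lookup-term" and term.domain_module:
            out.append(ValidationIssue("error", tpath, "lookup-term must not carry a domain module"))
        if not term.label:
            out.append(ValidationIssue("error", tpath, "term label is empty"))
        if not term.description:
            out.append(ValidationIssue("error", tpath, "term description is empty"))

    return ValidationReport(out)


def effective_options(element: Element, schema: SemanticSchema) -> list[LookupOption]:
    """Options a user can pick for a lookup element.

    Base-list options in file order, followed by the schema's global
    options (null flavors) when the value type injects them. Inputs are
    never mutated.
    """
    if not element.value_type.is_lookup:
        raise ValueError(
            f"element {element.name!r} has non-lookup value type {element.value_type.value}"
        )
    if element.lookup_ref not in schema.lookup_lists:
        raise KeyError(f"lookup list {element.lookup_ref!r} not found")
    base = list(schema.lookup_lists[element.lookup_ref].options)
    if element.value_type.includes_globals:
        return base + list(schema.global_lookup_options)
    return base


def reference_graph(
    schema: SemanticSchema,
) -> tuple[nx.MultiDiGraph, list[list[str]]]:
    """Directed module graph induced by Reference* elements, with cycles.

    One edge per reference element (source module -> target module,
    ``label`` = element name). Cycles are returned as node sequences
    (without the repeated closing node), each rotated to start at its
    lexicographically smallest module and the whole set sorted, so output
    is deterministic.
    """
    g = nx.MultiDiGraph()
    g.add_nodes_from(m.name for m in schema.modules)
    for module, el in schema.iter_elements():
        if el.value_type.is_reference and el.reference_target:
            g.add_edge(module.name, el.reference_target, label=el.name)
    cycles = []
    for cyc in nx.simple_cycles(nx.DiGraph(g)):
        k = cyc.index(min(cyc))
        cycles.append(cyc[k:] + cyc[:k])
    cycles.sort(key=lambda c: (len(c), c))
    return g, cycles


def compute_statistics(schema: SemanticSchema) -> SchemaStatistics:
    """Summary statistics over a schema.

    Global (null-flavor) options are excluded from all option counts; only
    lists referenced by at least one element are counted.
    """
    n_modules = len(schema.modules)
    elements = [el for _, el in schema.iter_elements()]
    lookup_elements = [el for el in elements if el.value_type.is_lookup]
    unique_names = schema.referenced_lookup_names()
    sizes = {n: len(schema.lookup_lists[n].options) for n in unique_names
             if n in schema.lookup_lists}
    per_element_sum = sum(
        sizes.get(el.lookup_ref, 0) for el in lookup_elements if el.lookup_ref
    )
    unique_sum = sum(sizes.values())
    min_list = max_list = None
    if sizes:
        min_name = min(sizes, key=lambda n: (sizes[n], n))
        max_name = max(sizes, key=lambda n: (sizes[n], n))
        min_list = (min_name, sizes[min_name])
        max_list = (max_name, sizes[max_name])
    return SchemaStatistics(
        n_modules=n_modules,
        n_elements=len(elements),
        n_lookup_elements=len(lookup_elements),
        n_unique_lookup_lists=len(sizes),
        total_lookup_options_per_element_sum=per_element_sum,
        total_unique_lookup_options=unique_sum,
        min_list=min_list,
        max_list=max_list,
        n_new_terms=len(schema.term_definitions),
    )
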