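"""Application-ontology and term-fragment generation.

The core Turtle file defines every module as an ``owl:Class`` (4 triples:
type, label, description, isDefinedBy) and every element as an
``owl:DatatypeProperty`` (6 triples: type, label, domain, isDefinedBy,
description, range), so a schema with *m* modules and *n* elements yields
exactly ``4m + 6n`` triples. Each unique lookup list gets its own Turtle
file whose options carry 4 triples each (type via the list's ``ofType``,
label, description, isDefinedBy pointing at the option's source-ontology
IRI); global null-flavor options live in a separate ``nullflavors.ttl``
that is not counted among the per-list files.

Subjects are always minted under the configurable W3ID-style namespace
from technical names; the imported source-ontology IRIs appear only as
``rdfs:isDefinedBy`` objects, so their meaning is never altered. Newly
minted terms (``FG_`` accessions) are emitted as one RDF-XML fragment per
term, suitable for individual hosting behind a W3ID redirect.
"""

from __future__ import annotations

import re

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import DCTERMS, OWL, RDF, RDFS, XSD

from fairschema.generators.base import (
    DEFAULT_NAMESPACE,
    Generator,
    GenerationError,
    register,
)
from fairschema.io import lookup_filename
from fairschema.model import (
    ACCESSION_RE,
    Element,
    LookupList,
    LookupOption,
    SchemaModule,
    SemanticSchema,
    ValueType,
    to_technical_name,
)

__all__ = [
    "mint_iri",
    "module_iri",
    "element_iri",
    "generate_core_ontology",
    "generate_lookup_ontologies",
    "generate_term_fragments",
    "core_ontology_filename",
    "OntologyGenerator",
    "TermFragmentGenerator",
]

_XSD_RANGE = {
    ValueType.String: XSD.string,
    ValueType.Text: XSD.string,
    ValueType.Integer: XSD.integer,
    ValueType.Decimal: XSD.decimal,
    ValueType.Boolean: XSD.boolean,
    ValueType.Date: XSD.date,
    ValueType.DateTime: XSD.dateTime,
}


def mint_iri(accession: str, namespace: str = DEFAULT_NAMESPACE) -> str:
    """Mint the persistent IRI of a new term.

    ``accession`` must match ``FG_`` + exactly seven digits; the result is
    ``<namespace>/<accession>`` (W3ID-style, stable under redirect).
    """
    if not ACCESSION_RE.match(accession or ""):
        raise ValueError(f"accession {accession!r} does not match FG_ + 7 digits")
    return f"{namespace.rstrip('/')}/{accession}"


def module_iri(module: SchemaModule, namespace: str = DEFAULT_NAMESPACE) -> URIRef:
    return URIRef(f"{namespace.rstrip('/')}/{module.technical_name}")


def element_iri(
    module: SchemaModule, element: Element, namespace: str = DEFAULT_NAMESPACE
) -> URIRef:
    return URIRef(f"{namespace.rstrip('/')}/{module.technical_name}/{element.technical_name}")


def _list_iri(name: str, namespace: str) -> URIRef:
    return URIRef(f"{namespace.rstrip('/')}/{name}")


def _option_iri(list_name: str, option: LookupOption, index: int, namespace: str) -> URIRef:
    slug = to_technical_name(option.value) or f"option{index}"
    return URIRef(f"{namespace.rstrip('/')}/{list_name}/{slug}")


def _new_graph() -> Graph:
    g = Graph()
    g.bind("rdf", RDF)
    g.bind("rdfs", RDFS)
    g.bind("owl", OWL)
    g.bind("dc", DCTERMS, override=True, replace=True)
    return g


def _range_for(element: Element, schema: SemanticSchema, namespace: str) -> URIRef:
    vt = element.value_type
    if vt.is_reference:
        return module_iri(schema.module(element.reference_target), namespace)
    if vt.is_lookup:
        lst = schema.lookup_lists[element.lookup_ref]
        if lst.of_type is not None:
            return URIRef(lst.of_type.iri)
        return _list_iri(element.lookup_ref, namespace)
    return _XSD_RANGE[vt]


def generate_core_ontology(schema: SemanticSchema, namespace: str = DEFAULT_NAMESPACE) -> str:
    """Serialize modules and elements as the core application ontology
    (Turtle); exactly 4 triples per module and 6 per element."""
    g = _new_graph()
    for module in schema.modules:
        s = module_iri(module, namespace)
        g.add((s, RDF.type, OWL.Class))
        g.add((s, RDFS.label, Literal(module.name, lang="en")))
        g.add((s, DCTERMS.description, Literal(module.description, lang="en")))
        g.add((s, RDFS.isDefinedBy, URIRef(module.annotation.iri)))
    for module, element in schema.iter_elements():
        s = element_iri(module, element, namespace)
        g.add((s, RDF.type, OWL.DatatypeProperty))
        g.add((s, RDFS.label, Literal(element.name, lang="en")))
        g.add((s, RDFS.domain, module_iri(module, namespace)))
        g.add((s, RDFS.isDefinedBy, URIRef(element.annotation.iri)))
        g.add((s, DCTERMS.description, Literal(element.description, lang="en")))
        g.add((s, RDFS.range, _range_for(element, schema, namespace)))
    return g.serialize(format="turtle")


def _options_graph(
    list_name: str, options: list[LookupOption], type_iri: URIRef, namespace: str
) -> Graph:
    g = _new_graph()
    for i, opt in enumerate(options):
        s = _option_iri(list_name, opt, i, namespace)
        g.add((s, RDF.type, type_iri))
        g.add((s, RDFS.label, Literal(opt.value, lang="en")))
        g.add((s, DCTERMS.description, Literal(opt.description, lang="en")))
        g.add((s, RDFS.isDefinedBy, URIRef(opt.iri)))
    return g


def generate_lookup_ontologies(
    schema: SemanticSchema, namespace: str = DEFAULT_NAMESPACE
) -> dict[str, str]:
    """One Turtle document per unique referenced lookup list, keyed by file
    name; plus ``nullflavors.ttl`` for the global options when injected."""
    out: dict[str, str] = {}
    for name in schema.referenced_lookup_names():
        lst: LookupList = schema.lookup_lists[name]
        type_iri = URIRef(lst.of_type.iri) if lst.of_type else _list_iri(name, namespace)
        fname = lookup_filename(name).removesuffix(".tsv") + ".ttl"
        out[fname] = _options_graph(name, lst.options, type_iri, namespace).serialize(
            format="turtle"
        )
    injected = any(
        el.value_type.includes_globals for _, el in schema.iter_elements() if el.lookup_ref
    )
    if schema.global_lookup_options and injected:
        out["nullflavors.ttl"] = _options_graph(
            "nullflavors",
            schema.global_lookup_options,
            _list_iri("nullflavors", namespace),
            namespace,
        ).serialize(format="turtle")
    return out


def core_ontology_filename(schema: SemanticSchema) -> str:
    slug = re.sub(r"[^0-9a-z]+", "-", schema.name.lower()).strip("-") or "schema"
    return f"{slug}.ttl"


def generate_term_fragments(
    schema: SemanticSchema, namespace: str = DEFAULT_NAMESPACE
) -> dict[str, str]:
    """One RDF-XML fragment per newly minted term, keyed by file name.

    Element-kind terms carry type, label, isDefinedBy, domain, description
    and identifier; lookup-kind terms the same minus the domain.
    """
    seen: set[str] = set()
    out: dict[str, str] = {}
    ns = namespace.rstrip("/")
    for term in schema.term_definitions:
        if term.accession in seen:
            raise GenerationError(f"duplicate accession {term.accession!r}")
        seen.add(term.accession)
        g = _new_graph()
        s = URIRef(mint_iri(term.accession, namespace))
        if term.kind == "element-term":
            g.add((s, RDF.type, OWL.DatatypeProperty))
            g.add((s, RDFS.domain, module_iri(schema.module(term.domain_module), namespace)))
        else:
            g.add((s, RDF.type, OWL.NamedIndividual))
        g.add((s, RDFS.label, Literal(term.label, lang="en")))
        g.add((s, RDFS.isDefinedBy, URIRef(ns)))
        g.add((s, DCTERMS.description, Literal(term.description, lang="en")))
        g.add((s, DCTERMS.identifier, Literal(term.identifier)))
        out[f"{term.accession}.rdf"] = g.serialize(format="xml")
    return out


@register
class OntologyGenerator(Generator):
    """Core application ontology plus per-lookup-list Turtle files."""

    target_name = "ontology"

    def produce(self, schema: SemanticSchema) -> list[tuple[str, bytes]]:
        ns = self.config.namespace
        files = {core_ontology_filename(schema): generate_core_ontology(schema, ns)}
        files.update(generate_lookup_ontologies(schema, ns))
        return [(name, text.encode("utf-8")) for name, text in files.items()]


@register
class TermFragmentGenerator(Generator):
    """RDF-XML fragments for newly minted FG terms."""

    target_name = "terms"

    def produce(self, schema: SemanticSchema) -> list[tuple[str, bytes]]:
        return [
            (name, text.encode("utf-8"))
            for name, text in generate_term_fragments(schema, self.config.namespace).items()
        ]
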