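"""Reading and writing schema bundles.

A bundle is a directory with one YAML schema file plus a directory of TSV
lookup lists (columns ``value, description, codesystem, code, iri``) and,
optionally, a directory of RDF-XML fragments for newly minted terms. All
I/O is UTF-8 with LF line endings; writing then parsing a schema is the
identity.

YAML key layout
---------------
Root: ``name, description, version, date, authors, copyright, license,
lookup-globals, modules`` and optionally ``new-terms``. Per module:
``name, description, ontology, elements``. Per element: ``name,
description, ontology, type`` plus ``reference`` (a module name) for
reference types, ``lookup`` (a list name) and optionally ``ofType`` for
lookup types. Ontology annotations are nested maps
``{codesystem, code, iri, label}``.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Callable

import yaml

from fairschema.model import (
    Element,
    LookupList,
    LookupOption,
    OntologyAnnotation,
    SchemaModule,
    SemanticSchema,
    TermDefinition,
    ValueType,
    validate,
)

__all__ = [
    "SchemaFormatError",
    "BundleError",
    "LOOKUP_TSV_HEADER",
    "lookup_filename",
    "parse_lookup_tsv",
    "write_lookup_tsv",
    "parse_schema",
    "write_schema",
    "load_bundle",
    "write_bundle",
]

LOOKUP_TSV_HEADER = ("value", "description", "codesystem", "code", "iri")

SCHEMA_FILE = "schema.yml"
LOOKUP_DIR = "lookups"
TERMS_DIR = "terms"

_ROOT_KEYS = (
    "name",
    "description",
    "version",
    "date",
    "authors",
    "copyright",
    "license",
    "lookup-globals",
    "modules",
    "new-terms",
)
_REQUIRED_ROOT_KEYS = (
    "name",
    "description",
    "version",
    "date",
    "authors",
    "copyright",
    "license",
    "modules",
)


class SchemaFormatError(ValueError):
    """A file does not conform to the bundle format (not a validation issue)."""


class BundleError(OSError):
    """A bundle directory is missing required files."""


def lookup_filename(list_name: str) -> str:
    """TSV file name for a lookup list: lower-case with underscores."""
    slug = re.sub(r"[^0-9a-z]+", "_", list_name.lower()).strip("_")
    if not slug:
        raise SchemaFormatError(f"cannot derive a file name from list name {list_name!r}")
    return f"{slug}.tsv"


def parse_lookup_tsv(text: str, name: str) -> LookupList:
    """Parse one lookup-list TSV.

    The header must carry exactly the columns ``value, description,
    codesystem, code, iri`` in that order (case-insensitive). Row order is
    preserved; blank trailing lines are ignored. Duplicate values parse
    fine and are reported by :func:`fairschema.model.validate`.
    """
    lines = text.split("\n")
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        raise SchemaFormatError(f"lookup list {name!r}: file is empty")
    header = tuple(h.strip().lower() for h in lines[0].split("\t"))
    if header != LOOKUP_TSV_HEADER:
        raise SchemaFormatError(
            f"lookup list {name!r}: bad header {lines[0]!r}; expected "
            + "\t".join(LOOKUP_TSV_HEADER)
        )
    options: list[LookupOption] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(LOOKUP_TSV_HEADER):
            raise SchemaFormatError(
                f"lookup list {name!r}: line {lineno} has {len(cells)} columns, "
                f"expected {len(LOOKUP_TSV_HEADER)}"
            )
        options.append(LookupOption(*[c.strip() for c in cells]))
    if not options:
        raise SchemaFormatError(f"lookup list {name!r}: no options (header only)")
    return LookupList(name=name, options=options)


def write_lookup_tsv(lst: LookupList) -> str:
    rows = ["\t".join(LOOKUP_TSV_HEADER)]
    for opt in lst.options:
        rows.append("\t".join([opt.value, opt.description, opt.codesystem, opt.code, opt.iri]))
    return "\n".join(rows) + "\n"


def _parse_annotation(data: dict, where: str) -> OntologyAnnotation:
    if not isinstance(data, dict):
        raise SchemaFormatError(f"{where}: ontology annotation must be a map")
    for key in ("codesystem", "code", "iri"):
        if key not in data:
            raise SchemaFormatError(f"{where}: ontology annotation misses key {key!r}")
    return OntologyAnnotation(
        codesystem=str(data["codesystem"]),
        code=str(data["code"]),
        iri=str(data["iri"]),
        label=str(data["label"]) if data.get("label") is not None else None,
    )


def _annotation_to_yaml(ann: OntologyAnnotation) -> dict:
    out = {"codesystem": ann.codesystem, "code": ann.code, "iri": ann.iri}
    if ann.label is not None:
        out["label"] = ann.label
    return out


def _parse_element(data: dict, where: str, resolver, schema: SemanticSchema) -> Element:
    for key in ("name", "description", "ontology", "type"):
        if key not in data:
            raise SchemaFormatError(f"{where}: element misses key {key!r}")
    token = str(data["type"])
    try:
        vt = ValueType(token)
    except ValueError:
        raise SchemaFormatError(f"{where}: unknown value type {token!r}") from None
    el = Element(
        name=str(data["name"]),
        description=str(data["description"]),
        annotation=_parse_annotation(data["ontology"], where),
        value_type=vt,
        reference_target=str(data["reference"]) if data.get("reference") else None,
        lookup_ref=str(data["lookup"]) if data.get("lookup") else None,
    )
    if el.lookup_ref and el.lookup_ref not in schema.lookup_lists:
        try:
            lst = resolver(el.lookup_ref)
        except FileNotFoundError:
            raise SchemaFormatError(
                f"{where}: lookup list {el.lookup_ref!r} not found "
                f"(sought {lookup_filename(el.lookup_ref)})"
            ) from None
        schema.lookup_lists[el.lookup_ref] = lst
    if el.lookup_ref and data.get("ofType") is not None:
        of_type = _parse_annotation(data["ofType"], f"{where}/ofType")
        lst = schema.lookup_lists[el.lookup_ref]
        if lst.of_type is not None and lst.of_type != of_type:
            raise SchemaFormatError(
                f"{where}: conflicting ofType for lookup list {el.lookup_ref!r}"
            )
        lst.of_type = of_type
    return el


def _parse_option(data: dict, where: str, is_global: bool) -> LookupOption:
    for key in LOOKUP_TSV_HEADER:
        if key not in data:
            raise SchemaFormatError(f"{where}: lookup option misses key {key!r}")
    return LookupOption(
        value=str(data["value"]),
        description=str(data["description"]),
        codesystem=str(data["codesystem"]),
        code=str(data["code"]),
        iri=str(data["iri"]),
        is_global=is_global,
    )


def _parse_term(data: dict, where: str) -> TermDefinition:
    for key in ("accession", "label", "description", "kind"):
        if key not in data:
            raise SchemaFormatError(f"{where}: term misses key {key!r}")
    return TermDefinition(
        accession=str(data["accession"]),
        label=str(data["label"]),
        description=str(data["description"]),
        kind=str(data["kind"]),
        domain_module=str(data["module"]) if data.get("module") else None,
    )


def parse_schema(
    yaml_text: str, lookup_resolver: Callable[[str], LookupList]
) -> SemanticSchema:
    """Parse a schema YAML document into a :class:`SemanticSchema`.

    ``lookup_resolver`` maps a lookup-list name to its parsed
    :class:`LookupList` (raising ``FileNotFoundError`` when absent); each
    referenced list is resolved exactly once, so lists shared by several
    elements keep one identity. Unknown keys are preserved on the returned
    object as ``parse_warnings`` and do not fail the parse.
    """
    data = yaml.safe_load(yaml_text)
    if not isinstance(data, dict):
        raise SchemaFormatError("schema YAML root must be a map")
    missing = [k for k in _REQUIRED_ROOT_KEYS if k not in data]
    if missing:
        raise SchemaFormatError("schema misses root key(s): " + ", ".join(missing))

    warnings = [f"unknown root key {k!r}" for k in data if k not in _ROOT_KEYS]

    date = data["date"]
    schema = SemanticSchema(
        name=str(data["name"]),
        description=str(data["description"]),
        version=str(data["version"]),
        date=date.isoformat() if hasattr(date, "isoformat") else str(date),
        authors=[str(a) for a in (data["authors"] or [])],
        copyright=str(data["copyright"]),
        license=str(data["license"]),
    )
    for i, opt in enumerate(data.get("lookup-globals") or []):
        schema.global_lookup_options.append(
            _parse_option(opt, f"root/globals[{i}]", is_global=True)
        )

    modules = data["modules"]
    if not modules:
        raise SchemaFormatError("schema has an empty modules list")
    for mdata in modules:
        where = f"module:{mdata.get('name', '?')}"
        for key in ("name", "description", "ontology", "elements"):
            if key not in mdata:
                raise SchemaFormatError(f"{where}: module misses key {key!r}")
        module = SchemaModule(
            name=str(mdata["name"]),
            description=str(mdata["description"]),
            annotation=_parse_annotation(mdata["ontology"], where),
        )
        for edata in mdata["elements"] or []:
            ewhere = f"{where}/element:{edata.get('name', '?')}"
            module.elements.append(_parse_element(edata, ewhere, lookup_resolver, schema))
            warnings.extend(
                f"{ewhere}: unknown key {k!r}"
                for k in edata
                if k not in ("name", "description", "ontology", "type", "reference", "lookup", "ofType")
            )
        schema.modules.append(module)

    for i, tdata in enumerate(data.get("new-terms") or []):
        schema.term_definitions.append(_parse_term(tdata, f"new-terms[{i}]"))

    schema.parse_warnings = warnings  # side channel, not a schema field
    return schema


def write_schema(schema: SemanticSchema) -> tuple[str, dict[str, str]]:
    """Serialize a schema to YAML text plus a ``{file name: TSV text}`` map.

    Output is deterministic (fixed key order, schema order preserved) and
    round-trips: ``parse_schema(*write_schema(s))`` equals ``s`` for any
    schema whose lookup lists are all referenced.
    """
    doc: dict = {
        "name": schema.name,
        "description": schema.description,
        "version": schema.version,
        "date": schema.date,
        "authors": list(schema.authors),
        "copyright": schema.copyright,
        "license": schema.license,
        "lookup-globals": [
            {
                "value": o.value,
                "description": o.description,
                "codesystem": o.codesystem,
                "code": o.code,
                "iri": o.iri,
            }
            for o in schema.global_lookup_options
        ],
        "modules": [],
    }
    emitted_of_type: set[str] = set()
    for module in schema.modules:
        mdoc = {
            "name": module.name,
            "description": module.description,
            "ontology": _annotation_to_yaml(module.annotation),
            "elements": [],
        }
        for el in module.elements:
            edoc = {
                "name": el.name,
                "description": el.description,
                "ontology": _annotation_to_yaml(el.annotation),
                "type": el.value_type.value,
            }
            if el.reference_target:
                edoc["reference"] = el.reference_target
            if el.lookup_ref:
                edoc["lookup"] = el.lookup_ref
                lst = schema.lookup_lists.get(el.lookup_ref)
                if lst is not None and lst.of_type is not None and el.lookup_ref not in emitted_of_type:
                    edoc["ofType"] = _annotation_to_yaml(lst.of_type)
                    emitted_of_type.add(el.lookup_ref)
            mdoc["elements"].append(edoc)
        doc["modules"].append(mdoc)
    if schema.term_definitions:
        doc["new-terms"] = [
            {
                "accession": t.accession,
                "label": t.label,
                "description": t.description,
                "kind": t.kind,
                **({"module": t.domain_module} if t.domain_module else {}),
            }
            for t in schema.term_definitions
        ]

    yaml_text = yaml.safe_dump(
        doc, sort_keys=False, allow_unicode=True, default_flow_style=False, width=100000
    )
    tsvs = {
        lookup_filename(name): write_lookup_tsv(lst)
        for name, lst in schema.lookup_lists.items()
    }
    return yaml_text, tsvs


def load_bundle(root_dir: str | Path) -> SemanticSchema:
    """Load a bundle directory and attach a validation report.

    Expects ``schema.yml`` and a ``lookups/`` directory under ``root_dir``.
    Every lookup reference must have a matching TSV; extra TSV files load
    fine and surface as unreferenced-list warnings. The report from
    :func:`fairschema.model.validate` is attached as
    ``schema.validation_report``.
    """
    root = Path(root_dir)
    schema_path = root / SCHEMA_FILE
    if not schema_path.is_file():
        raise BundleError(f"bundle {root}: missing {SCHEMA_FILE}")
    lookup_dir = root / LOOKUP_DIR

    def resolver(name: str) -> LookupList:
        path = lookup_dir / lookup_filename(name)
        if not path.is_file():
            raise FileNotFoundError(path)
        return parse_lookup_tsv(path.read_text(encoding="utf-8"), name)

    yaml_text = schema_path.read_text(encoding="utf-8")
    try:
        schema = parse_schema(yaml_text, resolver)
    except SchemaFormatError as exc:
        if "not found" in str(exc):
            raise BundleError(str(exc)) from exc
        raise

    # Pick up lookup files nobody referenced (warning at validation time).
    if lookup_dir.is_dir():
        known = {lookup_filename(n) for n in schema.lookup_lists}
        for path in sorted(lookup_dir.glob("*.tsv")):
            if path.name not in known:
                name = path.stem
                schema.lookup_lists[name] = parse_lookup_tsv(
                    path.read_text(encoding="utf-8"), name
                )

    terms_dir = root / TERMS_DIR
    if not schema.term_definitions and terms_dir.is_dir():
        for path in sorted(terms_dir.glob("*.rdf")):
            schema.term_definitions.append(
                parse_term_fragment(path.read_text(encoding="utf-8"), schema)
            )

    schema.validation_report = validate(schema)
    return schema


def write_bundle(schema: SemanticSchema, root_dir: str | Path) -> list[Path]:
    """Write a schema as a bundle directory; returns the files written."""
    root = Path(root_dir)
    root.mkdir(parents=True, exist_ok=True)
    yaml_text, tsvs = write_schema(schema)
    written = []
    schema_path = root / SCHEMA_FILE
    schema_path.write_text(yaml_text, encoding="utf-8", newline="\n")
    written.append(schema_path)
    lookup_dir = root / LOOKUP_DIR
    lookup_dir.mkdir(exist_ok=True)
    for fname, text in tsvs.items():
        path = lookup_dir / fname
        path.write_text(text, encoding="utf-8", newline="\n")
        written.append(path)
    return written


def parse_term_fragment(xml_text: str, schema: SemanticSchema) -> TermDefinition:
    """Recover a :class:`TermDefinition` from an RDF-XML term fragment."""
    import rdflib
    from rdflib.namespace import DCTERMS, RDFS

    g = rdflib.Graph()
    g.parse(data=xml_text, format="xml")
    subjects = set(g.subjects())
    if len(subjects) != 1:
        raise SchemaFormatError(f"term fragment must describe exactly one term, got {len(subjects)}")
    subj = subjects.pop()
    accession = str(subj).rsplit("/", 1)[-1]
    domain = g.value(subj, RDFS.domain)
    domain_module = None
    if domain is not None:
        tech = str(domain).rsplit("/", 1)[-1]
        for module in schema.modules:
            if module.technical_name == tech:
                domain_module = module.name
                break
    return TermDefinition(
        accession=accession,
        label=str(g.value(subj, RDFS.label) or ""),
        description=str(g.value(subj, DCTERMS.description) or ""),
        kind="element-term" if domain is not None else "lookup-term",
        domain_module=domain_module,
    )
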