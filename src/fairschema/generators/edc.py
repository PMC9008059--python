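"""EDC blueprint generation: MOLGENIS-EMX, MOLGENIS-EMX2, codebook TSVs
and a simplified ART-DECOR dataset XML.

Column dialects are fixed by this package and self-describing rather than
byte-compatible with any particular EDC release: definition tables carry
``entity, attribute, dataType, refEntity, description, ontologyTermIRI``
and lookup data rows carry ``value, label, codesystem, code, iri``.

Circular module references cannot be imported directly into a relational
system (no import order satisfies them), so the EMX blueprint defers the
cycle-closing reference columns into a standalone patch table applied
after the main import; the main import order is then a valid topological
order of the remaining dependency graph.
"""

from __future__ import annotations

import csv
import io as _stdio
import re
import zipfile
from dataclasses import dataclass, field

from lxml import etree

from fairschema.generators.base import Generator, register
from fairschema.io import lookup_filename
from fairschema.model import LookupOption, SemanticSchema, ValueType

__all__ = [
    "EmxBlueprint",
    "generate_emx",
    "generate_emx2",
    "generate_codebook",
    "generate_artdecor",
    "emx_import_plan",
    "package_name",
    "emx2_zip_bytes",
]

_DEF_HEADER = ("entity", "attribute", "dataType", "refEntity", "description", "ontologyTermIRI")
_DATA_HEADER = ("value", "label", "codesystem", "code", "iri")

_EMX_TYPE = {
    ValueType.String: "string",
    ValueType.Text: "text",
    ValueType.Integer: "int",
    ValueType.Decimal: "decimal",
    ValueType.Boolean: "bool",
    ValueType.Date: "date",
    ValueType.DateTime: "datetime",
}
_EMX2_TYPE = {
    ValueType.String: "string",
    ValueType.Text: "text",
    ValueType.Integer: "int",
    ValueType.Decimal: "decimal",
    ValueType.Boolean: "bool",
    ValueType.Date: "date",
    ValueType.DateTime: "datetime",
}


def package_name(schema: SemanticSchema) -> str:
    """Database namespace derived from the schema name (e.g. "fair-genomes")."""
    return re.sub(r"[^0-9a-z]+", "-", schema.name.lower()).strip("-") or "schema"


def _tsv(rows: list[tuple[str, ...]]) -> str:
    return "\n".join("\t".join(r) for r in rows) + "\n"


def _list_table_stem(name: str) -> str:
    return lookup_filename(name).removesuffix(".tsv")


def _materialized_options(schema: SemanticSchema, list_name: str) -> list[LookupOption]:
    """Data rows for one lookup table: base options, with the global null
    flavors appended when any referencing element injects them."""
    lst = schema.lookup_lists[list_name]
    injected = any(
        el.value_type.includes_globals and el.lookup_ref == list_name
        for _, el in schema.iter_elements()
    )
    rows = list(lst.options)
    if injected:
        rows += list(schema.global_lookup_options)
    return rows


def emx_import_plan(schema: SemanticSchema) -> tuple[list[str], list[tuple[str, str]]]:
    """Module import order plus the deferred cycle-closing references.

    Greedy, deterministic: repeatedly pick the first module (in schema
    order) whose reference targets are all already imported. When none
    qualifies (a cycle), the first blocked module's missing dependency is
    imported instead, with that dependency's own unsatisfied (i.e.
    cycle-closing) references deferred — so in a Clinical->Material->
    Clinical cycle the forward reference is kept and the back-reference is
    patched in afterwards. Returns ``(module order, [(module name, element
    name), ...])``; the non-deferred dependency graph is acyclic by
    construction and the returned order is a topological order of it.
    """
    remaining = [m.name for m in schema.modules]
    by_name = {m.name: m for m in schema.modules}
    order: list[str] = []
    deferred: list[tuple[str, str]] = []

    def unsatisfied(name: str) -> list[str]:
        deferred_els = {e for m, e in deferred if m == name}
        return [
            el.reference_target
            for el in by_name[name].elements
            if el.value_type.is_reference
            and el.reference_target
            and el.reference_target not in order
            and el.reference_target != name
            and el.name not in deferred_els
        ]

    while remaining:
        pick = next((n for n in remaining if not unsatisfied(n)), None)
        if pick is None:
            blocked = remaining[0]
            pick = unsatisfied(blocked)[0]
            for el in by_name[pick].elements:
                if (
                    el.value_type.is_reference
                    and el.reference_target
                    and el.reference_target not in order
                    and el.reference_target != pick
                ):
                    deferred.append((pick, el.name))
        order.append(pick)
        remaining.remove(pick)
    return order, deferred


@dataclass
class EmxBlueprint:
    """All parts of a MOLGENIS-EMX import, in import order."""

    package_tsv: str
    lookup_definitions_tsv: str
    lookup_data: dict[str, str]  # table stem -> TSV content
    module_definitions_tsv: str
    deferred_references_tsv: str
    import_order: list[str] = field(default_factory=list)

    def files(self) -> list[tuple[str, bytes]]:
        out = [("sys_md_Package.tsv", self.package_tsv)]
        out.append(("lookup_definitions.tsv", self.lookup_definitions_tsv))
        out += [(f"data_{stem}.tsv", text) for stem, text in self.lookup_data.items()]
        out.append(("module_definitions.tsv", self.module_definitions_tsv))
        out.append(("deferred_references.tsv", self.deferred_references_tsv))
        out.append(("import_order.txt", "\n".join(self.import_order) + "\n"))
        return [(p, t.encode("utf-8")) for p, t in out]


def generate_emx(schema: SemanticSchema) -> EmxBlueprint:
    """Build the MOLGENIS-EMX blueprint.

    Import proceeds in three stages — lookup definitions, lookup data,
    module definitions — with cycle-closing references split off into the
    deferred patch.
    """
    pkg = package_name(schema)
    package_tsv = _tsv([
        ("name", "label", "description"),
        (pkg, schema.name, schema.description),
    ])

    lookup_names = schema.referenced_lookup_names()
    lookup_entity = {n: f"{pkg}_{_list_table_stem(n)}" for n in lookup_names}
    def_rows: list[tuple[str, ...]] = [_DEF_HEADER]
    for name in lookup_names:
        lst = schema.lookup_lists[name]
        of_iri = lst.of_type.iri if lst.of_type else ""
        for col in _DATA_HEADER:
            def_rows.append((lookup_entity[name], col, "string", "", "", of_iri))
    lookup_definitions_tsv = _tsv(def_rows)

    lookup_data = {
        _list_table_stem(name): _tsv(
            [_DATA_HEADER]
            + [
                (o.value, o.description, o.codesystem, o.code, o.iri)
                for o in _materialized_options(schema, name)
            ]
        )
        for name in lookup_names
    }

    order, deferred = emx_import_plan(schema)
    deferred_set = set(deferred)
    module_entity = {m.name: f"{pkg}_{m.technical_name}" for m in schema.modules}
    mod_rows: list[tuple[str, ...]] = [_DEF_HEADER]
    patch_rows: list[tuple[str, ...]] = [("entity", "attribute", "refEntity")]
    for mname in order:
        module = schema.module(mname)
        for el in module.elements:
            ref_entity = ""
            if el.value_type.is_reference:
                ref_entity = module_entity[el.reference_target]
            elif el.value_type.is_lookup:
                ref_entity = lookup_entity[el.lookup_ref]
            dtype = _EMX_TYPE.get(
                el.value_type, "mref" if el.value_type.is_multi_valued else "xref"
            )
            if (mname, el.name) in deferred_set:
                patch_rows.append((module_entity[mname], el.technical_name, ref_entity))
                continue
            mod_rows.append(
                (
                    module_entity[mname],
                    el.technical_name,
                    dtype,
                    ref_entity,
                    el.description,
                    el.annotation.iri,
                )
            )

    import_order = (
        ["sys_md_Package.tsv", "lookup_definitions.tsv"]
        + [f"data_{_list_table_stem(n)}.tsv" for n in lookup_names]
        + ["module_definitions.tsv", "deferred_references.tsv"]
    )
    return EmxBlueprint(
        package_tsv=package_tsv,
        lookup_definitions_tsv=lookup_definitions_tsv,
        lookup_data=lookup_data,
        module_definitions_tsv=_tsv(mod_rows),
        deferred_references_tsv=_tsv(patch_rows),
        import_order=import_order,
    )


def _csv_text(rows: list[tuple[str, ...]]) -> str:
    buf = _stdio.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerows(rows)
    return buf.getvalue()


def generate_emx2(schema: SemanticSchema) -> dict[str, str]:
    """Build the MOLGENIS-EMX2 file set.

    ``molgenis.csv`` defines every module and lookup table; each table and
    column row carries its ontology IRI in the ``semantics`` column. One
    CSV of lookup values accompanies each unique lookup list.
    """
    rows: list[tuple[str, ...]] = [
        ("tableName", "columnName", "columnType", "refTable", "description", "semantics")
    ]
    lookup_names = schema.referenced_lookup_names()
    for name in lookup_names:
        lst = schema.lookup_lists[name]
        stem = _list_table_stem(name)
        rows.append((stem, "", "", "", f"Lookup list {name}.", lst.of_type.iri if lst.of_type else ""))
        for col in _DATA_HEADER:
            rows.append((stem, col, "string", "", "", ""))
    for module in schema.modules:
        rows.append(
            (module.technical_name, "", "", "", module.description, module.annotation.iri)
        )
        for el in module.elements:
            if el.value_type.is_reference:
                ctype = "ref_array" if el.value_type.is_multi_valued else "ref"
                ref = schema.module(el.reference_target).technical_name
            elif el.value_type.is_lookup:
                ctype = "ref_array" if el.value_type.is_multi_valued else "ref"
                ref = _list_table_stem(el.lookup_ref)
            else:
                ctype = _EMX2_TYPE[el.value_type]
                ref = ""
            rows.append(
                (
                    module.technical_name,
                    el.technical_name,
                    ctype,
                    ref,
                    el.description,
                    el.annotation.iri,
                )
            )
    files = {"molgenis.csv": _csv_text(rows)}
    for name in lookup_names:
        files[f"{_list_table_stem(name)}.csv"] = _csv_text(
            [_DATA_HEADER]
            + [
                (o.value, o.description, o.codesystem, o.code, o.iri)
                for o in _materialized_options(schema, name)
            ]
        )
    return files


def emx2_zip_bytes(files: dict[str, str]) -> bytes:
    """Pack an EMX2 file set as an importable ZIP (fixed timestamps, so the
    archive is byte-stable)."""
    buf = _stdio.BytesIO()
    with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(files):
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, files[name])
    return buf.getvalue()


@dataclass
class CodebookBundle:
    info_tsv: str
    codebook_tsv: str
    lookups: dict[str, str]  # file name -> TSV with language-suffixed headers

    def files(self) -> list[tuple[str, bytes]]:
        out = [("INFO.tsv", self.info_tsv), ("CODEBOOK.tsv", self.codebook_tsv)]
        out += sorted(self.lookups.items())
        return [(p, t.encode("utf-8")) for p, t in out]


def generate_codebook(schema: SemanticSchema) -> CodebookBundle:
    """Tabular codebook: INFO (schema metadata), CODEBOOK (one row per
    element, module-major order) and re-headered lookup TSVs with
    language-suffixed columns (value_en, description_en)."""
    info = _tsv([
        ("key", "value"),
        ("name", schema.name),
        ("version", schema.version),
        ("date", schema.date),
        ("description", schema.description),
    ])
    rows: list[tuple[str, ...]] = [
        ("module", "element", "description", "type", "reference", "lookup",
         "codesystem", "code", "iri")
    ]
    for module, el in schema.iter_elements():
        rows.append(
            (
                module.name,
                el.name,
                el.description,
                el.value_type.value,
                el.reference_target or "",
                el.lookup_ref or "",
                el.annotation.codesystem,
                el.annotation.code,
                el.annotation.iri,
            )
        )
    lookups = {}
    for name in schema.referenced_lookup_names():
        lst = schema.lookup_lists[name]
        lookups[lookup_filename(name)] = _tsv(
            [("value_en", "description_en", "codesystem", "code", "iri")]
            + [(o.value, o.description, o.codesystem, o.code, o.iri) for o in lst.options]
        )
    return CodebookBundle(info_tsv=info, codebook_tsv=_tsv(rows), lookups=lookups)


_OID_RE = re.compile(r"^\d+(\.\d+)+$")


def generate_artdecor(schema: SemanticSchema, project_oid: str) -> bytes:
    """Simplified ART-DECOR dataset XML: one dataset node, a group concept
    per module, an item concept per element (en-US language-tagged names
    and descriptions) and a valueSet per unique lookup list; ids are
    derived from the project OID plus a running index."""
    if not _OID_RE.match(project_oid or ""):
        raise ValueError(f"malformed project OID {project_oid!r}")

    decor = etree.Element("decor")
    project = etree.SubElement(decor, "project", oid=project_oid)
    etree.SubElement(project, "name", language="en-US").text = schema.name
    dataset = etree.SubElement(
        decor, "dataset", id=f"{project_oid}.1", versionLabel=schema.version
    )
    etree.SubElement(dataset, "name", language="en-US").text = schema.name
    etree.SubElement(dataset, "desc", language="en-US").text = schema.description

    valueset_id = {
        name: f"{project_oid}.2.{i}"
        for i, name in enumerate(schema.referenced_lookup_names(), start=1)
    }
    for mi, module in enumerate(schema.modules, start=1):
        group = etree.SubElement(dataset, "concept", id=f"{project_oid}.1.{mi}", type="group")
        etree.SubElement(group, "name", language="en-US").text = module.name
        etree.SubElement(group, "desc", language="en-US").text = module.description
        for ei, el in enumerate(module.elements, start=1):
            item = etree.SubElement(
                group, "concept", id=f"{project_oid}.1.{mi}.{ei}", type="item"
            )
            etree.SubElement(item, "name", language="en-US").text = el.name
            etree.SubElement(item, "desc", language="en-US").text = el.description
            etree.SubElement(
                item, "valueDomain", type=el.value_type.value
            )
            if el.lookup_ref:
                etree.SubElement(item, "vocabulary", valueSet=valueset_id[el.lookup_ref])

    terminology = etree.SubElement(decor, "terminology")
    for name, vsid in valueset_id.items():
        vs = etree.SubElement(terminology, "valueSet", id=vsid, name=name)
        clist = etree.SubElement(vs, "conceptList")
        for opt in schema.lookup_lists[name].options:
            etree.SubElement(
                clist,
                "concept",
                code=opt.code,
                codeSystem=opt.codesystem,
                displayName=opt.value,
            )
    return etree.tostring(
        decor, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


@register
class EmxGenerator(Generator):
    target_name = "emx"

    def produce(self, schema: SemanticSchema) -> list[tuple[str, bytes]]:
        return generate_emx(schema).files()


@register
class Emx2Generator(Generator):
    target_name = "emx2"

    def produce(self, schema: SemanticSchema) -> list[tuple[str, bytes]]:
        return [(p, t.encode("utf-8")) for p, t in generate_emx2(schema).items()]


@register
class CodebookGenerator(Generator):
    target_name = "codebook"

    def produce(self, schema: SemanticSchema) -> list[tuple[str, bytes]]:
        return generate_codebook(schema).files()


@register
class ArtDecorGenerator(Generator):
    target_name = "artdecor"

    def produce(self, schema: SemanticSchema) -> list[tuple[str, bytes]]:
        return [("dataset.xml", generate_artdecor(schema, self.config.project_oid))]
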