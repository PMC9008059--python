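"""EDC blueprints: EMX import plan, EMX2 file set, codebook, ART-DECOR XML."""

import csv
import io

import pytest
from lxml import etree

from fairschema.fixtures import make_random_schema
from fairschema.generators.edc import (
    emx2_zip_bytes,
    emx_import_plan,
    generate_artdecor,
    generate_codebook,
    generate_emx,
    generate_emx2,
    package_name,
)
from fairschema.model import compute_statistics

OID = "2.16.840.1.113883.2.4.3.11.60.120"


def _tsv_rows(text):
    lines = [l for l in text.split("\n") if l]
    return [tuple(l.split("\t")) for l in lines]


class TestEmx:
    def test_package_namespace(self, mini_schema):
        assert package_name(mini_schema) == "fair-genomes"
        bp = generate_emx(mini_schema)
        assert ("fair-genomes", "FAIR Genomes") == _tsv_rows(bp.package_tsv)[1][:2]

    def test_all_nine_modules_have_entities(self, mini_schema):
        bp = generate_emx(mini_schema)
        entities = {r[0] for r in _tsv_rows(bp.module_definitions_tsv)[1:]}
        entities |= {r[0] for r in _tsv_rows(bp.deferred_references_tsv)[1:]}
        assert len(entities) == 9
        assert all(e.startswith("fair-genomes_") for e in entities)

    def test_cycle_closing_reference_only_in_deferred_patch(self, mini_schema):
        bp = generate_emx(mini_schema)
        patch = _tsv_rows(bp.deferred_references_tsv)[1:]
        assert ("fair-genomes_material", "belongsToDiagnosis", "fair-genomes_clinical") in patch
        main_attrs = {r[1] for r in _tsv_rows(bp.module_definitions_tsv)[1:]}
        assert "belongsToDiagnosis" not in main_attrs
        assert "materialUsedInDiagnosis" in main_attrs

    def test_import_order_stages(self, mini_schema):
        bp = generate_emx(mini_schema)
        order = bp.import_order
        assert order[0] == "sys_md_Package.tsv"
        assert order[1] == "lookup_definitions.tsv"
        assert order[-2:] == ["module_definitions.tsv", "deferred_references.tsv"]
        assert all(f.startswith("data_") for f in order[2:-2])

    def test_noglobals_list_data_has_exactly_base_rows(self, mini_schema):
        bp = generate_emx(mini_schema)
        # inclusion_criteria is used only by a LookupOne_NoGlobals element
        assert len(_tsv_rows(bp.lookup_data["inclusion_criteria"])) == 1 + 3

    def test_globals_materialized_into_injected_lists(self, mini_schema):
        bp = generate_emx(mini_schema)
        rows = _tsv_rows(bp.lookup_data["represented_by"])[1:]
        assert len(rows) == 3 + 16
        assert rows[3][0] == "NoInformation" and rows[-1][0] == "Trace"

    @pytest.mark.parametrize("seed", range(8))
    def test_main_import_order_is_topological(self, seed):
        schema = make_random_schema(
            seed, n_modules=6, n_elements_per_module=4, n_lookup_lists=2, p_reference=0.5
        )
        order, deferred = emx_import_plan(schema)
        assert sorted(order) == sorted(m.name for m in schema.modules)
        deferred_set = set(deferred)
        position = {name: i for i, name in enumerate(order)}
        for module, el in schema.iter_elements():
            if el.value_type.is_reference and (module.name, el.name) not in deferred_set:
                if el.reference_target != module.name:
                    assert position[el.reference_target] < position[module.name]

    @pytest.mark.parametrize("seed", range(8))
    def test_non_deferred_graph_is_acyclic(self, seed):
        schema = make_random_schema(
            seed, n_modules=5, n_elements_per_module=4, n_lookup_lists=2, p_reference=0.6
        )
        _, deferred = emx_import_plan(schema)
        deferred_set = set(deferred)
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(m.name for m in schema.modules)
        for module, el in schema.iter_elements():
            if el.value_type.is_reference and (module.name, el.name) not in deferred_set:
                if el.reference_target != module.name:
                    g.add_edge(module.name, el.reference_target)
        assert nx.is_directed_acyclic_graph(g)

    def test_nothing_deferred_without_cycles(self):
        schema = make_random_schema(4, p_reference=0.0)
        _, deferred = emx_import_plan(schema)
        assert deferred == []


class TestEmx2:
    def test_lookup_csv_count_matches_statistics(self, mini_schema):
        files = generate_emx2(mini_schema)
        stats = compute_statistics(mini_schema)
        lookup_csvs = [f for f in files if f != "molgenis.csv"]
        assert len(lookup_csvs) == stats.n_unique_lookup_lists

    def test_zero_lookup_schema_emits_only_molgenis_csv(self):
        schema = make_random_schema(2, n_lookup_lists=0, p_lookup=0.0)
        assert set(generate_emx2(schema)) == {"molgenis.csv"}

    def test_every_element_row_carries_its_annotation_iri(self, mini_schema):
        files = generate_emx2(mini_schema)
        rows = list(csv.DictReader(io.StringIO(files["molgenis.csv"])))
        by_key = {(r["tableName"], r["columnName"]): r for r in rows}
        for module, el in mini_schema.iter_elements():
            row = by_key[(module.technical_name, el.technical_name)]
            assert row["semantics"] == el.annotation.iri

    def test_reference_columns_point_at_module_tables(self, mini_schema):
        files = generate_emx2(mini_schema)
        rows = list(csv.DictReader(io.StringIO(files["molgenis.csv"])))
        by_key = {(r["tableName"], r["columnName"]): r for r in rows}
        row = by_key[("clinical", "materialUsedInDiagnosis")]
        assert row["columnType"] == "ref_array" and row["refTable"] == "material"

    def test_zip_packaging_is_stable(self, mini_schema):
        files = generate_emx2(mini_schema)
        assert emx2_zip_bytes(files) == emx2_zip_bytes(dict(reversed(files.items())))


class TestCodebook:
    def test_info_carries_schema_metadata(self, mini_schema):
        cb = generate_codebook(mini_schema)
        rows = dict(_tsv_rows(cb.info_tsv)[1:])
        assert rows["version"] == "1.1"
        assert rows["name"] == "FAIR Genomes"
        assert rows["date"] == "2021-07-20"

    def test_lookups_have_language_suffixed_headers(self, mini_schema):
        cb = generate_codebook(mini_schema)
        for text in cb.lookups.values():
            header = _tsv_rows(text)[0]
            assert header[:2] == ("value_en", "description_en")

    def test_codebook_row_count_equals_n_elements(self, mini_schema):
        cb = generate_codebook(mini_schema)
        stats = compute_statistics(mini_schema)
        assert len(_tsv_rows(cb.codebook_tsv)) - 1 == stats.n_elements

    def test_rows_are_module_major(self, mini_schema):
        cb = generate_codebook(mini_schema)
        modules_in_order = [r[0] for r in _tsv_rows(cb.codebook_tsv)[1:]]
        expected = [m.name for m, _ in mini_schema.iter_elements()]
        assert modules_in_order == [m for m in expected]

    def test_schema_structure_recoverable(self, mini_schema):
        """Information loss is limited to formatting: names, types and
        ontology codes survive the codebook."""
        cb = generate_codebook(mini_schema)
        rows = _tsv_rows(cb.codebook_tsv)
        header = rows[0]
        for row in rows[1:]:
            rec = dict(zip(header, row))
            module = mini_schema.module(rec["module"])
            el = next(e for e in module.elements if e.name == rec["element"])
            assert rec["type"] == el.value_type.value
            assert rec["code"] == el.annotation.code


class TestArtDecor:
    def test_default_oid_in_output(self, mini_schema):
        doc = etree.fromstring(generate_artdecor(mini_schema, OID))
        assert doc.find("project").get("oid") == OID
        assert doc.find("dataset").get("id") == OID + ".1"

    def test_concept_count_is_modules_plus_elements(self, mini_schema):
        doc = etree.fromstring(generate_artdecor(mini_schema, OID))
        stats = compute_statistics(mini_schema)
        concepts = doc.findall(".//dataset//concept")
        assert len(concepts) == stats.n_modules + stats.n_elements

    def test_language_tagged_names(self, mini_schema):
        doc = etree.fromstring(generate_artdecor(mini_schema, OID))
        names = doc.findall(".//dataset//concept/name")
        assert names and all(n.get("language") == "en-US" for n in names)

    def test_valuesets_per_lookup_list(self, mini_schema):
        doc = etree.fromstring(generate_artdecor(mini_schema, OID))
        stats = compute_statistics(mini_schema)
        assert len(doc.findall(".//terminology/valueSet")) == stats.n_unique_lookup_lists

    def test_malformed_oid_rejected(self, mini_schema):
        with pytest.raises(ValueError, match="OID"):
            generate_artdecor(mini_schema, "not-an-oid")

    def test_output_is_well_formed_xml(self, mini_schema):
        parser = etree.XMLParser(recover=False)
        etree.fromstring(generate_artdecor(mini_schema, OID), parser=parser)
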