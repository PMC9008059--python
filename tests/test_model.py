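"""Schema model: validation, effective options, reference graph, statistics."""

import pytest

from fairschema.fixtures import make_null_flavors, make_random_schema
from fairschema.model import (
    Element,
    LookupList,
    LookupOption,
    OntologyAnnotation,
    SchemaModule,
    SemanticSchema,
    TermDefinition,
    ValueType,
    compute_statistics,
    effective_options,
    reference_graph,
    to_technical_name,
    validate,
)


def _ann(n):
    return OntologyAnnotation("SYN", f"T{n}", f"https://example.org/t/{n}")


def _tiny_schema(**overrides):
    lst = LookupList(
        "colors",
        [
            LookupOption("Red", "Red color.", "SYN", "C1", "https://example.org/c/1"),
            LookupOption("Blue", "Blue color.", "SYN", "C2", "https://example.org/c/2"),
        ],
    )
    schema = SemanticSchema(
        name="Tiny",
        description="Tiny test schema.",
        version="0.1",
        date="2021-07-20",
        authors=["t"],
        copyright="none",
        license="CC0-1.0",
        modules=[
            SchemaModule(
                "Alpha",
                "First module.",
                _ann(1),
                [
                    Element("Color", "A color.", _ann(2), ValueType.LookupOne, lookup_ref="colors"),
                    Element("Count", "A count.", _ann(3), ValueType.Integer),
                ],
            )
        ],
        lookup_lists={"colors": lst},
    )
    for key, value in overrides.items():
        setattr(schema, key, value)
    return schema


class TestTechnicalName:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("Intended insert size", "intendedInsertSize"),
            ("RepresentedBy", "representedby"),
            ("Percentage TR20", "percentageTr20"),
            ("Leaflet and consent form", "leafletAndConsentForm"),
        ],
    )
    def test_derivation(self, name, expected):
        assert to_technical_name(name) == expected

    def test_no_whitespace_ever(self):
        assert " " not in to_technical_name("  odd   spacing\there ")


class TestValidate:
    def test_mini_fixture_is_clean(self, mini_schema):
        report = validate(mini_schema)
        assert report.ok and not report.errors

    def test_tiny_schema_is_clean(self):
        assert validate(_tiny_schema()).ok

    def test_lookup_type_without_lookup_ref(self):
        schema = _tiny_schema()
        schema.modules[0].elements[0].lookup_ref = None
        report = validate(schema)
        assert not report.ok
        assert any(
            "requires a lookup reference" in i.message and "element:Color" in i.path
            for i in report.errors
        )

    def test_duplicate_module_names(self):
        schema = _tiny_schema()
        clone = SchemaModule("Alpha", "Clone module.", _ann(9), [
            Element("Other", "Other element.", _ann(10), ValueType.String)
        ])
        schema.modules.append(clone)
        report = validate(schema)
        assert any("duplicate module name" in i.message for i in report.errors)

    def test_relative_iri_rejected(self):
        schema = _tiny_schema()
        schema.modules[0].annotation.iri = "ftp://nope"
        assert not validate(schema).ok

    def test_duplicate_annotation_iri(self):
        schema = _tiny_schema()
        schema.modules[0].elements[1].annotation.iri = schema.modules[0].elements[0].annotation.iri
        assert any("already used" in i.message for i in validate(schema).errors)

    def test_global_option_collides_with_base_list(self):
        schema = _tiny_schema(global_lookup_options=make_null_flavors())
        schema.lookup_lists["colors"].options.append(
            LookupOption("Unknown", "Clashes with a null flavor.", "SYN", "C3",
                         "https://example.org/c/3")
        )
        report = validate(schema)
        assert any("collides with a global lookup option" in i.message for i in report.errors)

    def test_of_type_must_differ_from_element_annotation(self):
        schema = _tiny_schema()
        schema.lookup_lists["colors"].of_type = OntologyAnnotation(
            "SYN", "T2", "https://example.org/t/2"
        )
        assert any("must stay separate" in i.message for i in validate(schema).errors)

    def test_unreferenced_list_is_warning_not_error(self):
        schema = _tiny_schema()
        schema.lookup_lists["spare"] = LookupList(
            "spare", [LookupOption("X", "Spare option.", "SYN", "S1", "https://example.org/s/1")]
        )
        report = validate(schema)
        assert report.ok
        assert any("not referenced" in i.message for i in report.warnings)

    def test_tab_in_option_field(self):
        schema = _tiny_schema()
        schema.lookup_lists["colors"].options[0].description = "has\ttab"
        assert not validate(schema).ok

    def test_comma_in_value_of_multi_valued_list(self):
        schema = _tiny_schema()
        schema.modules[0].elements[0].value_type = ValueType.LookupMany
        schema.lookup_lists["colors"].options[0].value = "Red, dark"
        assert any("comma" in i.message for i in validate(schema).errors)

    def test_bad_accession(self):
        schema = _tiny_schema()
        schema.term_definitions.append(
            TermDefinition("FG_123", "Bad", "Bad accession.", "lookup-term")
        )
        assert any("FG_ + 7 digits" in i.message for i in validate(schema).errors)

    @pytest.mark.parametrize("field", ["name", "description", "version", "date", "license"])
    def test_empty_root_field(self, field):
        schema = _tiny_schema(**{field: ""})
        assert any(f"root field {field!r}" in i.message for i in validate(schema).errors)

    def test_validation_is_exhaustive_not_fail_fast(self):
        schema = _tiny_schema(name="", version="")
        schema.modules[0].elements[0].lookup_ref = "missing"
        assert len(validate(schema).errors) >= 3


class TestEffectiveOptions:
    def test_globals_appended_for_lookup_one(self, mini_schema):
        el = mini_schema.module("Personal").elements[2]  # RepresentedBy, base size 3
        opts = effective_options(el, mini_schema)
        assert len(opts) == 3 + 16
        assert [o.value for o in opts[:3]] == ["Self", "Legal guardian", "Authorized representative"]
        assert all(o.is_global for o in opts[3:])

    def test_noglobals_variant_gains_nothing(self, mini_schema):
        el = mini_schema.module("Personal").elements[2]
        el.value_type = ValueType.LookupOne_NoGlobals
        assert len(effective_options(el, mini_schema)) == 3

    def test_zero_globals_gives_base_list(self):
        schema = _tiny_schema()
        el = schema.modules[0].elements[0]
        assert [o.value for o in effective_options(el, schema)] == ["Red", "Blue"]

    def test_non_lookup_element_is_contract_violation(self, mini_schema):
        el = mini_schema.module("Personal").elements[0]  # Date of birth
        with pytest.raises(ValueError):
            effective_options(el, mini_schema)

    def test_inputs_not_mutated(self, mini_schema):
        el = mini_schema.module("Clinical").elements[0]
        before = len(mini_schema.lookup_lists[el.lookup_ref].options)
        effective_options(el, mini_schema)
        assert len(mini_schema.lookup_lists[el.lookup_ref].options) == before

    @pytest.mark.parametrize("seed", range(10))
    def test_length_arithmetic_over_random_fixtures(self, seed):
        schema = make_random_schema(seed, n_modules=3, n_elements_per_module=5, n_lookup_lists=4)
        n_glob = len(schema.global_lookup_options)
        for _, el in schema.iter_elements():
            if not el.value_type.is_lookup:
                continue
            base = len(schema.lookup_lists[el.lookup_ref].options)
            expected = base + (n_glob if el.value_type.includes_globals else 0)
            assert len(effective_options(el, schema)) == expected


def _brute_force_cycles(edges, nodes):
    """Enumerate elementary cycles by path extension (oracle for small graphs)."""
    adjacency = {n: sorted({t for s, t in edges if s == n}) for n in nodes}
    found = set()
    for start in nodes:
        stack = [(start, [start])]
        while stack:
            node, path = stack.pop()
            for nxt in adjacency[node]:
                if nxt == start and len(path) >= 1:
                    k = path.index(min(path))
                    found.add(tuple(path[k:] + path[:k]))
                elif nxt not in path:
                    stack.append((nxt, path + [nxt]))
    return sorted(found, key=lambda c: (len(c), c))


class TestReferenceGraph:
    def test_mini_cycles(self, mini_schema):
        graph, cycles = reference_graph(mini_schema)
        edges = {(u, v, d["label"]) for u, v, d in graph.edges(data=True)}
        assert ("Clinical", "Material", "Material used in diagnosis") in edges
        assert ("Material", "Clinical", "Belongs to diagnosis") in edges
        assert ["Clinical", "Material"] in cycles
        assert ["Personal", "Study"] in cycles

    def test_no_references_no_cycles(self):
        schema = _tiny_schema()
        graph, cycles = reference_graph(schema)
        assert graph.number_of_edges() == 0 and cycles == []

    @pytest.mark.parametrize("seed", range(12))
    def test_cycles_agree_with_brute_force_enumeration(self, seed):
        schema = make_random_schema(
            seed, n_modules=5, n_elements_per_module=4, n_lookup_lists=2, p_reference=0.5
        )
        graph, cycles = reference_graph(schema)
        simple_edges = {(u, v) for u, v, _ in graph.edges(keys=True)}
        oracle = _brute_force_cycles(simple_edges, [m.name for m in schema.modules])
        assert [tuple(c) for c in cycles] == list(oracle)


class TestStatistics:
    def test_mini_counts(self, mini_schema):
        stats = compute_statistics(mini_schema)
        assert stats.n_modules == 9
        assert stats.n_new_terms == 4
        assert stats.n_lookup_elements == 5
        assert stats.n_unique_lookup_lists == 4

    def test_shared_list_counted_per_element_and_once(self):
        schema = _tiny_schema()
        schema.lookup_lists["big"] = LookupList(
            "big",
            [
                LookupOption(f"B{i}", f"Option {i}.", "SYN", f"B{i}", f"https://example.org/b/{i}")
                for i in range(5)
            ],
        )
        module = schema.modules[0]
        module.elements = [
            Element("E1", "Uses big.", _ann(11), ValueType.LookupOne, lookup_ref="big"),
            Element("E2", "Uses big too.", _ann(12), ValueType.LookupMany, lookup_ref="big"),
            Element("E3", "Uses colors.", _ann(13), ValueType.LookupOne, lookup_ref="colors"),
        ]
        schema.lookup_lists["colors"].options = schema.lookup_lists["colors"].options[:2]
        stats = compute_statistics(schema)
        assert stats.total_lookup_options_per_element_sum == 5 + 5 + 2
        assert stats.total_unique_lookup_options == 5 + 2

    def test_no_lookups_all_zero(self):
        schema = _tiny_schema()
        schema.modules[0].elements = [Element("Count", "A count.", _ann(3), ValueType.Integer)]
        schema.lookup_lists = {}
        stats = compute_statistics(schema)
        assert stats.n_lookup_elements == 0
        assert stats.n_unique_lookup_lists == 0
        assert stats.total_lookup_options_per_element_sum == 0
        assert stats.total_unique_lookup_options == 0
        assert stats.min_list is None and stats.max_list is None

    @pytest.mark.parametrize("seed", range(10))
    def test_reuse_identity_against_brute_force(self, seed):
        schema = make_random_schema(seed, n_modules=4, n_elements_per_module=5, n_lookup_lists=3)
        stats = compute_statistics(schema)
        refs = [el.lookup_ref for _, el in schema.iter_elements() if el.lookup_ref]
        excess = sum(
            (refs.count(name) - 1) * len(schema.lookup_lists[name].options)
            for name in set(refs)
        )
        assert (
            stats.total_lookup_options_per_element_sum - stats.total_unique_lookup_options
            == excess
        )
        assert stats.total_lookup_options_per_element_sum >= stats.total_unique_lookup_options
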