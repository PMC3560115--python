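"""Data-type definition, XML round-trips, evolution, suggestion, forms."""

import random

import pytest
from lxml import etree

from metarepo import fixtures
from metarepo.exceptions import (
    EvolutionError,
    SchemaParseError,
    SchemaStructureError,
)
from metarepo.metamodel import (
    AddAttribute,
    AddEnumValue,
    AddGroup,
    AttributeDef,
    LoopDef,
    MakeRequired,
    MetadataGroup,
    OntologyCatalog,
    OntologyTermRef,
    RemovePath,
    SchemaHeader,
    define_datatype,
    evolve_datatype,
    parse_schema,
    render_entry_form,
    serialize_schema,
    suggest_terms,
)


def _header(name="MRI", **kwargs):
    kwargs.setdefault("created_at", "2012-01-01T00:00:00")
    return SchemaHeader(datatype_name=name, **kwargs)


class TestDefine:
    def test_minimal_schema_has_expected_paths(self, mri_schema):
        paths = [p for p, _ in mri_schema.iter_paths()]
        assert paths == [
            ("acquisition", None, "field_strength"),
            ("acquisition", None, "sequence"),
        ]
        assert mri_schema.version == 1

    def test_reagent_loop_type_is_valid(self, reagent_schema):
        loop = reagent_schema.resolve_loop("protocol", "reagent")
        assert [a.name for a in loop.attributes] == [
            "description", "concentration", "amount",
        ]

    def test_risk_factor_enumeration_loop(self):
        schema = define_datatype(
            _header("Clinical"),
            [MetadataGroup("anamnesis", (
                LoopDef("risk_factor", (
                    AttributeDef("factor", "enumeration",
                                 allowed_values=("smoke", "alchool",
                                                 "sedentary job")),
                    AttributeDef("present", "boolean"),
                )),
            ))],
        )
        _, attr = schema.resolve(("anamnesis", "risk_factor", "factor"))
        assert attr.allowed_values == ("smoke", "alchool", "sedentary job")

    def test_case_insensitive_name_collision_rejected(self):
        with pytest.raises(SchemaStructureError, match="(?i)collision.*[Dd]ose"):
            define_datatype(
                _header("T"),
                [MetadataGroup("g", (
                    AttributeDef("Dose", "decimal"),
                    AttributeDef("dose", "decimal"),
                ))],
            )

    def test_empty_groups_rejected(self):
        with pytest.raises(SchemaStructureError):
            define_datatype(_header("T"), [])

    @pytest.mark.parametrize("bad", [
        lambda: AttributeDef("", "text"),
        lambda: AttributeDef("a", "enumeration", allowed_values=()),
        lambda: AttributeDef("a", "integer", default="x"),
        lambda: AttributeDef("a", "enumeration", allowed_values=("x",),
                             default="y"),
        lambda: LoopDef("l", ()),
    ])
    def test_malformed_components_rejected(self, bad):
        with pytest.raises(SchemaStructureError):
            bad()

    def test_version_forced_to_one(self):
        schema = define_datatype(
            _header("T", version=5),
            [MetadataGroup("g", (AttributeDef("a"),))],
        )
        assert schema.version == 1


class TestSerialization:
    def test_round_trip_identity_and_byte_stability(self, reagent_schema):
        doc = serialize_schema(reagent_schema)
        parsed = parse_schema(doc)
        assert parsed == reagent_schema
        assert serialize_schema(parsed) == doc

    def test_document_structure(self, mri_schema):
        root = etree.fromstring(serialize_schema(mri_schema))
        assert [c.tag for c in root] == ["header", "metadata"]
        assert root.get("dialect") == "xtens-1"
        groups = root.findall("metadata/group")
        assert len(groups) == 1
        assert len(groups[0].findall("attribute")) == 2

    def test_loop_members_enclosed_in_loop_element(self, reagent_schema):
        root = etree.fromstring(serialize_schema(reagent_schema))
        group = root.find("metadata/group")
        assert len(group.findall("attribute")) == 1  # plain only
        loop = group.find("loop")
        assert loop.get("name") == "reagent"
        assert len(loop.findall("attribute")) == 3

    def test_missing_header_names_header(self):
        with pytest.raises(SchemaParseError, match="header"):
            parse_schema(b"<datatype><metadata/></datatype>")

    def test_unknown_element_reports_path(self):
        doc = (b"<datatype><header><name>T</name></header>"
               b"<metadata><bogus/></metadata></datatype>")
        with pytest.raises(SchemaParseError, match="bogus"):
            parse_schema(doc)

    def test_handwritten_reagent_document(self, reagent_schema):
        doc = """<?xml version="1.0" encoding="UTF-8"?>
        <datatype dialect="xtens-1">
          <header>
            <name>Microarray Assay</name><version>1</version>
            <description></description><fileAssociated>false</fileAssociated>
            <createdBy></createdBy><createdAt>2012-01-01T00:00:00</createdAt>
          </header>
          <metadata>
            <group name="protocol">
              <attribute name="platform" type="text" required="false"/>
              <loop name="reagent">
                <attribute name="description" type="text" required="true"/>
                <attribute name="concentration" type="decimal" required="true"/>
                <attribute name="amount" type="decimal" required="true"/>
              </loop>
            </group>
          </metadata>
        </datatype>"""
        assert parse_schema(doc) == reagent_schema

    def test_round_trip_property_over_random_schemas(self):
        rng = random.Random(2012)
        for _ in range(40):
            schema = fixtures.random_schema(rng)
            doc = serialize_schema(schema)
            assert parse_schema(doc) == schema
            assert serialize_schema(parse_schema(doc)) == doc


class TestEvolution:
    def test_add_optional_attribute_bumps_version(self, mri_schema):
        evolved = evolve_datatype(
            mri_schema,
            [AddAttribute("acquisition", AttributeDef("contrast_agent"))],
            has_instances=True,
        )
        assert evolved.version == 2
        assert evolved.resolve(("acquisition", None, "contrast_agent"))

    def test_empty_change_list_is_identity(self, mri_schema):
        assert evolve_datatype(mri_schema, []) is mri_schema

    def test_required_addition_without_default_rejected(self, mri_schema):
        with pytest.raises(EvolutionError, match="required"):
            evolve_datatype(
                mri_schema,
                [AddAttribute("acquisition",
                              AttributeDef("mandatory", required=True))],
                has_instances=True,
            )

    def test_destructive_changes_rejected_with_instances(self, mri_schema):
        for change in (
            RemovePath(("acquisition", None, "sequence")),
            MakeRequired(("acquisition", None, "field_strength")),
        ):
            with pytest.raises(EvolutionError, match="destructive"):
                evolve_datatype(mri_schema, [change], has_instances=True)

    def test_destructive_change_allowed_on_empty_store(self, mri_schema):
        evolved = evolve_datatype(
            mri_schema,
            [RemovePath(("acquisition", None, "sequence"))],
            has_instances=False,
        )
        assert evolved.resolve(("acquisition", None, "sequence")) is None

    def test_add_enum_value_and_group(self):
        schema = define_datatype(
            _header("T"),
            [MetadataGroup("g", (
                AttributeDef("status", "enumeration",
                             allowed_values=("known",)),
            ))],
        )
        evolved = evolve_datatype(
            schema,
            [
                AddEnumValue(("g", None, "status"), "novel"),
                AddGroup(MetadataGroup("extra", (AttributeDef("note"),))),
            ],
            has_instances=True,
        )
        _, attr = evolved.resolve(("g", None, "status"))
        assert attr.allowed_values == ("known", "novel")
        assert evolved.group("extra") is not None

    def test_additive_evolution_keeps_instances_valid(self):
        from metarepo.records import validate_instance

        rng = random.Random(99)
        for _ in range(20):
            schema = fixtures.random_schema(rng)
            instance = fixtures.random_conforming_instance(rng, schema)
            assert validate_instance(instance, schema) == []
            evolved = evolve_datatype(
                schema,
                [AddAttribute(schema.groups[0].name,
                              AttributeDef("added_later"))],
                has_instances=True,
            )
            pinned = instance.__class__(**{
                **instance.__dict__, "datatype_version": evolved.version,
            })
            assert validate_instance(pinned, evolved) == []


class TestSuggestion:
    CATALOG = OntologyCatalog("OBI", [
        OntologyTermRef("OBI", "OBI:1", "assay"),
        OntologyTermRef("OBI", "OBI:2", "Analyte"),
        OntologyTermRef("OBI", "OBI:3", "age"),
        OntologyTermRef("OBI", "OBI:4", "dose"),
        OntologyTermRef("OBI", "OBI:5", "dosage form"),
    ])

    def test_full_label_prefix_returns_term(self):
        labels = [t.label for t in suggest_terms("assay", self.CATALOG)]
        assert labels == ["assay"]

    def test_unmatched_prefix_returns_empty(self):
        assert suggest_terms("zzzz_nonexistent", self.CATALOG) == []

    def test_no_ontology_loaded_returns_empty(self):
        assert suggest_terms("a", None) == []

    def test_prefix_filter_matches_brute_force(self):
        got = [t.label for t in suggest_terms("a", self.CATALOG)]
        expected = sorted(
            (t.label for t in self.CATALOG.terms
             if t.label.lower().startswith("a")),
            key=str.lower,
        )
        assert got == expected == ["age", "Analyte", "assay"]

    def test_limit_caps_results(self):
        assert len(suggest_terms("d", self.CATALOG, limit=1)) == 1

    def test_obo_loading(self, tmp_path):
        obo = tmp_path / "mini.obo"
        obo.write_text(
            "format-version: 1.2\nontology: obi\n\n"
            "[Term]\nid: OBI:0000001\nname: assay\n\n"
            "[Term]\nid: OBI:0000002\nname: analyte\n\n"
            "[Typedef]\nid: part_of\nname: part of\n"
        )
        catalog = OntologyCatalog.from_obo(obo)
        assert {t.label for t in catalog.terms} == {"assay", "analyte"}
        assert suggest_terms("ass", catalog)[0].term_id == "OBI:0000001"


class TestEntryForm:
    def test_one_control_per_attribute(self, mri_schema):
        root = etree.fromstring(render_entry_form(mri_schema))
        inputs = root.findall(".//input")
        names = {i.get("name") for i in inputs}
        assert names == {"acquisition.field_strength", "acquisition.sequence"}

    def test_enumeration_renders_as_select(self):
        schema = define_datatype(
            _header("T"),
            [MetadataGroup("g", (
                AttributeDef("status", "enumeration",
                             allowed_values=("known", "novel")),
            ))],
        )
        root = etree.fromstring(render_entry_form(schema))
        options = root.findall(".//select/option")
        assert [o.get("value") for o in options] == ["known", "novel"]

    def test_required_attributes_marked(self, mri_schema):
        html = render_entry_form(mri_schema)
        root = etree.fromstring(html)
        assert len(root.findall(".//span[@class='required']")) == 2

    def test_loop_renders_repeatable_row(self, reagent_schema):
        root = etree.fromstring(render_entry_form(reagent_schema))
        loop_fs = root.find(".//fieldset[@data-loop='reagent']")
        assert loop_fs is not None
        row_controls = loop_fs.findall(".//div[@class='loop-row']//input")
        assert len(row_controls) == 3
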