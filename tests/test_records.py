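"""Instance validation, XML round-trips, mutation detection, file refs."""

import dataclasses
import random
from decimal import Decimal

import pytest
from lxml import etree

from metarepo import fixtures
from metarepo.exceptions import (
    AssociationError,
    SchemaParseError,
    ValidationUsageError,
)
from metarepo.records import (
    AttributeValue,
    DataInstance,
    FileRef,
    LoopInstance,
    Subject,
    attach_file,
    parse_instance,
    serialize_instance,
    validate_instance,
)


def _mri_instance(mri_schema, **overrides):
    base = dict(
        instance_id="D1",
        datatype_name="MRI",
        datatype_version=1,
        subject_id="S001",
        values=(
            AttributeValue(("acquisition", None, "field_strength"),
                           Decimal("1.5")),
            AttributeValue(("acquisition", None, "sequence"), "T1 MPRAGE"),
        ),
    )
    base.update(overrides)
    return DataInstance(**base)


def _reagent_instance(n_iterations=3):
    iterations = tuple(
        (
            AttributeValue(("protocol", "reagent", "description"), f"r{i}"),
            AttributeValue(("protocol", "reagent", "concentration"),
                           Decimal(i + 1)),
            AttributeValue(("protocol", "reagent", "amount"),
                           Decimal("0.5") * (i + 1)),
        )
        for i in range(n_iterations)
    )
    return DataInstance(
        instance_id="D2",
        datatype_name="Microarray Assay",
        datatype_version=1,
        subject_id=None,
        values=(AttributeValue(("protocol", None, "platform"), "chipX"),),
        loops=(LoopInstance(("protocol", "reagent"), iterations),),
    )


class TestValidation:
    def test_complete_instance_passes(self, mri_schema):
        assert validate_instance(_mri_instance(mri_schema), mri_schema) == []

    def test_reagent_iterations_pass(self, reagent_schema):
        report = validate_instance(_reagent_instance(), reagent_schema)
        assert report == []

    def test_missing_required_attribute_named_exactly_once(self, mri_schema):
        instance = _mri_instance(
            mri_schema,
            values=(AttributeValue(("acquisition", None, "field_strength"),
                                   Decimal("3")),),
        )
        report = validate_instance(instance, mri_schema)
        assert len(report) == 1
        assert report[0].path == "acquisition.sequence"
        assert "required" in report[0].reason

    def test_unknown_path_is_violation_not_crash(self, mri_schema):
        instance = _mri_instance(
            mri_schema,
            values=_mri_instance(mri_schema).values
            + (AttributeValue(("acquisition", None, "bogus"), "x"),),
        )
        report = validate_instance(instance, mri_schema)
        assert [v.path for v in report] == ["acquisition.bogus"]

    def test_kind_violation_reported(self, mri_schema):
        instance = _mri_instance(
            mri_schema,
            values=(
                AttributeValue(("acquisition", None, "field_strength"), "abc"),
                AttributeValue(("acquisition", None, "sequence"), "T1"),
            ),
        )
        report = validate_instance(instance, mri_schema)
        assert report and report[0].path == "acquisition.field_strength"

    def test_schema_mismatch_is_usage_error(self, mri_schema, reagent_schema):
        with pytest.raises(ValidationUsageError):
            validate_instance(_mri_instance(mri_schema), reagent_schema)

    def test_files_on_non_file_type_flagged(self, reagent_schema):
        instance = dataclasses.replace(
            _reagent_instance(), files=(FileRef("file:///x"),)
        )
        report = validate_instance(instance, reagent_schema)
        assert any("file-associated" in v.reason for v in report)

    def test_empty_loop_is_valid(self, reagent_schema):
        instance = dataclasses.replace(_reagent_instance(0), loops=())
        assert validate_instance(instance, reagent_schema) == []

    def test_random_conforming_instances_validate_clean(self):
        rng = random.Random(7)
        for _ in range(30):
            schema = fixtures.random_schema(rng)
            instance = fixtures.random_conforming_instance(rng, schema)
            assert validate_instance(instance, schema) == []

    def test_single_mutation_detected_at_mutated_path(self):
        """Dropping a required value or corrupting a kind yields a report
        naming exactly the touched path."""
        rng = random.Random(13)
        checked = 0
        while checked < 25:
            schema = fixtures.random_schema(rng)
            instance = fixtures.random_conforming_instance(rng, schema)
            required_plain = [
                i for i, av in enumerate(instance.values)
                if schema.resolve(av.path)[1].required
                and schema.resolve(av.path)[1].default is None
            ]
            if not required_plain:
                continue
            idx = rng.choice(required_plain)
            target = instance.values[idx]
            mutated = dataclasses.replace(
                instance,
                values=instance.values[:idx] + instance.values[idx + 1:],
            )
            report = validate_instance(mutated, schema)
            assert len(report) >= 1
            expected = ".".join(p for p in target.path if p)
            assert any(v.path == expected for v in report), (report, expected)
            checked += 1


class TestSerialization:
    def test_round_trip_identity(self, reagent_schema):
        instance = _reagent_instance()
        doc = serialize_instance(instance)
        assert parse_instance(doc, reagent_schema,
                              instance_id="D2") == instance

    def test_loop_element_count_matches_iterations(self, reagent_schema):
        root = etree.fromstring(serialize_instance(_reagent_instance(3)))
        assert len(root.findall(".//loop[@name='reagent']/iteration")) == 3

    def test_kind_violation_in_document_rejected(self, mri_schema):
        doc = """<data datatype="MRI" version="1" subject="S001">
          <group name="acquisition">
            <attribute name="field_strength">abc</attribute>
            <attribute name="sequence">T1</attribute>
          </group></data>"""
        with pytest.raises(SchemaParseError, match="field_strength"):
            parse_instance(doc, mri_schema)

    def test_datatype_mismatch_rejected(self, mri_schema):
        doc = '<data datatype="Other" version="1"><group name="g"/></data>'
        with pytest.raises(SchemaParseError, match="datatype"):
            parse_instance(doc, mri_schema)

    def test_random_instance_round_trips(self):
        rng = random.Random(31)
        for _ in range(25):
            schema = fixtures.random_schema(rng)
            instance = fixtures.random_conforming_instance(rng, schema)
            doc = serialize_instance(instance)
            assert parse_instance(doc, schema, instance_id="R1") == instance


class TestFiles:
    def test_attach_grows_file_list(self, mri_schema):
        instance = _mri_instance(mri_schema)
        out = attach_file(instance, FileRef("file:///scan.dcm"), mri_schema)
        assert len(out.files) == 1 and instance.files == ()

    def test_attach_to_clinical_type_rejected(self, reagent_schema):
        with pytest.raises(AssociationError, match="not file-associated"):
            attach_file(_reagent_instance(), FileRef("file:///x"),
                        reagent_schema)

    def test_two_uris_retained_in_order(self, mri_schema):
        out = _mri_instance(mri_schema)
        out = attach_file(out, FileRef("file:///a"), mri_schema)
        out = attach_file(out, FileRef("file:///b"), mri_schema)
        assert [f.uri for f in out.files] == ["file:///a", "file:///b"]


def test_subject_type_has_no_personal_name_slot():
    """Anonymity by construction: no field could hold a person's name."""
    field_names = {f.name for f in dataclasses.fields(Subject)}
    assert field_names == {"subject_id", "sex", "birth_date", "diagnosis"}
    assert not any("name" in f for f in field_names)
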