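"""Dynamic query composition, execution vs brute-force oracle, overviews."""

import random
from decimal import Decimal

import pytest

from helpers import brute_force_query, snapshot
from metarepo import fixtures
from metarepo.exceptions import CompositionError, NotFoundError
from metarepo.query import (
    DataCondition,
    QuerySpec,
    SubjectCondition,
    compose_query,
    execute_query,
    list_fields,
    subject_overview,
)


class TestListFields:
    def test_enumerates_all_paths(self, bootstrapped_store):
        paths = list_fields(bootstrapped_store, "Genetic Variant")
        assert ("variant", None, "gene") in paths
        assert len(paths) == 5

    def test_loop_paths_are_loop_qualified(self, bootstrapped_store):
        paths = list_fields(bootstrapped_store, "Clinical Evaluation")
        assert ("examination", "risk_factor", "factor") in paths

    def test_unknown_datatype_not_found(self, bootstrapped_store):
        with pytest.raises(NotFoundError):
            list_fields(bootstrapped_store, "nope")


class TestCompose:
    def test_worked_example_conditions_compose(self, cohort_store):
        spec = compose_query(
            cohort_store,
            [
                SubjectCondition("sex", "eq", "male"),
                SubjectCondition("diagnosis", "contains", "Amnestic MCI"),
            ],
            [
                DataCondition("Clinical Evaluation", "field",
                              path=("examination", "risk_factor", "factor"),
                              operator="eq", value="smoke"),
                DataCondition("Genetic Variant", "field",
                              path=("variant", None, "gene"),
                              operator="eq", value="MAPT"),
                DataCondition("MRI", "exists"),
            ],
        )
        assert len(spec.subject_conditions) == 2
        assert len(spec.data_conditions) == 3

    def test_empty_spec_is_valid_and_matches_all(self, cohort_store):
        spec = compose_query(cohort_store)
        assert execute_query(cohort_store, spec) == \
            [s.subject_id for s in cohort_store.list_subjects()]

    def test_ordering_operator_on_sex_rejected(self, cohort_store):
        with pytest.raises(CompositionError, match="ordering"):
            compose_query(
                cohort_store, [SubjectCondition("sex", "lt", "male")]
            )

    def test_unknown_path_rejected_at_composition(self, cohort_store):
        with pytest.raises(CompositionError, match="unknown path"):
            compose_query(cohort_store, [], [
                DataCondition("MRI", "field",
                              path=("acquisition", None, "bogus"),
                              operator="eq", value="x"),
            ])

    def test_unknown_datatype_rejected(self, cohort_store):
        with pytest.raises(CompositionError, match="unknown datatype"):
            compose_query(cohort_store, [],
                          [DataCondition("Nope", "exists")])

    def test_operator_kind_mismatch_rejected(self, cohort_store):
        with pytest.raises(CompositionError):
            compose_query(cohort_store, [], [
                DataCondition("Neuropsychological Tests", "field",
                              path=("battery", None, "rey_delayed_recall"),
                              operator="contains", value="6"),
            ])

    def test_spec_serializes_to_json(self, cohort_store):
        spec = compose_query(
            cohort_store,
            [SubjectCondition("sex", "eq", "male")],
            [DataCondition("MRI", "exists")],
        )
        doc = spec.to_json()
        assert doc["subject"][0]["field"] == "sex"
        assert doc["data"][0]["mode"] == "exists"


class TestExecute:
    def test_rey_delayed_recall_below_six(self, cohort_store):
        """Subjects scoring < 6 words on the delayed recall measure."""
        spec = compose_query(cohort_store, [], [
            DataCondition("Neuropsychological Tests", "field",
                          path=("battery", None, "rey_delayed_recall"),
                          operator="lt", value=6),
        ])
        got = execute_query(cohort_store, spec)
        assert got == brute_force_query(snapshot(cohort_store), spec)
        assert got  # the seeded cohort contains impaired subjects

    def test_full_worked_query_matches_oracle(self, cohort_store):
        """Male amnestic-MCI smokers with a MAPT variant and >=1 MRI."""
        spec = compose_query(
            cohort_store,
            [
                SubjectCondition("sex", "eq", "male"),
                SubjectCondition("diagnosis", "contains", "Amnestic MCI"),
            ],
            [
                DataCondition("Clinical Evaluation", "field",
                              path=("examination", "risk_factor", "factor"),
                              operator="eq", value="smoke"),
                DataCondition("Genetic Variant", "field",
                              path=("variant", None, "gene"),
                              operator="eq", value="MAPT"),
                DataCondition("MRI", "exists"),
            ],
        )
        assert execute_query(cohort_store, spec) == \
            brute_force_query(snapshot(cohort_store), spec)

    def test_random_specs_match_oracle(self, cohort_store):
        snap = snapshot(cohort_store)
        rng = random.Random(111)
        for _ in range(60):
            spec = fixtures.random_query_spec(rng, cohort_store)
            assert execute_query(cohort_store, spec) == \
                brute_force_query(snap, spec), spec

    def test_adding_conditions_never_enlarges_results(self, cohort_store):
        rng = random.Random(222)
        for _ in range(20):
            spec = fixtures.random_query_spec(rng, cohort_store)
            narrowed = QuerySpec(
                subject_conditions=spec.subject_conditions
                + (SubjectCondition("sex", "eq", "female"),),
                data_conditions=spec.data_conditions,
            )
            assert set(execute_query(cohort_store, narrowed)) <= \
                set(execute_query(cohort_store, spec))

    def test_composition_soundness(self, cohort_store):
        rng = random.Random(333)
        for _ in range(30):
            spec = fixtures.random_query_spec(rng, cohort_store)
            execute_query(cohort_store, spec)  # never raises


class TestOverview:
    def test_sections_cover_all_datatypes_with_correct_counts(
        self, cohort_store
    ):
        overview = subject_overview(cohort_store, "S001")
        counts = {name: len(instances)
                  for name, instances in overview.sections}
        for name, _version in cohort_store.list_datatypes():
            expected = len(cohort_store.list_instances(
                datatype_name=name, subject_id="S001"))
            assert counts[name] == expected

    def test_subject_without_data_gets_empty_sections(self, bootstrapped_store):
        from metarepo.records import Subject

        bootstrapped_store.save_subject(Subject("S-EMPTY", "female"))
        overview = subject_overview(bootstrapped_store, "S-EMPTY")
        assert all(len(instances) == 0 for _, instances in overview.sections)
        assert overview.timeline == ()

    def test_unknown_subject_not_found(self, cohort_store):
        with pytest.raises(NotFoundError):
            subject_overview(cohort_store, "S999")

    def test_renderings_include_values_files_and_timeline(self, cohort_store):
        overview = subject_overview(cohort_store, "S001")
        text = overview.render_text()
        assert "Subject S001" in text
        assert "rey_delayed_recall" in text
        assert "Timeline:" in text
        html = overview.render_html()
        assert "subject-overview" in html and "data-datatype" in html

    def test_loop_values_display_one_based_iterations(self, cohort_store):
        for subject in cohort_store.list_subjects():
            text = subject_overview(cohort_store,
                                    subject.subject_id).render_text()
            if "risk_factor" in text:
                assert "risk_factor[1]" in text
                assert "risk_factor[0]" not in text
                break
        else:
            pytest.fail("no subject with risk factors in seeded cohort")
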