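"""DICOM round trips, modality detection, atomic registration."""

import datetime
import random
from decimal import Decimal

import pytest

from metarepo import fixtures, imaging
from metarepo.exceptions import ModalityRejection
from metarepo.imaging import (
    default_profiles,
    detect_modality,
    extract_metadata,
    register_imaging,
    write_synthetic_dicom,
)
from metarepo.records import Subject


@pytest.fixture()
def imaging_store(bootstrapped_store):
    bootstrapped_store.save_subject(
        Subject("S001", "male", "1950-01-01", "Control")
    )
    return bootstrapped_store


def _mr_file(tmp_path, name="scan.dcm", series="T1 MPRAGE", **extra):
    tags = {
        "SeriesDescription": series,
        "StudyDate": "20120301",
        "EchoTime": "30",
        "RepetitionTime": "2000",
        "MagneticFieldStrength": "1.5",
    }
    tags.update(extra)
    return write_synthetic_dicom("MR", tags, tmp_path / name,
                                 uid_entropy=name)


class TestDetection:
    @pytest.mark.parametrize("code,series,expected", [
        ("MR", "T1 MPRAGE", "MRI"),
        ("MR", "fMRI BOLD task", "fMRI"),
        ("MR", "resting-state bold epi", "fMRI"),
        ("PT", "FDG PET", "PET"),
        ("NM", "perfusion", "SPECT"),
    ])
    def test_modality_mapping(self, tmp_path, code, series, expected):
        path = write_synthetic_dicom(
            code, {"SeriesDescription": series}, tmp_path / "f.dcm",
            uid_entropy="t",
        )
        assert detect_modality(path) == expected

    def test_renamed_text_file_rejected_as_not_dicom(self, tmp_path):
        path = tmp_path / "fake.dcm"
        path.write_text("this is not an image")
        with pytest.raises(ModalityRejection, match="not DICOM"):
            detect_modality(path)

    def test_unmapped_modality_rejected_with_reason(self, tmp_path):
        path = tmp_path / "ct.dcm"
        write_synthetic_dicom("MR", {}, path, uid_entropy="ct")
        import pydicom

        dataset = pydicom.dcmread(str(path))
        dataset.Modality = "CT"
        dataset.save_as(str(path), enforce_file_format=True)
        with pytest.raises(ModalityRejection, match="unmapped modality"):
            detect_modality(path)

    def test_unreadable_file_is_io_error_not_rejection(self, tmp_path):
        with pytest.raises(OSError):
            detect_modality(tmp_path / "missing.dcm")


class TestExtraction:
    def test_written_values_extracted_exactly(self, imaging_store, tmp_path):
        path = _mr_file(tmp_path)
        values = extract_metadata(path, default_profiles()["MRI"],
                                  store=imaging_store)
        by_attr = {av.path[2]: av.value for av in values}
        assert by_attr == {
            "sequence": "T1 MPRAGE",
            "study_date": datetime.date(2012, 3, 1),
            "echo_time": Decimal("30"),
            "repetition_time": Decimal("2000"),
            "field_strength": Decimal("1.5"),
        }

    def test_missing_optional_tag_skipped(self, imaging_store, tmp_path):
        path = write_synthetic_dicom(
            "PT", {"SeriesDescription": "FDG"}, tmp_path / "p.dcm",
            uid_entropy="p",
        )
        values = extract_metadata(path, default_profiles()["PET"],
                                  store=imaging_store)
        assert "radiopharmaceutical" not in {av.path[2] for av in values}

    def test_patient_identifying_tags_never_mapped(self):
        from metarepo.imaging import ModalityProfile, TagMapping

        with pytest.raises(ValueError, match="identifying"):
            ModalityProfile(
                "MRI", "MRI", "MRI acquisition",
                (TagMapping("PatientName", ("acquisition", None, "sequence")),),
            )

    def test_random_tag_values_round_trip(self, imaging_store, tmp_path):
        rng = random.Random(55)
        for i in range(10):
            echo = str(rng.randint(1, 200))
            series = rng.choice(("T1", "T2 FLAIR", "DWI"))
            path = _mr_file(tmp_path, name=f"r{i}.dcm", series=series,
                            EchoTime=echo)
            values = extract_metadata(path, default_profiles()["MRI"],
                                      store=imaging_store)
            by_attr = {av.path[2]: av.value for av in values}
            assert by_attr["echo_time"] == Decimal(echo)
            assert by_attr["sequence"] == series


class TestRegistration:
    def _process(self, store):
        taxonomy = fixtures.study_taxonomy(store)
        return taxonomy, taxonomy.create_process("Visit", "Baseline",
                                                 subject_id="S001")

    def test_one_instance_one_event_created(self, imaging_store, tmp_path):
        taxonomy, process = self._process(imaging_store)
        path = _mr_file(tmp_path)
        instance, event = register_imaging(
            imaging_store, path, "S001", process, taxonomy
        )
        assert instance.datatype_name == "MRI"
        assert event.type_name == "MRI acquisition"
        assert event.data == (instance.instance_id,)
        assert [f.uri for f in instance.files] == [path.resolve().as_uri()]
        assert imaging_store.list_instances(datatype_name="MRI") == \
            [instance.instance_id]

    def test_rejected_file_leaves_store_untouched(self, imaging_store,
                                                  tmp_path):
        taxonomy, process = self._process(imaging_store)
        fake = tmp_path / "fake.dcm"
        fake.write_text("nope")
        before = imaging_store.row_counts()
        with pytest.raises(ModalityRejection):
            register_imaging(imaging_store, fake, "S001", process, taxonomy)
        assert imaging_store.row_counts() == before

    def test_two_files_two_events_in_order(self, imaging_store, tmp_path):
        taxonomy, process = self._process(imaging_store)
        for name in ("a.dcm", "b.dcm"):
            register_imaging(imaging_store, _mr_file(tmp_path, name=name),
                             "S001", process, taxonomy)
        timeline = imaging_store.subject_timeline("S001")
        assert len(timeline) == 2
        assert [e["data"][0] for e in timeline] == \
            sorted(e["data"][0] for e in timeline)

    def test_modality_routes_to_matching_datatype_and_event(
        self, imaging_store, tmp_path
    ):
        taxonomy, process = self._process(imaging_store)
        path = write_synthetic_dicom(
            "PT",
            {"SeriesDescription": "FDG", "StudyDate": "20120301",
             "Radiopharmaceutical": "F-18 FDG"},
            tmp_path / "pet.dcm", uid_entropy="pet",
        )
        instance, event = register_imaging(
            imaging_store, path, "S001", process, taxonomy
        )
        assert instance.datatype_name == "PET"
        assert event.type_name == "PET acquisition"


class TestSyntheticWriter:
    def test_unsupported_modality_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unsupported modality"):
            write_synthetic_dicom("XA", {}, tmp_path / "x.dcm")

    def test_seeded_batch_has_distinct_sop_instance_uids(self, tmp_path):
        import pydicom

        uids = set()
        for i in range(5):
            path = write_synthetic_dicom(
                "MR", {"SeriesDescription": "T1"}, tmp_path / f"{i}.dcm",
                uid_entropy=f"batch-{i}",
            )
            uids.add(pydicom.dcmread(str(path)).SOPInstanceUID)
        assert len(uids) == 5

    def test_same_entropy_reproduces_identical_uid(self, tmp_path):
        import pydicom

        paths = [
            write_synthetic_dicom("MR", {}, tmp_path / f"s{i}.dcm",
                                  uid_entropy="same")
            for i in range(2)
        ]
        a, b = (pydicom.dcmread(str(p)).SOPInstanceUID for p in paths)
        assert a == b
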