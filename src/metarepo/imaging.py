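"""Automatic DICOM metadata extraction for imaging data types.

For the predefined imaging data types (MRI, fMRI, PET, SPECT) metadata
entry is automated: the DICOM header of an uploaded file is read, its
Modality tag mapped through a profile set (MR→MRI, PT→PET, NM→SPECT;
fMRI split from MR by a configurable series-description pattern, since
DICOM has no fMRI modality code), the mapped header tags converted into
typed attribute values of the target data type, the file attached by
URI, and an acquisition event of the modality's event type appended to
the given process — all in one transaction.  A file that is not DICOM,
or whose modality has no profile, is rejected with a reason and the
store is left untouched; file-type checking thus happens before upload.

Patient-identifying DICOM tags (PatientName, PatientID, PatientBirthDate)
are never extracted or stored, consistent with fully anonymized subject
records.

:func:`write_synthetic_dicom` writes minimal valid DICOM files for
fixtures and tests; the files it writes round-trip exactly through
:func:`extract_metadata`.  Synthetic PT/NM files carry the
Radiopharmaceutical tag (0018,0031) as a top-level element — a fixture
simplification; real files nest it in a sequence.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Any, Optional, Sequence

import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.errors import InvalidDicomError
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .exceptions import ExtractionError, ModalityRejection, NotFoundError
from .metamodel import AttributePath
from .process_event import Event, Process, Taxonomy
from .records import AttributeValue, DataInstance, FileRef
from .storage import Store
from .values import parse_value

#: default rule separating functional MR series from structural ones
FMRI_SERIES_PATTERN = re.compile(r"fmri|bold", re.IGNORECASE)

_SOP_CLASS = {
    "MR": "1.2.840.10008.5.1.4.1.1.4",  # MR Image Storage
    "PT": "1.2.840.10008.5.1.4.1.1.128",  # PET Image Storage
    "NM": "1.2.840.10008.5.1.4.1.1.20",  # NM Image Storage
}

#: DICOM tags that must never be extracted or stored
EXCLUDED_TAGS = frozenset({"PatientName", "PatientID", "PatientBirthDate"})


@dataclass(frozen=True)
class TagMapping:
    """One (DICOM keyword → attribute path) extraction rule."""

    keyword: str
    path: AttributePath
    required: bool = False


@dataclass(frozen=True)
class ModalityProfile:
    """How one modality maps onto a data type and an event type."""

    modality: str  # MRI | fMRI | PET | SPECT
    datatype_name: str
    event_type: str
    tag_map: tuple[TagMapping, ...]

    def __post_init__(self):
        object.__setattr__(self, "tag_map", tuple(self.tag_map))
        for mapping in self.tag_map:
            if mapping.keyword in EXCLUDED_TAGS:
                raise ValueError(
                    f"patient-identifying tag {mapping.keyword} must not "
                    "be extracted"
                )


def default_profiles() -> dict[str, ModalityProfile]:
    """Minimal built-in tag maps; extensible in configuration."""
    mr_tags = (
        TagMapping("SeriesDescription", ("acquisition", None, "sequence")),
        TagMapping("StudyDate", ("acquisition", None, "study_date")),
        TagMapping("EchoTime", ("acquisition", None, "echo_time")),
        TagMapping("RepetitionTime", ("acquisition", None, "repetition_time")),
        TagMapping("MagneticFieldStrength",
                   ("acquisition", None, "field_strength")),
    )
    nuc_tags = (
        TagMapping("Radiopharmaceutical",
                   ("acquisition", None, "radiopharmaceutical")),
        TagMapping("StudyDate", ("acquisition", None, "study_date")),
        TagMapping("SeriesDescription", ("acquisition", None, "sequence")),
    )
    return {
        "MRI": ModalityProfile("MRI", "MRI", "MRI acquisition", mr_tags),
        "fMRI": ModalityProfile("fMRI", "fMRI", "fMRI acquisition", mr_tags),
        "PET": ModalityProfile("PET", "PET", "PET acquisition", nuc_tags),
        "SPECT": ModalityProfile("SPECT", "SPECT", "SPECT acquisition",
                                 nuc_tags),
    }


# ---------------------------------------------------------------------------
# detection


def detect_modality(
    path: str | Path,
    profiles: Optional[dict[str, ModalityProfile]] = None,
    fmri_pattern: re.Pattern = FMRI_SERIES_PATTERN,
) -> str:
    """Map a file's DICOM Modality tag onto a configured profile.

    Raises :class:`ModalityRejection` for readable non-DICOM files and
    for modalities with no profile; OS errors for unreadable files pass
    through untouched.
    """
    profiles = profiles if profiles is not None else default_profiles()
    dataset = _read(path)
    modality_code = getattr(dataset, "Modality", None)
    if not modality_code:
        raise ModalityRejection("no Modality tag in DICOM header")
    if modality_code == "MR":
        series = str(getattr(dataset, "SeriesDescription", "") or "")
        name = "fMRI" if fmri_pattern.search(series) else "MRI"
    elif modality_code == "PT":
        name = "PET"
    elif modality_code == "NM":
        name = "SPECT"
    else:
        raise ModalityRejection(
            f"unmapped modality {modality_code!r}: no profile configured"
        )
    if name not in profiles:
        raise ModalityRejection(
            f"unmapped modality {name!r}: no profile configured"
        )
    return name


def _read(path: str | Path) -> Dataset:
    with open(path, "rb") as handle:  # surfaces OSError before parsing
        pass
    try:
        return pydicom.dcmread(str(path))
    except InvalidDicomError as exc:
        raise ModalityRejection(f"not DICOM: {exc}") from exc


# ---------------------------------------------------------------------------
# extraction


def extract_metadata(
    path: str | Path,
    profile: ModalityProfile,
    schema=None,
    store: Optional[Store] = None,
) -> list[AttributeValue]:
    """One attribute value per mapped tag present in the file.

    Values are converted to the target attribute's kind (taken from the
    profile's data type, loaded from *store* or passed as *schema*).
    Missing optional tags are skipped; a missing tag mapped to a required
    attribute, or an unconvertible value, raises
    :class:`ExtractionError` naming the attribute.
    """
    if schema is None:
        if store is None:
            raise ValueError("extract_metadata needs a schema or a store")
        schema = store.load_schema(profile.datatype_name)
    dataset = _read(path)
    values: list[AttributeValue] = []
    for mapping in profile.tag_map:
        raw = getattr(dataset, mapping.keyword, None)
        if raw is None or raw == "":
            if mapping.required:
                raise ExtractionError(
                    f"required tag {mapping.keyword} missing for attribute "
                    f"{'.'.join(p for p in mapping.path if p)}"
                )
            continue
        resolved = schema.resolve(mapping.path)
        if resolved is None:
            raise ExtractionError(
                f"profile maps {mapping.keyword} to unknown path "
                f"{mapping.path} in datatype {schema.name!r}"
            )
        canonical, attr = resolved
        try:
            value = _convert(raw, attr.value_kind)
        except ValueError as exc:
            raise ExtractionError(
                f"tag {mapping.keyword} -> attribute "
                f"{canonical[0]}.{canonical[2]}: {exc}"
            ) from exc
        values.append(AttributeValue(path=canonical, value=value))
    return values


def _convert(raw: Any, kind: str) -> Any:
    text = str(raw)
    if kind == "date" and re.fullmatch(r"\d{8}", text):
        # DICOM DA format YYYYMMDD
        return datetime.date(int(text[:4]), int(text[4:6]), int(text[6:8]))
    if kind == "decimal":
        try:
            value = Decimal(text)
        except InvalidOperation:
            raise ValueError(f"{text!r} is not a decimal number") from None
        if not value.is_finite():
            raise ValueError(f"{text!r} is not a finite decimal")
        return value
    return parse_value(kind, text)


# ---------------------------------------------------------------------------
# registration


def register_imaging(
    store: Store,
    path: str | Path,
    subject_id: str,
    process: Process,
    taxonomy: Taxonomy,
    profiles: Optional[dict[str, ModalityProfile]] = None,
    uri: Optional[str] = None,
    occurred_at: str = "",
) -> tuple[DataInstance, Event]:
    """Detect, extract, store and log one imaging file — atomically.

    Creates a validated instance of the profile's data type with the file
    attached (by URI; payloads are never copied into the store) and an
    event of the profile's event type under *process*.  Any failure at
    any stage leaves the store row counts unchanged.
    """
    profiles = profiles if profiles is not None else default_profiles()
    modality = detect_modality(Path(path), profiles)  # rejection before writes
    profile = profiles[modality]
    if not store.has_subject(subject_id):
        raise NotFoundError(f"unknown subject {subject_id!r}")
    schema = store.load_schema(profile.datatype_name)
    values = extract_metadata(path, profile, schema=schema)
    file_uri = uri if uri is not None else Path(path).resolve().as_uri()
    with store.transaction():
        instance = DataInstance(
            instance_id=f"D{store.next_id('instance')}",
            datatype_name=schema.name,
            datatype_version=schema.version,
            subject_id=subject_id,
            values=tuple(values),
            files=(FileRef(uri=file_uri, declared_format="DICOM"),),
        )
        store.save_instance(instance)
        event = taxonomy.add_event(
            process,
            profile.event_type,
            occurred_at=occurred_at,
            data=[instance.instance_id],
        )
    return instance, event


# ---------------------------------------------------------------------------
# synthetic fixture writer


def write_synthetic_dicom(
    modality: str,
    tags: dict[str, Any],
    destination: str | Path,
    uid_entropy: Optional[str] = None,
) -> Path:
    """Write a minimal valid DICOM file with exactly the given header tags.

    *modality* is the DICOM code (MR, PT, NM).  *tags* maps DICOM
    keywords to values (e.g. ``{"EchoTime": "30", "StudyDate":
    "20120301"}``).  With *uid_entropy* given the SOP instance identifier
    is derived deterministically from it, so seeded fixture batches are
    reproducible; otherwise a random identifier is generated.
    """
    if modality not in _SOP_CLASS:
        raise ValueError(
            f"unsupported modality {modality!r} (expected one of "
            f"{sorted(_SOP_CLASS)})"
        )
    destination = Path(destination)
    sop_instance = generate_uid(
        entropy_srcs=[uid_entropy] if uid_entropy is not None else None
    )
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _SOP_CLASS[modality]
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    dataset = FileDataset(
        str(destination), {}, file_meta=meta, preamble=b"\0" * 128
    )
    dataset.SOPClassUID = _SOP_CLASS[modality]
    dataset.SOPInstanceUID = sop_instance
    dataset.Modality = modality
    for keyword, value in tags.items():
        setattr(dataset, keyword, value)
    dataset.save_as(str(destination), enforce_file_format=True)
    return destination
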