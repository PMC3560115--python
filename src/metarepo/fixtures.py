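"""Seeded synthetic study fixtures: datatypes, cohort, samples, images.

This module makes every other module testable without any external data.
It bootstraps the data types of a multi-centre early-Alzheimer study —
clinical evaluation (with a risk-factor loop), neuropsychological test
battery (including the Rey Auditory Verbal Learning Test delayed-recall
measure), genetic variants per candidate gene (MAPT, PSEN1, APP...),
gene-screening setup, the four imaging types and a serum biomarker — and
generates a deterministic cohort: anonymous subjects with sex, birth
date and diagnosis (normal controls, single-/multi-domain amnestic MCI,
Alzheimer's disease), one visit process per subject with acquisition and
screening events, clinical/neuropsychological/genetic instances,
synthetic DICOM-backed imaging records, and blood samples placed in a
configured -80C freezer (some shipped by courier to the analysis site
and re-placed there).

Everything is driven by one integer seed through ``random.Random`` and a
synthetic clock, so two runs with equal (spec, seed) produce
byte-identical store exports.  The attribute names, score ranges and
diagnosis mix are modelled on the study narrative; they are test
scaffolding, not claimed clinical standards.

It also provides seeded random generators for schemas, conforming
instances and query specs, used by property tests and by the
verification script.
"""

from __future__ import annotations

import datetime
import random
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Optional, Sequence

from . import imaging, samples
from .exceptions import ConflictError
from .metamodel import (
    AttributeDef,
    DataTypeSchema,
    LoopDef,
    MetadataGroup,
    SchemaHeader,
    define_datatype,
)
from .process_event import Taxonomy
from .records import AttributeValue, DataInstance, LoopInstance, Subject
from .samples import FreezerLayout, SlotCoordinate
from .storage import Store

FIXTURE_CREATED_AT = "2012-01-01T00:00:00"

RISK_FACTORS = ("smoke", "alchool", "sedentary job")

#: static external-reference catalog for candidate genes (link shape of the
#: public gene and variant-database pages; no network access involved)
GENE_CATALOG = {
    "MAPT": {
        "ncbi_url": "https://www.ncbi.nlm.nih.gov/gene/4137",
        "molgen_url": "https://www.molgen.ua.ac.be/ADMutations/gene/MAPT#variants",
    },
    "APP": {
        "ncbi_url": "https://www.ncbi.nlm.nih.gov/gene/351",
        "molgen_url": "https://www.molgen.ua.ac.be/ADMutations/gene/APP#variants",
    },
    "PSEN1": {
        "ncbi_url": "https://www.ncbi.nlm.nih.gov/gene/5663",
        "molgen_url": "https://www.molgen.ua.ac.be/ADMutations/gene/PSEN1#variants",
    },
    "PSEN2": {
        "ncbi_url": "https://www.ncbi.nlm.nih.gov/gene/5664",
        "molgen_url": "https://www.molgen.ua.ac.be/ADMutations/gene/PSEN2#variants",
    },
    "GRN": {
        "ncbi_url": "https://www.ncbi.nlm.nih.gov/gene/2896",
        "molgen_url": "https://www.molgen.ua.ac.be/ADMutations/gene/GRN#variants",
    },
}

DIAGNOSES = {
    "Control": ("Control",),
    "aMCI": ("Amnestic MCI (single-domain)", "Amnestic MCI (multi-domain)"),
    "AD": ("Alzheimer's disease",),
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the generated study population."""

    n_subjects: int = 20
    diagnosis_mix: tuple[tuple[str, float], ...] = (
        ("Control", 0.3), ("aMCI", 0.4), ("AD", 0.3)
    )
    seed: int = 0
    #: integer score range of the Rey AVLT delayed recall measure
    rey_delayed_recall_range: tuple[int, int] = (0, 15)
    variant_genes: tuple[str, ...] = tuple(GENE_CATALOG)
    max_variants_per_subject: int = 2
    pet_probability: float = 0.6
    fmri_probability: float = 0.2
    spect_probability: float = 0.1
    shipped_fraction: float = 0.3

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("cohort needs >= 1 subject")
        total = sum(p for _, p in self.diagnosis_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("diagnosis mix proportions must sum to 1")


# ---------------------------------------------------------------------------
# fixture datatypes


def _fixture_schemas() -> list[DataTypeSchema]:
    def header(name: str, description: str, file_associated: bool = False):
        return SchemaHeader(
            datatype_name=name,
            description=description,
            file_associated=file_associated,
            created_by="fixture",
            created_at=FIXTURE_CREATED_AT,
        )

    clinical = define_datatype(
        header("Clinical Evaluation", "general and neurological examination"),
        [
            MetadataGroup(
                "examination",
                (
                    AttributeDef("visit_date", "date", required=True),
                    AttributeDef("mmse", "integer", unit="points"),
                    AttributeDef("notes", "text"),
                    LoopDef(
                        "risk_factor",
                        (
                            AttributeDef(
                                "factor",
                                "enumeration",
                                required=True,
                                allowed_values=RISK_FACTORS,
                            ),
                            AttributeDef("present", "boolean", required=True),
                        ),
                    ),
                ),
            )
        ],
    )
    neuropsych = define_datatype(
        header("Neuropsychological Tests", "cognitive test battery"),
        [
            MetadataGroup(
                "battery",
                (
                    AttributeDef("assessment_date", "date", required=True),
                    AttributeDef(
                        "rey_delayed_recall", "integer", required=True,
                        unit="words",
                    ),
                    AttributeDef("rey_immediate_recall", "integer",
                                 unit="words"),
                    AttributeDef("verbal_fluency", "integer"),
                ),
            )
        ],
    )
    genetic = define_datatype(
        header("Genetic Variant", "variant found by candidate-gene screening"),
        [
            MetadataGroup(
                "variant",
                (
                    AttributeDef("gene", "text", required=True),
                    AttributeDef("variant", "text", required=True),
                    AttributeDef(
                        "status",
                        "enumeration",
                        required=True,
                        allowed_values=("known", "novel"),
                    ),
                    AttributeDef("ncbi_url", "text"),
                    AttributeDef("molgen_url", "text"),
                ),
            )
        ],
    )
    screening = define_datatype(
        header("Gene Screening Setup",
               "genes to screen, their exons and relevant known variants"),
        [
            MetadataGroup(
                "setup",
                (
                    AttributeDef("gene", "text", required=True),
                    AttributeDef("ncbi_url", "text"),
                    AttributeDef("molgen_url", "text"),
                    LoopDef(
                        "exons",
                        (
                            AttributeDef("exon_number", "integer",
                                         required=True),
                            AttributeDef("size_bp", "integer"),
                        ),
                    ),
                    LoopDef(
                        "known_variants",
                        (
                            AttributeDef("variant", "text", required=True),
                            AttributeDef("pathogenic", "boolean"),
                        ),
                    ),
                ),
            )
        ],
    )
    serum = define_datatype(
        header("Serum Biomarker", "a generic serum biomarker measurement"),
        [
            MetadataGroup(
                "measurement",
                (
                    AttributeDef("biomarker", "text", required=True),
                    AttributeDef("concentration", "decimal", unit="pg/mL"),
                    AttributeDef("sampling_date", "date"),
                ),
            )
        ],
    )

    def imaging_type(name: str, description: str, nuclear: bool = False):
        attrs: tuple[AttributeDef, ...]
        if nuclear:
            attrs = (
                AttributeDef("radiopharmaceutical", "text"),
                AttributeDef("study_date", "date"),
                AttributeDef("sequence", "text"),
            )
        else:
            attrs = (
                AttributeDef("sequence", "text"),
                AttributeDef("study_date", "date"),
                AttributeDef("echo_time", "decimal", unit="ms"),
                AttributeDef("repetition_time", "decimal", unit="ms"),
                AttributeDef("field_strength", "decimal", unit="T"),
            )
        return define_datatype(
            header(name, description, file_associated=True),
            [MetadataGroup("acquisition", attrs)],
        )

    return [
        clinical,
        neuropsych,
        genetic,
        screening,
        serum,
        imaging_type("MRI", "structural magnetic resonance imaging"),
        imaging_type("fMRI", "functional magnetic resonance imaging"),
        imaging_type("PET", "positron emission tomography", nuclear=True),
        imaging_type("SPECT", "single-photon emission tomography",
                     nuclear=True),
    ]


def bootstrap_datatypes(store: Store) -> list[tuple[str, int]]:
    """Define the fixture data types in *store*; idempotent re-run.

    A store that already holds a *different* user-defined type under one
    of the fixture names is refused, with all collisions listed.
    """
    from .metamodel import serialize_schema

    keys: list[tuple[str, int]] = []
    collisions: list[str] = []
    for schema in _fixture_schemas():
        try:
            existing = store.load_schema(schema.name, schema.version)
        except Exception:
            existing = None
        if existing is not None:
            if serialize_schema(existing) == serialize_schema(schema):
                keys.append((schema.name, schema.version))
                continue
            collisions.append(schema.name)
            continue
        keys.append(store.save_schema(schema))
    if collisions:
        raise ConflictError(
            "fixture datatype names collide with user-defined types: "
            + ", ".join(sorted(collisions))
        )
    return keys


# ---------------------------------------------------------------------------
# cohort generation


class _Clock:
    """Deterministic timestamps: strictly increasing from a fixed origin."""

    def __init__(self, start: str = "2012-02-01T08:00:00"):
        self._t = datetime.datetime.fromisoformat(start)

    def tick(self, minutes: int = 30) -> str:
        self._t += datetime.timedelta(minutes=minutes)
        return self._t.replace(microsecond=0).isoformat()


def study_taxonomy(store: Optional[Store] = None) -> Taxonomy:
    """The process/event types used by the generated study."""
    taxonomy = Taxonomy()
    if store is not None:
        store.bind_taxonomy(taxonomy)
    taxonomy.register_process_type("Visit", "a subject visit",
                                   allowed_child_types=("Study",))
    taxonomy.register_process_type("Study", "one study within a visit")
    for event_type in (
        "Clinical examination",
        "Neuropsychological assessment",
        "Blood draw",
        "Genetic screening",
        "MRI acquisition",
        "fMRI acquisition",
        "PET acquisition",
        "SPECT acquisition",
    ):
        taxonomy.register_event_type(event_type)
    return taxonomy


def generate_cohort(
    store: Store,
    spec: CohortSpec = CohortSpec(),
    image_dir: Optional[str | Path] = None,
) -> dict:
    """Populate *store* with a deterministic synthetic cohort.

    Requires :func:`bootstrap_datatypes` to have run.  DICOM files are
    written under *image_dir* (a temporary directory when omitted) and
    registered by relative-filename URI, so stores generated in
    different directories still export identically.  Returns a report of
    per-datatype instance counts plus subject/sample/event totals.
    """
    rng = random.Random(spec.seed)
    clock = _Clock()
    if image_dir is None:
        import tempfile

        image_dir = tempfile.mkdtemp(prefix="metarepo-dicom-")
    image_dir = Path(image_dir)
    image_dir.mkdir(parents=True, exist_ok=True)

    taxonomy = study_taxonomy(store)
    # one rack of 2 slots with 9x9 boxes holds 162 samples; larger cohorts
    # get extra racks so every subject's blood sample has a coordinate
    n_racks = max(1, -(-spec.n_subjects // 162))
    racks = tuple((f"R{i + 1}", 2) for i in range(n_racks))
    genoa = FreezerLayout("GENOA-80", "-80C", racks, (9, 9))
    lubbock = FreezerLayout("LUBBOCK-80", "-80C", racks, (9, 9))
    samples.configure_freezer(store, genoa)
    samples.configure_freezer(store, lubbock)

    # study-level gene screening setup (not subject-bound)
    screening_schema = store.load_schema("Gene Screening Setup")
    for gene in sorted(spec.variant_genes)[:3]:
        links = GENE_CATALOG.get(gene, {})
        n_exons = rng.randint(3, 8)
        instance = DataInstance(
            instance_id=f"SETUP-{gene}",
            datatype_name=screening_schema.name,
            datatype_version=screening_schema.version,
            subject_id=None,
            values=(
                AttributeValue(("setup", None, "gene"), gene),
                AttributeValue(("setup", None, "ncbi_url"),
                               links.get("ncbi_url", "")),
                AttributeValue(("setup", None, "molgen_url"),
                               links.get("molgen_url", "")),
            ),
            loops=(
                LoopInstance(
                    path=("setup", "exons"),
                    iterations=tuple(
                        (
                            AttributeValue(("setup", "exons", "exon_number"),
                                           i + 1),
                            AttributeValue(("setup", "exons", "size_bp"),
                                           rng.randint(80, 400)),
                        )
                        for i in range(n_exons)
                    ),
                ),
                LoopInstance(
                    path=("setup", "known_variants"),
                    iterations=tuple(
                        (
                            AttributeValue(
                                ("setup", "known_variants", "variant"),
                                f"c.{rng.randint(10, 999)}"
                                f"{rng.choice('ACGT')}>{rng.choice('ACGT')}",
                            ),
                            AttributeValue(
                                ("setup", "known_variants", "pathogenic"),
                                rng.random() < 0.5,
                            ),
                        )
                        for _ in range(rng.randint(1, 4))
                    ),
                ),
            ),
        )
        store.save_instance(instance)

    counts: dict[str, int] = {}

    def count(name: str) -> None:
        counts[name] = counts.get(name, 0) + 1

    placement = _SlotIterator(genoa)
    lubbock_placement = _SlotIterator(lubbock)
    n_events = 0
    for i in range(spec.n_subjects):
        subject_id = f"S{i + 1:03d}"
        category = _pick_category(rng, spec.diagnosis_mix)
        diagnosis = rng.choice(DIAGNOSES[category])
        sex = rng.choice(("male", "female"))
        age = rng.randint(55, 85)
        birth = datetime.date(2012 - age, rng.randint(1, 12), rng.randint(1, 28))
        store.save_subject(
            Subject(subject_id, sex, birth.isoformat(), diagnosis)
        )
        visit = taxonomy.create_process(
            "Visit", f"Baseline visit {subject_id}", subject_id=subject_id,
            started_at=clock.tick(),
        )
        acquisition = taxonomy.create_process(
            "Study", "Data acquisition", parent=visit, subject_id=subject_id
        )

        # clinical evaluation with risk-factor loop (only present factors)
        present_factors = [f for f in RISK_FACTORS if rng.random() < 0.4]
        clinical = DataInstance(
            instance_id=f"CLIN-{subject_id}",
            datatype_name="Clinical Evaluation",
            datatype_version=1,
            subject_id=subject_id,
            values=(
                AttributeValue(("examination", None, "visit_date"),
                               datetime.date(2012, 2, 1)),
                AttributeValue(("examination", None, "mmse"),
                               _mmse(rng, category)),
            ),
            loops=(
                LoopInstance(
                    path=("examination", "risk_factor"),
                    iterations=tuple(
                        (
                            AttributeValue(
                                ("examination", "risk_factor", "factor"), f
                            ),
                            AttributeValue(
                                ("examination", "risk_factor", "present"), True
                            ),
                        )
                        for f in present_factors
                    ),
                ),
            ) if present_factors else (),
        )
        store.save_instance(clinical)
        count("Clinical Evaluation")
        taxonomy.add_event(acquisition, "Clinical examination",
                           occurred_at=clock.tick(),
                           data=[clinical.instance_id])
        n_events += 1

        # neuropsychological battery
        lo, hi = spec.rey_delayed_recall_range
        neuro = DataInstance(
            instance_id=f"NPSY-{subject_id}",
            datatype_name="Neuropsychological Tests",
            datatype_version=1,
            subject_id=subject_id,
            values=(
                AttributeValue(("battery", None, "assessment_date"),
                               datetime.date(2012, 2, 2)),
                AttributeValue(("battery", None, "rey_delayed_recall"),
                               _rey_delayed(rng, category, lo, hi)),
                AttributeValue(("battery", None, "rey_immediate_recall"),
                               rng.randint(15, 60)),
                AttributeValue(("battery", None, "verbal_fluency"),
                               rng.randint(10, 45)),
            ),
        )
        store.save_instance(neuro)
        count("Neuropsychological Tests")
        taxonomy.add_event(acquisition, "Neuropsychological assessment",
                           occurred_at=clock.tick(),
                           data=[neuro.instance_id])
        n_events += 1

        # imaging: MRI always; PET/fMRI/SPECT by probability
        modalities = ["MR"]
        if rng.random() < spec.fmri_probability:
            modalities.append("MR-fmri")
        if rng.random() < spec.pet_probability:
            modalities.append("PT")
        if rng.random() < spec.spect_probability:
            modalities.append("NM")
        for j, modality in enumerate(modalities):
            filename = f"{subject_id}_{j}.dcm"
            path = image_dir / filename
            _write_image(rng, modality, path,
                         uid_entropy=f"{spec.seed}-{subject_id}-{j}")
            instance, _event = imaging.register_imaging(
                store, path, subject_id, acquisition, taxonomy,
                uri=filename, occurred_at=clock.tick(),
            )
            count(instance.datatype_name)
            n_events += 1

        # blood sample, freezer placement, possible courier shipment
        sample_id = f"B-{subject_id}"
        samples.register_sample(store, sample_id, "blood", subject_id,
                                timestamp=clock.tick())
        draw = taxonomy.add_event(acquisition, "Blood draw",
                                  occurred_at=clock.tick())
        n_events += 1
        samples.place_sample(store, sample_id, placement.next(),
                             timestamp=clock.tick())
        if rng.random() < spec.shipped_fraction:
            samples.register_shipment(
                store, sample_id,
                courier_number=f"CN{rng.randint(10**8, 10**9 - 1)}",
                timestamp=clock.tick(),
            )
            samples.place_sample(store, sample_id, lubbock_placement.next(),
                                 timestamp=clock.tick())

        # genetic screening results
        screening_study = taxonomy.create_process(
            "Study", "Genetic screening", parent=visit, subject_id=subject_id
        )
        variant_ids = []
        for k in range(rng.randint(0, spec.max_variants_per_subject)):
            gene = rng.choice(sorted(spec.variant_genes))
            links = GENE_CATALOG.get(gene, {})
            variant = DataInstance(
                instance_id=f"VAR-{subject_id}-{k}",
                datatype_name="Genetic Variant",
                datatype_version=1,
                subject_id=subject_id,
                values=(
                    AttributeValue(("variant", None, "gene"), gene),
                    AttributeValue(
                        ("variant", None, "variant"),
                        f"c.{rng.randint(10, 999)}"
                        f"{rng.choice('ACGT')}>{rng.choice('ACGT')}",
                    ),
                    AttributeValue(("variant", None, "status"),
                                   rng.choice(("known", "novel"))),
                    AttributeValue(("variant", None, "ncbi_url"),
                                   links.get("ncbi_url", "")),
                    AttributeValue(("variant", None, "molgen_url"),
                                   links.get("molgen_url", "")),
                ),
            )
            store.save_instance(variant)
            count("Genetic Variant")
            variant_ids.append(variant.instance_id)
        taxonomy.add_event(screening_study, "Genetic screening",
                           occurred_at=clock.tick(), data=variant_ids)
        n_events += 1

        # serum biomarker for a subset
        if rng.random() < 0.5:
            serum = DataInstance(
                instance_id=f"SER-{subject_id}",
                datatype_name="Serum Biomarker",
                datatype_version=1,
                subject_id=subject_id,
                values=(
                    AttributeValue(("measurement", None, "biomarker"),
                                   rng.choice(("ABeta42", "tau", "p-tau"))),
                    AttributeValue(
                        ("measurement", None, "concentration"),
                        Decimal(rng.randint(100, 9000)) / 10,
                    ),
                    AttributeValue(("measurement", None, "sampling_date"),
                                   datetime.date(2012, 2, 3)),
                ),
            )
            store.save_instance(serum)
            count("Serum Biomarker")

    counts["Gene Screening Setup"] = len(sorted(spec.variant_genes)[:3])
    return {
        "subjects": spec.n_subjects,
        "instances_by_datatype": dict(sorted(counts.items())),
        "events": n_events,
        "samples": spec.n_subjects,
        "seed": spec.seed,
    }


def _pick_category(rng: random.Random,
                   mix: Sequence[tuple[str, float]]) -> str:
    roll = rng.random()
    cumulative = 0.0
    for category, proportion in mix:
        cumulative += proportion
        if roll < cumulative:
            return category
    return mix[-1][0]


def _mmse(rng: random.Random, category: str) -> int:
    if category == "Control":
        return rng.randint(27, 30)
    if category == "aMCI":
        return rng.randint(24, 28)
    return rng.randint(12, 24)


def _rey_delayed(rng: random.Random, category: str, lo: int, hi: int) -> int:
    # short-term memory impairment tracks diagnosis: controls recall well,
    # AD subjects poorly; <6 words flags likely impairment
    if category == "Control":
        return rng.randint(max(lo, 6), hi)
    if category == "aMCI":
        return rng.randint(max(lo, 2), min(hi, 8))
    return rng.randint(lo, min(hi, 5))


def _write_image(rng: random.Random, modality: str, path: Path,
                 uid_entropy: str) -> None:
    study_date = "20120203"
    if modality == "MR":
        imaging.write_synthetic_dicom(
            "MR",
            {
                "SeriesDescription": rng.choice(("T1 MPRAGE", "T2 FLAIR")),
                "StudyDate": study_date,
                "EchoTime": str(rng.randint(5, 120)),
                "RepetitionTime": str(rng.randint(400, 4000)),
                "MagneticFieldStrength": rng.choice(("1.5", "3")),
            },
            path,
            uid_entropy=uid_entropy,
        )
    elif modality == "MR-fmri":
        imaging.write_synthetic_dicom(
            "MR",
            {
                "SeriesDescription": "fMRI BOLD resting state",
                "StudyDate": study_date,
                "EchoTime": str(rng.randint(20, 40)),
                "RepetitionTime": str(rng.randint(1500, 3000)),
                "MagneticFieldStrength": "3",
            },
            path,
            uid_entropy=uid_entropy,
        )
    elif modality == "PT":
        imaging.write_synthetic_dicom(
            "PT",
            {
                "SeriesDescription": "FDG PET brain",
                "StudyDate": study_date,
                "Radiopharmaceutical": "F-18 FDG",
            },
            path,
            uid_entropy=uid_entropy,
        )
    else:
        imaging.write_synthetic_dicom(
            "NM",
            {
                "SeriesDescription": "perfusion SPECT",
                "StudyDate": study_date,
                "Radiopharmaceutical": "Tc-99m HMPAO",
            },
            path,
            uid_entropy=uid_entropy,
        )


class _SlotIterator:
    """Deterministic walk over the free coordinates of a freezer."""

    def __init__(self, layout: FreezerLayout):
        self._coords = iter(
            SlotCoordinate(layout.freezer_id, rack_id, slot, x, y)
            for rack_id, slots in layout.racks
            for slot in range(1, slots + 1)
            for y in range(1, layout.box_grid[1] + 1)
            for x in range(1, layout.box_grid[0] + 1)
        )

    def next(self) -> SlotCoordinate:
        return next(self._coords)


# ---------------------------------------------------------------------------
# seeded random generators for property testing


def random_schema(rng: random.Random, name: Optional[str] = None) -> DataTypeSchema:
    """A random valid data type: attributes, enumerations, loops."""
    kinds = ("text", "integer", "decimal", "date", "boolean", "enumeration")
    name = name or f"Type{rng.randrange(10**9)}"
    used_names: set[str] = set()

    def fresh(prefix: str) -> str:
        while True:
            candidate = f"{prefix}{rng.randrange(1000)}"
            if candidate.lower() not in used_names:
                used_names.add(candidate.lower())
                return candidate

    def attr(required_allowed: bool = True) -> AttributeDef:
        kind = rng.choice(kinds)
        allowed = ()
        default = None
        if kind == "enumeration":
            allowed = tuple(
                f"opt{rng.randrange(100)}_{i}" for i in range(rng.randint(1, 4))
            )
        if rng.random() < 0.2:
            default = _random_value(rng, kind, allowed)
        return AttributeDef(
            name=fresh("attr"),
            value_kind=kind,
            required=required_allowed and rng.random() < 0.4,
            allowed_values=allowed,
            unit="u" if rng.random() < 0.2 else None,
            default=default,
        )

    groups = []
    for _ in range(rng.randint(1, 3)):
        members: list = [attr() for _ in range(rng.randint(1, 4))]
        if rng.random() < 0.5:
            members.append(
                LoopDef(
                    name=fresh("loop"),
                    attributes=tuple(attr() for _ in range(rng.randint(1, 3))),
                )
            )
        rng.shuffle(members)
        groups.append(MetadataGroup(name=fresh("group"), members=tuple(members)))
    return define_datatype(
        SchemaHeader(
            datatype_name=name,
            description="randomly generated",
            file_associated=rng.random() < 0.3,
            created_by="generator",
            created_at=FIXTURE_CREATED_AT,
        ),
        groups,
    )


def _random_value(rng: random.Random, kind: str,
                  allowed: Sequence[str] = ()):
    if kind == "text":
        return f"text{rng.randrange(10**6)}"
    if kind == "integer":
        return rng.randint(-1000, 1000)
    if kind == "decimal":
        return Decimal(rng.randint(-10**6, 10**6)) / 100
    if kind == "date":
        return datetime.date(rng.randint(1940, 2012), rng.randint(1, 12),
                             rng.randint(1, 28))
    if kind == "boolean":
        return rng.random() < 0.5
    return rng.choice(list(allowed))


def random_conforming_instance(
    rng: random.Random,
    schema: DataTypeSchema,
    instance_id: str = "R1",
    subject_id: Optional[str] = None,
) -> DataInstance:
    """A random instance that validates cleanly against *schema*."""
    values: list[AttributeValue] = []
    loops: list[LoopInstance] = []
    for group in schema.groups:
        for member in group.members:
            if isinstance(member, LoopDef):
                iterations = []
                for _ in range(rng.randint(0, 3)):
                    chosen = [
                        a for a in member.attributes
                        if a.required or rng.random() < 0.7
                    ] or [member.attributes[0]]
                    iterations.append(tuple(
                        AttributeValue(
                            path=(group.name, member.name, a.name),
                            value=_random_value(rng, a.value_kind,
                                                a.allowed_values),
                        )
                        for a in chosen
                    ))
                if iterations:
                    loops.append(
                        LoopInstance(path=(group.name, member.name),
                                     iterations=tuple(iterations))
                    )
            else:
                if member.required or rng.random() < 0.7:
                    values.append(
                        AttributeValue(
                            path=(group.name, None, member.name),
                            value=_random_value(rng, member.value_kind,
                                                member.allowed_values),
                        )
                    )
    return DataInstance(
        instance_id=instance_id,
        datatype_name=schema.name,
        datatype_version=schema.version,
        subject_id=subject_id,
        values=tuple(values),
        loops=tuple(loops),
    )


def random_query_spec(rng: random.Random, store: Store):
    """A random valid query over the store's schemas (composed, validated).

    Mixes subject conditions, field conditions (plain and loop paths) and
    existence conditions.
    """
    from .query import DataCondition, SubjectCondition, compose_query

    subject_conditions = []
    if rng.random() < 0.5:
        subject_conditions.append(
            SubjectCondition("sex", "eq", rng.choice(("male", "female")))
        )
    if rng.random() < 0.4:
        subject_conditions.append(
            SubjectCondition(
                "diagnosis", "contains",
                rng.choice(("Amnestic", "Control", "Alzheimer", "MCI")),
            )
        )
    if rng.random() < 0.3:
        subject_conditions.append(
            SubjectCondition(
                "birth_date", rng.choice(("lt", "ge")),
                datetime.date(rng.randint(1930, 1955), 1, 1).isoformat(),
            )
        )
    data_conditions = []
    datatypes = store.list_datatypes()
    for _ in range(rng.randint(0, 3)):
        name, _version = rng.choice(datatypes)
        schema = store.load_schema(name)
        paths = list(schema.iter_paths())
        if rng.random() < 0.3 or not paths:
            data_conditions.append(DataCondition(name, "exists"))
            continue
        path, attr = rng.choice(paths)
        kind = attr.value_kind
        if kind in ("integer", "decimal", "date"):
            operator = rng.choice(("eq", "ne", "lt", "le", "gt", "ge"))
        elif kind == "boolean":
            operator = rng.choice(("eq", "ne"))
        else:
            operator = rng.choice(("eq", "ne", "contains", "in"))
        if operator == "in":
            value = [
                _plausible_value(rng, attr) for _ in range(rng.randint(1, 3))
            ]
        else:
            value = _plausible_value(rng, attr)
        data_conditions.append(
            DataCondition(name, "field", path=path, operator=operator,
                          value=value)
        )
    return compose_query(store, subject_conditions, data_conditions)


def _plausible_value(rng: random.Random, attr: AttributeDef):
    """Values with a realistic hit rate against the generated cohort."""
    kind = attr.value_kind
    if kind == "enumeration":
        return rng.choice(list(attr.allowed_values))
    if kind == "integer":
        return rng.randint(0, 30)
    if kind == "decimal":
        return Decimal(rng.randint(0, 4000)) / 10
    if kind == "date":
        return datetime.date(2012, rng.randint(1, 3), rng.randint(1, 28))
    if kind == "boolean":
        return rng.random() < 0.5
    return rng.choice(
        ("MAPT", "APP", "PSEN1", "T1", "FDG", "ABeta42", "tau", "BOLD",
         "c.1", "MPRAGE")
    )
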