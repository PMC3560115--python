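# metarepo

An embeddable research-data repository engine for studies whose data
model cannot be fixed in advance — multidisciplinary clinical research
combining examinations, neuropsychological test batteries, genetic
screening, blood biomarkers and medical imaging.

Instead of a compiled-in schema, `metarepo` implements a **meta data
model**: users define *data types* at run time — a header plus groups of
typed attributes and repeatable *loops* (one iteration per reagent, per
risk factor, ...) — and use them immediately, with no database rebuild.
Around that core:

* **Dual persistence** — every instance is stored both as a canonical
  XML document and flattened into entity-attribute-value (EAV) rows
  `(instance, group, loop?, iteration?, attribute, value)`; injective
  canonical value encodings keep the two representations mutually
  checkable at all times.
* **Process-event provenance** — user-defined hierarchical processes
  containing ordered sub-processes and atomic events that carry the
  data, yielding a timeline of everything done to a subject; the
  structure maps onto the XCEDE hierarchy (visit/study → processes,
  episode/acquisition → events).
* **Dynamic queries** — conjunctions of subject conditions (diagnosis,
  sex, birth date) and per-datatype field or existence conditions, with
  the field vocabulary auto-filled from the stored schemas, executed as
  SQL over the EAV rows, and an integrated per-subject overview.
* **Access control** — default-deny group permissions per data type and
  function, with field-level masking of personal data (a user without
  the grant never sees a birth date in any rendering).
* **Sample tracking** — configurable freezer/rack/slot/box-grid layouts,
  x-y placement, movement history, courier shipment between sites.
* **DICOM auto-extraction** — modality detection (MRI/fMRI/PET/SPECT),
  header-tag extraction into typed attributes, file-type checking before
  upload, and atomic creation of instance + acquisition event.
* **Anonymous subjects by construction** — the subject record has no
  field that could hold a personal name.

A seeded fixture generator produces a synthetic two-site early-Alzheimer
study cohort (controls, amnestic MCI, Alzheimer's disease; test scores,
variants in MAPT and other candidate genes, synthetic DICOM scans, blood
samples in a −80C freezer) so every feature is exercisable offline.

## Worked example

```python
import tempfile
from metarepo import Store
from metarepo import fixtures
from metarepo.query import (DataCondition, SubjectCondition, compose_query,
                            execute_query, list_fields)

store = Store()                      # or Store("study.db") for a file
fixtures.bootstrap_datatypes(store)  # study data types, usable immediately
report = fixtures.generate_cohort(
    store, fixtures.CohortSpec(n_subjects=20, seed=42),
    image_dir=tempfile.mkdtemp(),
)
print(report["instances_by_datatype"])

# the field list fills itself from the runtime-defined type
print(list_fields(store, "Neuropsychological Tests"))

# subjects scoring below 6 words on the Rey delayed recall measure
spec = compose_query(store, [], [
    DataCondition("Neuropsychological Tests", "field",
                  path=("battery", None, "rey_delayed_recall"),
                  operator="lt", value=6),
])
print(execute_query(store, spec))

# male amnestic-MCI smokers with a MAPT variant and at least one MRI
spec = compose_query(
    store,
    [SubjectCondition("sex", "eq", "male"),
     SubjectCondition("diagnosis", "contains", "Amnestic MCI")],
    [DataCondition("Clinical Evaluation", "field",
                   path=("examination", "risk_factor", "factor"),
                   operator="eq", value="smoke"),
     DataCondition("Genetic Variant", "field",
                   path=("variant", None, "gene"), operator="eq", value="MAPT"),
     DataCondition("MRI", "exists")],
)
print(execute_query(store, spec))
```

prints

```
{'Clinical Evaluation': 20, 'Gene Screening Setup': 3, 'Genetic Variant': 21,
 'MRI': 20, 'Neuropsychological Tests': 20, 'PET': 10, 'Serum Biomarker': 5,
 'fMRI': 4}
[('battery', None, 'assessment_date'), ('battery', None, 'rey_delayed_recall'),
 ('battery', None, 'rey_immediate_recall'), ('battery', None, 'verbal_fluency')]
['S002', 'S007', 'S008', 'S009', 'S010', 'S011', 'S013', 'S014', 'S020']
['S002']
```

The first dictionary is the generated cohort (per-datatype instance
counts).  The first query finds the nine subjects whose generated Rey
Auditory Verbal Learning Test delayed-recall score is in the impaired
range (< 6 words); the second combines subject variables with three data
conditions — a loop-attribute match (some recorded risk factor is
`smoke`), a field match on the genetic-variant type, and bare existence
of MRI data — and finds the single subject in this seeded cohort meeting
all five.  Both results are verified in the test suite against an
independent brute-force in-memory filter.

There is also a CLI over the same operations:

```sh
metarepo --store study.db fixture cohort --n 20 --seed 42
metarepo --store study.db query run \
    --where 'data:Neuropsychological Tests.battery.rey_delayed_recall<6'
metarepo --store study.db query overview S002
metarepo --store study.db sample find B-S002
```

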