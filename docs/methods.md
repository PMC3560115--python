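# Methods

`metarepo` is an embeddable engine for managing multidisciplinary
clinical-research data whose shape is not known in advance.  Its core idea
is a *meta* data model: instead of fixing a schema at development time,
users define **data types** at run time — and use them immediately, with no
database rebuild, redeployment or restart.  Around that core sit a
provenance taxonomy (processes and events), a dual-representation store, a
dynamic query layer, group-based access control with personal-data masking,
a biosample freezer tracker, and automatic DICOM metadata extraction.

## The meta data model

A data type is a header (name, version, description, file-association
flag, author, timestamp) plus one or more **groups**, each an ordered mix
of typed **attributes** and **loops**.

* Attributes carry one of six value kinds — `text`, `integer`, `decimal`,
  `date`, `boolean`, `enumeration` — plus a required flag, an optional
  unit, an optional default, an optional ontology term reference, and
  (for enumerations) the allowed labels.  The kind vocabulary was chosen
  to cover everything a clinical/genetic/imaging study records: scores,
  dates, sexes, gene names, yes/no risk flags, category labels.
* A **loop** is a repeatable block of attributes for information whose
  schema is known but whose multiplicity is not: one iteration per
  reagent of an assay (description, concentration, amount), one per
  cardiovascular risk factor.  Loops do not nest; the motivating use
  cases are flat repetitions and nesting would buy complexity with no
  clear need.
* Names are unique **case-insensitively** at every level (attributes and
  loops share a group's namespace), with original casing preserved for
  display.  This prevents silently colliding entity-attribute-value rows
  (`Dose` vs `dose`).

Data types serialize to a small XML dialect (root `datatype`,
`dialect="xtens-1"`, sections `header` and `metadata`).  Serialization is
deterministic — fixed element order, UTF-8 — so `parse ∘ serialize` is the
identity and re-serialization is byte-identical, which the test suite
checks over hundreds of randomly generated schemas.

**Evolution.**  Schema versions are immutable once stored; a change
produces version *n*+1.  While a type has stored instances, only additive
changes are accepted: add attribute / loop / group / enumeration label, or
relax required→optional.  Added attributes must be optional or carry a
default; correspondingly, validation treats a missing required attribute
*with* a default as satisfied.  Together these two rules guarantee that
every instance valid under version *n* is valid under version *n*+1 — the
formal content of "extend the model after data entry, without rebuilding
anything".  Destructive changes (remove/rename a path, change a kind,
make optional required) are allowed only on types with no stored data.

**Ontology suggestions.**  Attribute names can be auto-completed from OBO
ontologies (e.g. OBI, SO).  Only `[Term]` stanzas' `id:`/`name:` lines are
consumed (via `obonet`); suggestion is a case-insensitive *prefix* match,
ordered lexicographically and capped — deliberately minimal, no fuzzy
matching.

**Forms.**  `render_entry_form` emits an HTML form straight from a schema:
one control per attribute, `<select>` for enumerations, required markers,
and each loop as a repeatable row template a dynamic front end can clone.

## Instances and subjects

An instance pins the exact (datatype, version) it was entered under;
validation always uses the pinned version.  Subjects are anonymous **by
construction**: the `Subject` type has fields for an opaque identifier,
sex, birth date and diagnosis, and *no slot at all* for a personal name —
linking identifiers to people happens outside the system.

Validation is total and deterministic: any (instance, schema) pair yields
a report, never a crash.  Unknown attribute paths are violations rather
than being ignored — silently dropping them would poison the EAV
projection.  Dates are ISO-8601 calendar dates; decimals validate with
exact decimal semantics (no float parsing).  An instance references at
most one event; files may only be attached to file-associated types
(imaging yes, clinical evaluation no).  A loop with zero iterations is
accepted, but the canonical serialized form omits empty loop blocks and
empty iterations, keeping the XML and EAV projections equivalent.

One deliberate widening: `subject_id` is optional on instances, because
study-level configuration records (the gene-screening setup listing genes,
exons and known variants) belong to the study, not to one participant.
Such records simply never match subject-joined queries.

## Dual representation and the store

Every saved instance is persisted twice, atomically:

* the canonical **XML document** in the `data` table — the authoritative
  record, returned transparently on load (callers cannot tell a stored
  document from a regenerated one);
* its **EAV projection** — one row per supplied value:
  `(instance, group, loop?, iteration?, attribute, kind, text)` — which
  dynamic queries run against.

Value encodings are canonical and injective per kind (integers base-10,
decimals in plain notation with trailing zeros stripped, dates ISO-8601,
booleans `true`/`false`, text verbatim), so the two representations are
mutually checkable: `consistency_check` re-derives every instance's rows
from its XML blob and reports any divergence.  Iteration indices are
0-based internally and rendered 1-based.

The reference backend is a single-file embedded SQLite store behind a
narrow contract (a server RDBMS could stand behind the same surface).  A
failed save — validation failure, dangling subject reference — changes no
table.  Both representations are always written; storing only one is a
deployment optimization, not a semantic option.  A whole store exports as
a directory of XML documents plus a JSON manifest, deterministically for
equal contents.

## Process-event provenance

Processes are ordered hierarchical containers (a pre-surgical analysis
with sub-processes for acquisition, post-processing, trajectory study,
surgery-area estimation); events are atomic leaves — an acquisition, a
blood draw, an administrative action — each owned by exactly one process
and optionally carrying data-instance references.  Process/event *types*
and their allowed parent-child relationships are user-defined; an empty
allowed-child list means "any".  Children are ordered by insertion (the
performed sequence); no reorder operation is offered.  `timeline` returns
a depth-first, sequence-ordered event list and also exposes each event's
own timestamp, so both structural and chronological orders are available.
Because every creation mints a fresh node, the forest invariant (no node
is its own ancestor) holds by construction and is property-tested under
thousands of random operations.

The structure maps onto the XCEDE experiment hierarchy: `visit` and
`study` become parent/child processes, `episode` and `acquisition`
collapse into events, `project` and `subject` are context around the tree.

## Dynamic queries

A query is a conjunction of subject conditions (diagnosis, sex, birth
date) and data conditions (existence of a data type, or a condition on
one attribute path).  The candidate paths auto-fill from the latest
stored schema.  Semantics, stated once and mirrored exactly by the
brute-force test oracle:

* conjunction only — conditions accumulate with AND (the UI pattern the
  engine serves offers exactly that);
* each data condition is **independently existential** over the subject's
  instances of its type; same-instance semantics across conditions are
  not promised;
* loop conditions match when *some iteration* matches — a "smoker" is a
  subject with some risk-factor iteration equal to `smoke`;
* text equality is case-insensitive exact and `contains` a
  case-insensitive substring: forgiving defaults for clinician-typed
  values;
* queries resolve against latest schema versions; older-version instances
  participate through shared paths.

Composition validates paths and operator/kind compatibility up front
(ordering operators only on integer/decimal/date); execution runs as SQL
over the EAV rows and returns sorted subject ids.  Numeric predicates
compare through a float projection column; validation itself remains
exact-decimal.  The central property test replays hundreds of random
composed queries against an independent in-memory filter and requires
identical id sets.

`subject_overview` assembles everything recorded for one subject — every
data type's instances with values and file URIs, plus the process/event
timeline — renderable as text or HTML, with access control applied when a
user is given.

## Access control

Groups hold permissions (`view`/`insert`/`modify`) on resources:
`datatype:<name>`, `function:<name>`, or `subject_personal_data`.  Checks
are default-deny and reduce to set union over the user's groups.  "Pages"
of a front end collapse into named functions.  Which subject fields count
as personal is configurable and defaults to `{birth_date}` — sex and
diagnosis are clinical; the id is anonymous by design.  A user without
the personal-data permission receives a masked subject view whose marker
survives every rendering, and overviews omit data types the user cannot
view.  Authentication is out of scope: the engine trusts the
caller-supplied identity.  Mutating calls append one line to an
append-only operation log.

## Samples

Freezers (temperature class −80C or −45C) hold racks of numbered slots;
each slot holds one box with a uniform x-y grid (the engine models a slot
as a box holder).  Coordinates are numeric and 1-based, with A1-style
labels for display.  A sample is registered to a subject, placed, moved,
and shipped; shipping clears the location (in transit, courier number
retained) until the sample is placed again at the destination site's own
freezer — matching a two-site workflow with couriered blood samples.  The
coordinate→sample mapping is injective at all times (checked in logic and
by a unique index); histories are append-only with non-decreasing
timestamps; reconfiguring a freezer is refused if any located sample
would fall out of bounds.

## Imaging

For MRI, fMRI, PET and SPECT, metadata entry is automated from DICOM
headers.  The Modality tag routes through a profile set (MR→MRI, PT→PET,
NM→SPECT); fMRI is split from MR by a configurable series-description
pattern (default: contains `fmri` or `bold`), since DICOM has no fMRI
modality code.  Default tag maps are deliberately minimal
(SeriesDescription, StudyDate, EchoTime/RepetitionTime/field strength for
MR; Radiopharmaceutical for PT/NM) and user-extensible.
Patient-identifying tags (PatientName, PatientID, PatientBirthDate) are
never extractable — profiles refusing them is enforced at construction.
Registration is atomic: one validated instance with the file attached by
URI plus one modality event under the given process, or nothing.
Rejected files (non-DICOM, unmapped modality) never mutate the store, and
rejection is distinct from an I/O error.

The synthetic DICOM writer produces minimal valid files whose headers
contain exactly the requested tags, with SOP instance identifiers derived
deterministically from a seed when requested.  Two simplifications,
acceptable for fixtures only: the Radiopharmaceutical element is written
top-level rather than inside its information sequence, and no pixel data
is written.

## Synthetic cohort

The fixture generator emulates a small two-site early-Alzheimer study:

* **Defaults**: 20 subjects; diagnosis mix 30 % controls, 40 % amnestic
  MCI (single-/multi-domain labels), 30 % Alzheimer's disease; ages
  55–85; Rey Auditory Verbal Learning Test delayed recall on 0–15 words,
  sampled so that controls score ≥6 and AD subjects ≤5 (below 6 flags
  likely short-term-memory impairment); candidate genes MAPT, APP, PSEN1,
  PSEN2, GRN with static external-reference URLs shaped like the public
  gene/variant database pages (no network access); every subject gets an
  MRI, 60 % a PET, 20 % an fMRI, 10 % a SPECT; one blood sample per
  subject placed in a −80C freezer (1 rack × 2 slots × 9×9 boxes = 162
  positions; more racks appear automatically for larger cohorts), 30 %
  shipped by courier and re-placed at the second site.
* The risk-factor loop records only factors that are *present*, so
  "smoker" is expressible as the single field condition
  `risk_factor.factor = smoke` in the conjunction-only query model.
* All randomness flows through one `random.Random(seed)` and a synthetic
  clock, so equal (spec, seed) produce byte-identical store exports —
  verified by test.

What the generator does **not** emulate: missing data, free-text noise,
longitudinal visits, inter-site schema drift, real DICOM series (one file
per acquisition, no pixel data), or realistic genetic variant
distributions.  Passing tests therefore demonstrate the engine's
*mechanics* — validation, equivalence of representations, query
correctness, invariants — not clinical realism.

## Problem sizes and numerical choices

The verification script and acceptance-style tests use: 200 random
schemas for round-trip identity, 200 (schema, instance) pairs for
validation soundness under single mutations, a 20-subject cohort for
dual-representation and worked-query checks, a 200-subject store with 500
random queries for oracle equivalence, 50 stored instances for the
evolution check, 1,000 random operations for the forest and freezer
invariant sweeps, and 50 synthetic DICOM files for the imaging round
trip.  These sizes exercise every code path and branch combination many
times over while keeping the whole pipeline interactive.

Tie-breaks and degenerate inputs: query results are sorted by subject id;
suggestion ties sort by (label, term id); an empty query spec matches all
subjects; an empty change list leaves a schema (and its version)
untouched; empty loops validate but are canonicalized away; `-0` encodes
as `0`.

## Known limitations

* Conjunction-only queries: no OR, no grouping, no same-instance joins
  across conditions.
* Numeric query predicates go through float projection (range queries on
  >15-significant-digit decimals could misorder; validation is exact).
* No distributed or federated storage; file payloads are referenced by
  URI only and never copied.
* No authentication, sessions, or audit beyond the operation log.
* The process-event model is descriptive provenance only — no workflow
  execution, no services attached to events.
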