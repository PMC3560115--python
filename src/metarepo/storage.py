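"""Single-file relational store with dual XML + EAV representation.

Every data instance is persisted twice, by design:

* as a canonical XML document in the ``data`` table — the authoritative,
  human-auditable record, retrieved transparently so callers cannot tell
  a stored document from a generated one; and
* flattened into entity-attribute-value (EAV) rows in the ``eav`` table —
  one row per supplied attribute value (plain, or per loop iteration) —
  which is what dynamic queries run against.

Because value encodings are canonical and injective per kind
(:mod:`metarepo.values`), the two representations are mutually checkable:
re-deriving the EAV rows from the XML blob must reproduce the stored rows
exactly, which :meth:`Store.consistency_check` verifies instance by
instance.

All mutating calls are atomic: a save that fails validation changes no
table.  Stored schema versions are immutable — evolution writes a new
(name, version) row, never overwrites one.  The backend is an embedded
SQLite file (or ``:memory:``); the public surface is a narrow contract a
server RDBMS could stand behind instead.

Iteration indices are 0-based internally and displayed 1-based.
"""

from __future__ import annotations

import datetime
import json
import sqlite3
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence

from . import metamodel, records
from .exceptions import (
    ConflictError,
    InstanceValidationError,
    IntegrityError,
    NotFoundError,
)
from .metamodel import DataTypeSchema
from .process_event import Event, Process, Taxonomy
from .records import DataInstance, FileRef, Subject
from .values import encode_value, numeric_value, parse_value

_DDL = """
CREATE TABLE IF NOT EXISTS datatype (
    name TEXT NOT NULL COLLATE NOCASE,
    version INTEGER NOT NULL,
    xml TEXT NOT NULL,
    PRIMARY KEY (name, version)
);
CREATE TABLE IF NOT EXISTS subject (
    subject_id TEXT PRIMARY KEY,
    sex TEXT NOT NULL,
    birth_date TEXT,
    diagnosis TEXT NOT NULL DEFAULT ''
);
CREATE TABLE IF NOT EXISTS data (
    instance_id TEXT PRIMARY KEY,
    datatype TEXT NOT NULL COLLATE NOCASE,
    version INTEGER NOT NULL,
    subject_id TEXT REFERENCES subject(subject_id),
    event_id TEXT,
    xml TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS eav (
    instance_id TEXT NOT NULL REFERENCES data(instance_id) ON DELETE CASCADE,
    ord INTEGER NOT NULL,
    grp TEXT NOT NULL,
    loop TEXT,
    iteration INTEGER,
    attribute TEXT NOT NULL,
    value_kind TEXT NOT NULL,
    value_text TEXT NOT NULL,
    value_num REAL
);
CREATE INDEX IF NOT EXISTS eav_lookup
    ON eav (attribute, grp, loop, value_text);
CREATE INDEX IF NOT EXISTS eav_instance ON eav (instance_id, ord);
CREATE TABLE IF NOT EXISTS file (
    instance_id TEXT NOT NULL REFERENCES data(instance_id) ON DELETE CASCADE,
    ord INTEGER NOT NULL,
    uri TEXT NOT NULL,
    format TEXT,
    checksum TEXT
);
CREATE TABLE IF NOT EXISTS process (
    process_id TEXT PRIMARY KEY,
    type TEXT NOT NULL,
    label TEXT NOT NULL,
    subject_id TEXT,
    parent TEXT REFERENCES process(process_id),
    ord INTEGER NOT NULL,
    started_at TEXT,
    ended_at TEXT
);
CREATE TABLE IF NOT EXISTS event (
    event_id TEXT PRIMARY KEY,
    type TEXT NOT NULL,
    process_id TEXT NOT NULL REFERENCES process(process_id),
    ord INTEGER NOT NULL,
    occurred_at TEXT,
    note TEXT
);
CREATE TABLE IF NOT EXISTS event_data (
    event_id TEXT NOT NULL REFERENCES event(event_id),
    instance_id TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS freezer (
    freezer_id TEXT PRIMARY KEY,
    temperature_class TEXT NOT NULL,
    box_cols INTEGER NOT NULL,
    box_rows INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS rack (
    freezer_id TEXT NOT NULL REFERENCES freezer(freezer_id),
    rack_id TEXT NOT NULL,
    slots INTEGER NOT NULL,
    PRIMARY KEY (freezer_id, rack_id)
);
CREATE TABLE IF NOT EXISTS sample (
    sample_id TEXT PRIMARY KEY,
    material TEXT NOT NULL,
    subject_id TEXT NOT NULL REFERENCES subject(subject_id),
    freezer_id TEXT,
    rack_id TEXT,
    slot_index INTEGER,
    x INTEGER,
    y INTEGER,
    courier_number TEXT
);
CREATE UNIQUE INDEX IF NOT EXISTS sample_slot
    ON sample (freezer_id, rack_id, slot_index, x, y)
    WHERE freezer_id IS NOT NULL;
CREATE TABLE IF NOT EXISTS sample_history (
    sample_id TEXT NOT NULL REFERENCES sample(sample_id),
    seq INTEGER NOT NULL,
    timestamp TEXT NOT NULL,
    action TEXT NOT NULL,
    freezer_id TEXT,
    rack_id TEXT,
    slot_index INTEGER,
    x INTEGER,
    y INTEGER,
    PRIMARY KEY (sample_id, seq)
);
CREATE TABLE IF NOT EXISTS ugroup (
    group_name TEXT PRIMARY KEY,
    description TEXT NOT NULL DEFAULT ''
);
CREATE TABLE IF NOT EXISTS group_member (
    group_name TEXT NOT NULL REFERENCES ugroup(group_name),
    user_id TEXT NOT NULL,
    PRIMARY KEY (group_name, user_id)
);
CREATE TABLE IF NOT EXISTS permission (
    group_name TEXT NOT NULL REFERENCES ugroup(group_name),
    resource TEXT NOT NULL,
    action TEXT NOT NULL,
    PRIMARY KEY (group_name, resource, action)
);
CREATE TABLE IF NOT EXISTS function (
    name TEXT PRIMARY KEY
);
CREATE TABLE IF NOT EXISTS oplog (
    seq INTEGER PRIMARY KEY AUTOINCREMENT,
    timestamp TEXT NOT NULL,
    user TEXT NOT NULL,
    operation TEXT NOT NULL,
    detail TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS sequence (
    name TEXT PRIMARY KEY,
    next INTEGER NOT NULL
);
"""

TABLES = (
    "datatype", "subject", "data", "eav", "file", "process", "event",
    "event_data", "freezer", "rack", "sample", "sample_history",
    "ugroup", "group_member", "permission", "function", "oplog",
)


@dataclass(frozen=True)
class EAVRow:
    """One attribute value flattened for querying."""

    instance_id: str
    datatype_name: str
    group: str
    loop: Optional[str]
    iteration: Optional[int]
    attribute: str
    value_kind: str
    value_text: str

    def display_iteration(self) -> Optional[int]:
        """Iteration shown to users (1-based); internal storage is 0-based."""
        return None if self.iteration is None else self.iteration + 1


def flatten_instance(
    instance: DataInstance, schema: DataTypeSchema
) -> list[EAVRow]:
    """Project an instance onto its EAV rows, in canonical value order.

    Paths are canonicalized against the schema, values encoded with the
    canonical injective text encoding.  Row order: plain values in
    instance order, then loop iterations in order.
    """
    rows: list[EAVRow] = []
    for av in instance.values:
        canonical, attr = schema.resolve(av.path)
        rows.append(
            EAVRow(
                instance_id=instance.instance_id,
                datatype_name=schema.name,
                group=canonical[0],
                loop=None,
                iteration=None,
                attribute=canonical[2],
                value_kind=attr.value_kind,
                value_text=encode_value(attr.value_kind, av.value),
            )
        )
    for loop_inst in instance.loops:
        loop_def = schema.resolve_loop(*loop_inst.path)
        group = schema.group(loop_inst.path[0])
        # iteration indices count only non-empty iterations, matching the
        # canonical XML form (empty iterations are omitted there)
        i = -1
        for iteration in loop_inst.iterations:
            if not iteration:
                continue
            i += 1
            for av in iteration:
                attr = loop_def.attribute(av.path[2])
                rows.append(
                    EAVRow(
                        instance_id=instance.instance_id,
                        datatype_name=schema.name,
                        group=group.name,
                        loop=loop_def.name,
                        iteration=i,
                        attribute=attr.name,
                        value_kind=attr.value_kind,
                        value_text=encode_value(attr.value_kind, av.value),
                    )
                )
    return rows


class Store:
    """One repository = one database file (or ``:memory:``)."""

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.isolation_level = None  # explicit transaction control
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._tx_depth = 0
        # executescript manages its own transaction; keep it outside _tx
        self._conn.executescript(_DDL)

    def close(self) -> None:
        self._conn.close()

    # -- transactions -------------------------------------------------------

    @contextmanager
    def _tx(self):
        """Re-entrant transaction: outermost call commits or rolls back."""
        if self._tx_depth > 0:
            self._tx_depth += 1
            try:
                yield self._conn
            finally:
                self._tx_depth -= 1
            return
        self._conn.execute("BEGIN")
        self._tx_depth = 1
        try:
            yield self._conn
        except BaseException:
            self._conn.execute("ROLLBACK")
            raise
        finally:
            self._tx_depth = 0
        self._conn.execute("COMMIT")

    @contextmanager
    def transaction(self):
        """Public atomic block: group several calls into one transaction."""
        with self._tx() as conn:
            yield conn

    def log(self, operation: str, detail: str, user: str = "system",
            timestamp: Optional[str] = None) -> None:
        """Append one line to the append-only operation log."""
        with self._tx():
            self._conn.execute(
                "INSERT INTO oplog (timestamp, user, operation, detail) "
                "VALUES (?, ?, ?, ?)",
                (timestamp or _now(), user, operation, detail),
            )

    def next_id(self, name: str) -> int:
        with self._tx():
            row = self._conn.execute(
                "SELECT next FROM sequence WHERE name = ?", (name,)
            ).fetchone()
            value = row[0] if row else 1
            self._conn.execute(
                "INSERT INTO sequence (name, next) VALUES (?, ?) "
                "ON CONFLICT(name) DO UPDATE SET next = ?",
                (name, value + 1, value + 1),
            )
            return value

    def row_counts(self) -> dict[str, int]:
        return {
            t: self._conn.execute(f"SELECT COUNT(*) FROM {t}").fetchone()[0]
            for t in TABLES
        }

    # -- schemas ------------------------------------------------------------

    def save_schema(self, schema: DataTypeSchema) -> tuple[str, int]:
        """Persist a schema version; (name, version) pairs are immutable."""
        xml = metamodel.serialize_schema(schema).decode()
        with self._tx():
            exists = self._conn.execute(
                "SELECT 1 FROM datatype WHERE name = ? AND version = ?",
                (schema.name, schema.version),
            ).fetchone()
            if exists:
                raise ConflictError(
                    f"datatype {schema.name!r} v{schema.version} already stored"
                )
            self._conn.execute(
                "INSERT INTO datatype (name, version, xml) VALUES (?, ?, ?)",
                (schema.name, schema.version, xml),
            )
        self.log("save_schema", f"{schema.name} v{schema.version}")
        return (schema.name, schema.version)

    def load_schema(self, name: str, version: Optional[int] = None) -> DataTypeSchema:
        if version is None:
            row = self._conn.execute(
                "SELECT xml FROM datatype WHERE name = ? "
                "ORDER BY version DESC LIMIT 1",
                (name,),
            ).fetchone()
        else:
            row = self._conn.execute(
                "SELECT xml FROM datatype WHERE name = ? AND version = ?",
                (name, version),
            ).fetchone()
        if row is None:
            raise NotFoundError(
                f"unknown datatype {name!r}"
                + (f" v{version}" if version is not None else "")
            )
        return metamodel.parse_schema(row[0])

    def list_datatypes(self) -> list[tuple[str, int]]:
        """(name, latest version) pairs, sorted by name."""
        return [
            tuple(r)
            for r in self._conn.execute(
                "SELECT name, MAX(version) FROM datatype GROUP BY name "
                "ORDER BY name"
            )
        ]

    def has_datatype(self, name: str) -> bool:
        return self._conn.execute(
            "SELECT 1 FROM datatype WHERE name = ? LIMIT 1", (name,)
        ).fetchone() is not None

    def has_instances(self, datatype_name: str) -> bool:
        return self._conn.execute(
            "SELECT 1 FROM data WHERE datatype = ? LIMIT 1", (datatype_name,)
        ).fetchone() is not None

    def evolve_datatype(
        self, name: str, changes: Sequence[metamodel.SchemaChange]
    ) -> DataTypeSchema:
        """Evolve the latest stored version and persist the new one."""
        schema = self.load_schema(name)
        evolved = metamodel.evolve_datatype(
            schema, changes, has_instances=self.has_instances(schema.name)
        )
        if evolved.version != schema.version:
            self.save_schema(evolved)
        return evolved

    # -- subjects -----------------------------------------------------------

    def save_subject(self, subject: Subject) -> str:
        with self._tx():
            self._conn.execute(
                "INSERT INTO subject (subject_id, sex, birth_date, diagnosis) "
                "VALUES (?, ?, ?, ?) "
                "ON CONFLICT(subject_id) DO UPDATE SET "
                "sex = excluded.sex, birth_date = excluded.birth_date, "
                "diagnosis = excluded.diagnosis",
                (subject.subject_id, subject.sex, subject.birth_date,
                 subject.diagnosis),
            )
        self.log("save_subject", subject.subject_id)
        return subject.subject_id

    def load_subject(self, subject_id: str) -> Subject:
        row = self._conn.execute(
            "SELECT subject_id, sex, birth_date, diagnosis FROM subject "
            "WHERE subject_id = ?",
            (subject_id,),
        ).fetchone()
        if row is None:
            raise NotFoundError(f"unknown subject {subject_id!r}")
        return Subject(*row)

    def list_subjects(self) -> list[Subject]:
        return [
            Subject(*row)
            for row in self._conn.execute(
                "SELECT subject_id, sex, birth_date, diagnosis FROM subject "
                "ORDER BY subject_id"
            )
        ]

    def has_subject(self, subject_id: str) -> bool:
        return self._conn.execute(
            "SELECT 1 FROM subject WHERE subject_id = ?", (subject_id,)
        ).fetchone() is not None

    # -- instances ----------------------------------------------------------

    def save_instance(self, instance: DataInstance) -> str:
        """Validate and persist an instance: XML blob + EAV rows, atomically."""
        schema = self.load_schema(instance.datatype_name, instance.datatype_version)
        report = records.validate_instance(instance, schema)
        if report:
            raise InstanceValidationError(
                f"instance {instance.instance_id or '<new>'} fails validation: "
                + "; ".join(str(v) for v in report),
                report=report,
            )
        with self._tx():
            if not instance.instance_id:
                instance = records.replace(  # type: ignore[attr-defined]
                    instance, instance_id=f"D{self.next_id('instance')}"
                )
            if instance.subject_id is not None \
                    and not self.has_subject(instance.subject_id):
                raise IntegrityError(
                    f"instance references unknown subject {instance.subject_id!r}"
                )
            if self._conn.execute(
                "SELECT 1 FROM data WHERE instance_id = ?",
                (instance.instance_id,),
            ).fetchone():
                raise ConflictError(
                    f"instance {instance.instance_id!r} already stored"
                )
            xml = records.serialize_instance(instance).decode()
            self._conn.execute(
                "INSERT INTO data (instance_id, datatype, version, subject_id, "
                "event_id, xml) VALUES (?, ?, ?, ?, ?, ?)",
                (instance.instance_id, schema.name, schema.version,
                 instance.subject_id, instance.event_id, xml),
            )
            for ord_, row in enumerate(flatten_instance(instance, schema)):
                self._conn.execute(
                    "INSERT INTO eav (instance_id, ord, grp, loop, iteration, "
                    "attribute, value_kind, value_text, value_num) "
                    "VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?)",
                    (row.instance_id, ord_, row.group, row.loop, row.iteration,
                     row.attribute, row.value_kind, row.value_text,
                     numeric_value(row.value_kind,
                                   parse_value(row.value_kind, row.value_text))),
                )
            for ord_, file_ref in enumerate(instance.files):
                self._conn.execute(
                    "INSERT INTO file (instance_id, ord, uri, format, checksum) "
                    "VALUES (?, ?, ?, ?, ?)",
                    (instance.instance_id, ord_, file_ref.uri,
                     file_ref.declared_format, file_ref.checksum),
                )
        self.log("save_instance", f"{instance.instance_id} ({schema.name})")
        return instance.instance_id

    def has_instance(self, instance_id: str) -> bool:
        return self._conn.execute(
            "SELECT 1 FROM data WHERE instance_id = ?", (instance_id,)
        ).fetchone() is not None

    def load_instance(self, instance_id: str, source: str = "xml") -> DataInstance:
        """Reconstruct an instance from either representation.

        ``source`` selects the path ("xml" blob or "eav" rows); the result
        is identical either way — the choice is invisible to callers, which
        is exactly the transparency the dual representation promises.
        """
        row = self._conn.execute(
            "SELECT datatype, version, subject_id, event_id, xml FROM data "
            "WHERE instance_id = ?",
            (instance_id,),
        ).fetchone()
        if row is None:
            raise NotFoundError(f"unknown instance {instance_id!r}")
        datatype, version, subject_id, event_id, xml = row
        schema = self.load_schema(datatype, version)
        if source == "xml":
            return records.parse_instance(xml, schema, instance_id=instance_id)
        if source == "eav":
            return self._instance_from_eav(
                instance_id, schema, subject_id, event_id
            )
        raise ValueError(f"unknown source {source!r}")

    def _instance_from_eav(
        self,
        instance_id: str,
        schema: DataTypeSchema,
        subject_id: Optional[str],
        event_id: Optional[str],
    ) -> DataInstance:
        rows = self._conn.execute(
            "SELECT grp, loop, iteration, attribute, value_kind, value_text "
            "FROM eav WHERE instance_id = ? ORDER BY ord",
            (instance_id,),
        ).fetchall()
        values: list[records.AttributeValue] = []
        loop_order: list[tuple[str, str]] = []
        loop_iters: dict[tuple[str, str], dict[int, list[records.AttributeValue]]] = {}
        for grp, loop, iteration, attribute, kind, text in rows:
            av = records.AttributeValue(
                path=(grp, loop, attribute), value=parse_value(kind, text)
            )
            if loop is None:
                values.append(av)
            else:
                key = (grp, loop)
                if key not in loop_iters:
                    loop_iters[key] = {}
                    loop_order.append(key)
                loop_iters[key].setdefault(iteration, []).append(av)
        loops = tuple(
            records.LoopInstance(
                path=key,
                iterations=tuple(
                    tuple(loop_iters[key][i])
                    for i in sorted(loop_iters[key])
                ),
            )
            for key in loop_order
        )
        files = tuple(
            FileRef(uri=uri, declared_format=fmt, checksum=checksum)
            for uri, fmt, checksum in self._conn.execute(
                "SELECT uri, format, checksum FROM file "
                "WHERE instance_id = ? ORDER BY ord",
                (instance_id,),
            )
        )
        return DataInstance(
            instance_id=instance_id,
            datatype_name=schema.name,
            datatype_version=schema.version,
            subject_id=subject_id,
            event_id=event_id,
            values=tuple(values),
            loops=loops,
            files=files,
        )

    def list_instances(
        self,
        datatype_name: Optional[str] = None,
        subject_id: Optional[str] = None,
    ) -> list[str]:
        sql = "SELECT instance_id FROM data"
        clauses, params = [], []
        if datatype_name is not None:
            clauses.append("datatype = ?")
            params.append(datatype_name)
        if subject_id is not None:
            clauses.append("subject_id = ?")
            params.append(subject_id)
        if clauses:
            sql += " WHERE " + " AND ".join(clauses)
        sql += " ORDER BY instance_id"
        return [r[0] for r in self._conn.execute(sql, params)]

    # -- dual-representation guard ------------------------------------------

    def consistency_check(self) -> list[str]:
        """Ids of instances whose EAV rows diverge from their XML blob.

        Healthy stores return an empty list.  Report-only: nothing is
        repaired.
        """
        divergent: list[str] = []
        for instance_id, datatype, version, xml in self._conn.execute(
            "SELECT instance_id, datatype, version, xml FROM data "
            "ORDER BY instance_id"
        ).fetchall():
            schema = self.load_schema(datatype, version)
            try:
                instance = records.parse_instance(
                    xml, schema, instance_id=instance_id
                )
                expected = [
                    (r.group, r.loop, r.iteration, r.attribute,
                     r.value_kind, r.value_text)
                    for r in flatten_instance(instance, schema)
                ]
            except Exception:
                divergent.append(instance_id)
                continue
            stored = [
                tuple(row)
                for row in self._conn.execute(
                    "SELECT grp, loop, iteration, attribute, value_kind, "
                    "value_text FROM eav WHERE instance_id = ? ORDER BY ord",
                    (instance_id,),
                )
            ]
            if expected != stored:
                divergent.append(instance_id)
        return divergent

    # -- processes and events -----------------------------------------------

    def bind_taxonomy(self, taxonomy: Taxonomy) -> Taxonomy:
        """Wire a taxonomy so every created process/event persists here.

        Also installs the instance resolver, so dangling event data
        references are rejected at ``add_event`` time.
        """
        taxonomy._instance_resolver = self.has_instance
        taxonomy._process_sink = self._persist_process
        taxonomy._event_sink = self._persist_event
        taxonomy._id_alloc = lambda prefix: f"{prefix}{self.next_id('node')}"
        return taxonomy

    def _child_ord(self, parent_process_id: Optional[str]) -> int:
        if parent_process_id is None:
            n = self._conn.execute(
                "SELECT COUNT(*) FROM process WHERE parent IS NULL"
            ).fetchone()[0]
            return n
        n = self._conn.execute(
            "SELECT (SELECT COUNT(*) FROM process WHERE parent = ?) + "
            "(SELECT COUNT(*) FROM event WHERE process_id = ?)",
            (parent_process_id, parent_process_id),
        ).fetchone()[0]
        return n

    def _persist_process(self, process: Process) -> None:
        parent_id = process.parent.process_id if process.parent else None
        with self._tx():
            self._conn.execute(
                "INSERT INTO process (process_id, type, label, subject_id, "
                "parent, ord, started_at, ended_at) "
                "VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
                (process.process_id, process.type_name, process.label,
                 process.subject_id, parent_id,
                 self._child_ord(parent_id),
                 process.started_at, process.ended_at),
            )

    def _persist_event(self, event: Event) -> None:
        with self._tx():
            self._conn.execute(
                "INSERT INTO event (event_id, type, process_id, ord, "
                "occurred_at, note) VALUES (?, ?, ?, ?, ?, ?)",
                (event.event_id, event.type_name, event.process.process_id,
                 self._child_ord(event.process.process_id),
                 event.occurred_at, event.note),
            )
            for instance_id in event.data:
                self._conn.execute(
                    "INSERT INTO event_data (event_id, instance_id) "
                    "VALUES (?, ?)",
                    (event.event_id, instance_id),
                )

    def save_process_tree(self, taxonomy: Taxonomy, root: Process) -> None:
        """Persist a process subtree built on an unbound taxonomy."""
        with self._tx():
            self._persist_process(root)
            for child in root.children:
                if isinstance(child, Event):
                    self._persist_event(child)
                else:
                    self.save_process_tree(taxonomy, child)

    def subject_timeline(self, subject_id: str) -> list[dict]:
        """All persisted events under the subject's processes, depth-first.

        Each entry carries the event id/type/timestamp, the owning process
        label and the linked data-instance ids.
        """
        events: list[dict] = []

        def walk(process_id: str, label: str) -> None:
            children: list[tuple[int, str, tuple]] = []
            for pid, plabel, ord_ in self._conn.execute(
                "SELECT process_id, label, ord FROM process WHERE parent = ?",
                (process_id,),
            ):
                children.append((ord_, "process", (pid, plabel)))
            for eid, etype, occurred, ord_ in self._conn.execute(
                "SELECT event_id, type, occurred_at, ord FROM event "
                "WHERE process_id = ?",
                (process_id,),
            ):
                children.append((ord_, "event", (eid, etype, occurred)))
            for ord_, kind, payload in sorted(children, key=lambda c: c[0]):
                if kind == "process":
                    walk(payload[0], payload[1])
                else:
                    eid, etype, occurred = payload
                    data = [
                        r[0]
                        for r in self._conn.execute(
                            "SELECT instance_id FROM event_data "
                            "WHERE event_id = ?",
                            (eid,),
                        )
                    ]
                    events.append(
                        {
                            "event_id": eid,
                            "type": etype,
                            "occurred_at": occurred,
                            "process": label,
                            "data": data,
                        }
                    )

        for pid, label in self._conn.execute(
            "SELECT process_id, label FROM process "
            "WHERE parent IS NULL AND subject_id = ? ORDER BY ord",
            (subject_id,),
        ).fetchall():
            walk(pid, label)
        return events

    # -- export -------------------------------------------------------------

    def export_store(self, directory: str | Path) -> Path:
        """Export the whole store as XML documents plus a JSON manifest.

        Deterministic given the store contents: files are named by key and
        the manifest serialized with sorted keys, so two stores with equal
        contents export byte-identically.
        """
        directory = Path(directory)
        (directory / "datatypes").mkdir(parents=True, exist_ok=True)
        (directory / "instances").mkdir(parents=True, exist_ok=True)
        for name, version, xml in self._conn.execute(
            "SELECT name, version, xml FROM datatype ORDER BY name, version"
        ):
            safe = name.replace(" ", "_")
            (directory / "datatypes" / f"{safe}_v{version}.xml").write_text(xml)
        for instance_id, xml in self._conn.execute(
            "SELECT instance_id, xml FROM data ORDER BY instance_id"
        ):
            (directory / "instances" / f"{instance_id}.xml").write_text(xml)
        manifest = {
            "subjects": [
                dict(zip(("subject_id", "sex", "birth_date", "diagnosis"), r))
                for r in self._conn.execute(
                    "SELECT subject_id, sex, birth_date, diagnosis "
                    "FROM subject ORDER BY subject_id"
                )
            ],
            "processes": [
                dict(zip(("process_id", "type", "label", "subject_id",
                          "parent", "ord"), r))
                for r in self._conn.execute(
                    "SELECT process_id, type, label, subject_id, parent, ord "
                    "FROM process ORDER BY process_id"
                )
            ],
            "events": [
                dict(zip(("event_id", "type", "process_id", "ord",
                          "occurred_at"), r))
                for r in self._conn.execute(
                    "SELECT event_id, type, process_id, ord, occurred_at "
                    "FROM event ORDER BY event_id"
                )
            ],
            "samples": [
                dict(zip(("sample_id", "material", "subject_id", "freezer_id",
                          "rack_id", "slot_index", "x", "y",
                          "courier_number"), r))
                for r in self._conn.execute(
                    "SELECT sample_id, material, subject_id, freezer_id, "
                    "rack_id, slot_index, x, y, courier_number "
                    "FROM sample ORDER BY sample_id"
                )
            ],
            "eav_rows": self._conn.execute(
                "SELECT COUNT(*) FROM eav"
            ).fetchone()[0],
        }
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return directory


def _now() -> str:
    return datetime.datetime.now().replace(microsecond=0).isoformat()
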