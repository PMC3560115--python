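"""Dynamic query composition over subjects and EAV metadata rows.

Queries combine *subject conditions* (diagnosis, sex, birth date) with
*data conditions* on any runtime-defined data type: either bare existence
("has one or more MRI records") or a condition on one attribute path,
whose candidate paths are enumerated automatically from the latest stored
schema — the field list fills itself from the data type definition.

Semantics, stated once and mirrored exactly by the brute-force test
oracle:

* conditions combine as a conjunction (AND accumulation only);
* each data condition is independently existential over the subject's
  instances of that type — some instance must satisfy it;
* a condition on a loop attribute matches when *some iteration* matches
  (a "smoker" is a subject with some risk-factor iteration = smoke);
* text equality is case-insensitive exact, ``contains`` is a
  case-insensitive substring — forgiving defaults for clinician-typed
  values;
* queries resolve paths against the latest schema version; instances
  pinned to older versions participate through their shared paths.

Invalid paths and operator/kind mismatches are rejected when the query is
*composed*, never at execution time.  Execution runs as SQL against the
EAV projection and returns subject ids sorted and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

from .exceptions import CompositionError, NotFoundError
from .metamodel import AttributePath, DataTypeSchema, path_str
from .records import Subject
from .storage import Store
from .values import ORDERED_KINDS, encode_value, numeric_value

SUBJECT_FIELDS = ("diagnosis", "sex", "birth_date")
ORDER_OPS = ("lt", "le", "gt", "ge")
_SQL_ORDER = {"lt": "<", "le": "<=", "gt": ">", "ge": ">="}


@dataclass(frozen=True)
class SubjectCondition:
    field: str  # diagnosis | sex | birth_date
    operator: str  # eq ne lt le gt ge contains
    value: Any


@dataclass(frozen=True)
class DataCondition:
    datatype_name: str
    mode: str = "exists"  # exists | field
    path: Optional[AttributePath] = None
    operator: Optional[str] = None  # eq ne lt le gt ge contains in
    value: Any = None


@dataclass(frozen=True)
class QuerySpec:
    """A validated conjunction of subject and data conditions."""

    subject_conditions: tuple[SubjectCondition, ...] = ()
    data_conditions: tuple[DataCondition, ...] = ()

    def to_json(self) -> dict:
        return {
            "subject": [
                {"field": c.field, "operator": c.operator, "value": _json_value(c.value)}
                for c in self.subject_conditions
            ],
            "data": [
                {
                    "datatype": c.datatype_name,
                    "mode": c.mode,
                    **(
                        {
                            "path": list(c.path),
                            "operator": c.operator,
                            "value": _json_value(c.value),
                        }
                        if c.mode == "field"
                        else {}
                    ),
                }
                for c in self.data_conditions
            ],
        }


def _json_value(value):
    if isinstance(value, (list, tuple)):
        return [_json_value(v) for v in value]
    if isinstance(value, (str, int, float, bool)) or value is None:
        return value
    return str(value)  # Decimal, date


# ---------------------------------------------------------------------------
# field enumeration


def list_fields(store: Store, datatype_name: str) -> list[AttributePath]:
    """All attribute paths of the latest schema version, in stable order.

    This is the enumeration that auto-fills the "field" parameter of a
    condition once a data type has been chosen.
    """
    schema = store.load_schema(datatype_name)  # raises NotFoundError
    return [path for path, _ in schema.iter_paths()]


# ---------------------------------------------------------------------------
# composition


def compose_query(
    store: Store,
    subject_conditions: Sequence[SubjectCondition] = (),
    data_conditions: Sequence[DataCondition] = (),
) -> QuerySpec:
    """Validate conditions against the stored schemas and build a spec.

    An empty spec is valid and matches every subject.
    """
    for cond in subject_conditions:
        if cond.field not in SUBJECT_FIELDS:
            raise CompositionError(
                f"unknown subject field {cond.field!r} "
                f"(expected one of {', '.join(SUBJECT_FIELDS)})"
            )
        if cond.field in ("diagnosis", "sex"):
            if cond.operator not in ("eq", "ne", "contains"):
                raise CompositionError(
                    f"operator {cond.operator!r} not applicable to "
                    f"{cond.field!r} (ordering applies only to birth_date)"
                )
            if not isinstance(cond.value, str):
                raise CompositionError(
                    f"subject field {cond.field!r} takes a text value"
                )
        else:  # birth_date
            if cond.operator not in ("eq", "ne") + ORDER_OPS:
                raise CompositionError(
                    f"operator {cond.operator!r} not applicable to birth_date"
                )
            if not isinstance(cond.value, str):
                raise CompositionError(
                    "birth_date conditions take an ISO-8601 date string"
                )
    resolved: list[DataCondition] = []
    for cond in data_conditions:
        try:
            schema = store.load_schema(cond.datatype_name)
        except NotFoundError:
            raise CompositionError(
                f"unknown datatype {cond.datatype_name!r} in condition"
            ) from None
        if cond.mode == "exists":
            if cond.path is not None or cond.operator is not None:
                raise CompositionError(
                    f"existence condition on {cond.datatype_name!r} "
                    "carries no path or operator"
                )
            resolved.append(
                DataCondition(datatype_name=schema.name, mode="exists")
            )
            continue
        if cond.mode != "field":
            raise CompositionError(f"unknown condition mode {cond.mode!r}")
        if cond.path is None or cond.operator is None:
            raise CompositionError(
                f"field condition on {cond.datatype_name!r} needs a path "
                "and an operator"
            )
        hit = schema.resolve(tuple(cond.path))
        if hit is None:
            raise CompositionError(
                f"unknown path {path_str(tuple(cond.path))} in datatype "
                f"{schema.name!r}"
            )
        canonical, attr = hit
        _check_operator(attr.value_kind, cond.operator, cond.value, canonical)
        resolved.append(
            DataCondition(
                datatype_name=schema.name,
                mode="field",
                path=canonical,
                operator=cond.operator,
                value=cond.value,
            )
        )
    return QuerySpec(
        subject_conditions=tuple(subject_conditions),
        data_conditions=tuple(resolved),
    )


def _check_operator(kind: str, operator: str, value: Any,
                    path: AttributePath) -> None:
    where = path_str(path)
    if operator in ORDER_OPS:
        if kind not in ORDERED_KINDS:
            raise CompositionError(
                f"{where}: ordering operator {operator!r} not applicable "
                f"to kind {kind!r}"
            )
    elif operator == "contains":
        if kind not in ("text", "enumeration"):
            raise CompositionError(
                f"{where}: 'contains' applies only to text attributes"
            )
    elif operator == "in":
        if not isinstance(value, (list, tuple)) or not value:
            raise CompositionError(
                f"{where}: 'in' takes a non-empty list of values"
            )
    elif operator not in ("eq", "ne"):
        raise CompositionError(f"{where}: unknown operator {operator!r}")
    candidates = value if operator == "in" else [value]
    from .values import check_value

    for candidate in candidates:
        if not check_value(kind, candidate) and not (
            kind == "enumeration" and isinstance(candidate, str)
        ):
            raise CompositionError(
                f"{where}: value {candidate!r} does not satisfy kind {kind!r}"
            )


# ---------------------------------------------------------------------------
# execution (SQL over the EAV projection)


def execute_query(store: Store, spec: QuerySpec) -> list[str]:
    """Subject ids satisfying the whole conjunction, sorted, deterministic."""
    clauses: list[str] = []
    params: list = []
    for cond in spec.subject_conditions:
        clause, cond_params = _subject_sql(cond)
        clauses.append(clause)
        params.extend(cond_params)
    for cond in spec.data_conditions:
        clause, cond_params = _data_sql(store, cond)
        clauses.append(clause)
        params.extend(cond_params)
    sql = "SELECT s.subject_id FROM subject s"
    if clauses:
        sql += " WHERE " + " AND ".join(clauses)
    sql += " ORDER BY s.subject_id"
    return [row[0] for row in store._conn.execute(sql, params)]


def _subject_sql(cond: SubjectCondition) -> tuple[str, list]:
    column = {"diagnosis": "s.diagnosis", "sex": "s.sex",
              "birth_date": "s.birth_date"}[cond.field]
    if cond.field == "birth_date":
        if cond.operator == "eq":
            return f"{column} = ?", [cond.value]
        if cond.operator == "ne":
            return f"{column} <> ?", [cond.value]
        return f"{column} {_SQL_ORDER[cond.operator]} ?", [cond.value]
    if cond.operator == "eq":
        return f"lower({column}) = lower(?)", [cond.value]
    if cond.operator == "ne":
        return f"lower({column}) <> lower(?)", [cond.value]
    return f"instr(lower({column}), lower(?)) > 0", [cond.value]


def _data_sql(store: Store, cond: DataCondition) -> tuple[str, list]:
    if cond.mode == "exists":
        return (
            "EXISTS (SELECT 1 FROM data d WHERE d.subject_id = s.subject_id "
            "AND d.datatype = ?)",
            [cond.datatype_name],
        )
    schema = store.load_schema(cond.datatype_name)
    _, attr = schema.resolve(cond.path)
    group, loop, attribute = cond.path
    loop_clause = "e.loop = ?" if loop is not None else "e.loop IS NULL"
    base = (
        "EXISTS (SELECT 1 FROM data d JOIN eav e "
        "ON e.instance_id = d.instance_id "
        "WHERE d.subject_id = s.subject_id AND d.datatype = ? "
        f"AND e.grp = ? AND {loop_clause} AND e.attribute = ? AND {{pred}})"
    )
    params: list = [cond.datatype_name, group]
    if loop is not None:
        params.append(loop)
    params.append(attribute)
    pred, pred_params = _value_predicate(attr.value_kind, cond.operator, cond.value)
    return base.format(pred=pred), params + pred_params


def _value_predicate(kind: str, operator: str, value: Any) -> tuple[str, list]:
    if operator == "in":
        encoded = [encode_value(kind, v) if kind != "enumeration"
                   else v for v in value]
        placeholders = ", ".join("?" for _ in encoded)
        if kind in ("text", "enumeration"):
            return (
                f"lower(e.value_text) IN ({placeholders})",
                [v.lower() for v in encoded],
            )
        return f"e.value_text IN ({placeholders})", encoded
    if operator in ORDER_OPS:
        op = _SQL_ORDER[operator]
        if kind in ("integer", "decimal"):
            return f"e.value_num {op} ?", [numeric_value(kind, value)]
        # dates: ISO-8601 text orders chronologically
        return f"e.value_text {op} ?", [encode_value(kind, value)]
    encoded = encode_value(kind, value)
    if kind in ("text", "enumeration"):
        if operator == "eq":
            return "lower(e.value_text) = lower(?)", [encoded]
        if operator == "ne":
            return "lower(e.value_text) <> lower(?)", [encoded]
        return "instr(lower(e.value_text), lower(?)) > 0", [encoded]
    if kind in ("integer", "decimal"):
        op = "=" if operator == "eq" else "<>"
        return f"e.value_num {op} ?", [numeric_value(kind, value)]
    op = "=" if operator == "eq" else "<>"
    return f"e.value_text {op} ?", [encoded]


# ---------------------------------------------------------------------------
# integrated per-subject overview


@dataclass(frozen=True)
class InstanceSummary:
    instance_id: str
    values: tuple[tuple[str, str], ...]  # (display path, encoded value)
    files: tuple[str, ...]


@dataclass(frozen=True)
class Overview:
    """All of one subject's data, grouped by datatype, plus the timeline."""

    subject: Subject
    sections: tuple[tuple[str, tuple[InstanceSummary, ...]], ...]
    timeline: tuple[dict, ...]

    def render_text(self) -> str:
        lines = [
            f"Subject {self.subject.subject_id}",
            f"  sex: {self.subject.sex}",
            f"  birth date: {self.subject.birth_date}",
            f"  diagnosis: {self.subject.diagnosis}",
        ]
        for datatype, summaries in self.sections:
            lines.append(f"[{datatype}] ({len(summaries)} record(s))")
            for summary in summaries:
                lines.append(f"  {summary.instance_id}:")
                for path, value in summary.values:
                    lines.append(f"    {path} = {value}")
                for uri in summary.files:
                    lines.append(f"    file: {uri}")
        if self.timeline:
            lines.append("Timeline:")
            for entry in self.timeline:
                refs = f" [{', '.join(entry['data'])}]" if entry["data"] else ""
                lines.append(
                    f"  {entry['occurred_at'] or '-'}  {entry['type']} "
                    f"({entry['process']}){refs}"
                )
        return "\n".join(lines)

    def render_html(self) -> str:
        from lxml import etree

        root = etree.Element("div", attrib={"class": "subject-overview"})
        head = etree.SubElement(root, "h2")
        head.text = f"Subject {self.subject.subject_id}"
        dl = etree.SubElement(root, "dl")
        for label, value in (
            ("sex", self.subject.sex),
            ("birth date", str(self.subject.birth_date)),
            ("diagnosis", self.subject.diagnosis),
        ):
            etree.SubElement(dl, "dt").text = label
            etree.SubElement(dl, "dd").text = value
        for datatype, summaries in self.sections:
            section = etree.SubElement(
                root, "section", attrib={"class": "datatype",
                                         "data-datatype": datatype}
            )
            etree.SubElement(section, "h3").text = datatype
            for summary in summaries:
                table = etree.SubElement(
                    section, "table", attrib={"data-instance": summary.instance_id}
                )
                for path, value in summary.values:
                    tr = etree.SubElement(table, "tr")
                    etree.SubElement(tr, "td").text = path
                    etree.SubElement(tr, "td").text = value
                for uri in summary.files:
                    tr = etree.SubElement(table, "tr")
                    etree.SubElement(tr, "td").text = "file"
                    etree.SubElement(tr, "td").text = uri
        if self.timeline:
            timeline_el = etree.SubElement(
                root, "section", attrib={"class": "timeline"}
            )
            etree.SubElement(timeline_el, "h3").text = "Timeline"
            ol = etree.SubElement(timeline_el, "ol")
            for entry in self.timeline:
                li = etree.SubElement(ol, "li")
                li.text = (
                    f"{entry['occurred_at'] or '-'} {entry['type']} "
                    f"({entry['process']})"
                )
        return etree.tostring(root, pretty_print=True, encoding="unicode")


def subject_overview(
    store: Store,
    subject_id: str,
    user: Optional[str] = None,
) -> Overview:
    """Integrated view of everything recorded for one subject.

    With *user* given, access control applies: data types the user cannot
    view are omitted entirely and personal fields the user may not see are
    masked in the subject header (see :mod:`metarepo.access`).
    """
    subject = store.load_subject(subject_id)  # raises NotFoundError
    if user is not None:
        from .access import masked_view

        subject = masked_view(store, user, subject)
    sections: list[tuple[str, tuple[InstanceSummary, ...]]] = []
    for datatype, _version in store.list_datatypes():
        if user is not None:
            from .access import check_access

            if not check_access(store, user, f"datatype:{datatype}", "view"):
                continue
        summaries = []
        for instance_id in store.list_instances(
            datatype_name=datatype, subject_id=subject_id
        ):
            rows = store._conn.execute(
                "SELECT grp, loop, iteration, attribute, value_text FROM eav "
                "WHERE instance_id = ? ORDER BY ord",
                (instance_id,),
            ).fetchall()
            values = tuple(
                (
                    f"{grp}.{loop}[{iteration + 1}].{attribute}"
                    if loop is not None
                    else f"{grp}.{attribute}",
                    text,
                )
                for grp, loop, iteration, attribute, text in rows
            )
            files = tuple(
                r[0]
                for r in store._conn.execute(
                    "SELECT uri FROM file WHERE instance_id = ? ORDER BY ord",
                    (instance_id,),
                )
            )
            summaries.append(
                InstanceSummary(
                    instance_id=instance_id, values=values, files=files
                )
            )
        sections.append((datatype, tuple(summaries)))
    return Overview(
        subject=subject,
        sections=tuple(sections),
        timeline=tuple(store.subject_timeline(subject_id)),
    )
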