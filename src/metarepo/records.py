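"""Data instances: records conforming to runtime-defined data types.

An instance pins the exact datatype name and version it was entered
under, references an anonymous subject, optionally an event in the
provenance tree, and carries plain attribute values, loop iterations and
(for file-associated types such as imaging data) file URIs.

Subjects are deliberately anonymous: the type has *no slot* for a
personal name.  The link between a repository subject and a person is an
opaque identifier managed outside the system by clinicians.

Validation is total and deterministic: every (instance, schema) pair
yields a report of violations — possibly empty — and each violation names
the offending attribute path and the reason.  A missing required
attribute that carries a schema default counts as satisfied (the default
applies), which is what keeps historical instances valid when a schema
later gains a required-with-default attribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Optional, Sequence, Union
from urllib.parse import urlparse

from lxml import etree

from .exceptions import AssociationError, SchemaParseError, ValidationUsageError
from .metamodel import (
    AttributeDef,
    AttributePath,
    DataTypeSchema,
    LoopDef,
    path_str,
)
from .values import encode_value, parse_value


@dataclass(frozen=True)
class Subject:
    """An anonymous study participant.

    Only the opaque identifier, sex, birth date and diagnosis are stored;
    by construction there is no field that could hold a personal name.
    """

    subject_id: str
    sex: str = "other/unknown"  # male | female | other/unknown
    birth_date: Optional[str] = None  # ISO-8601 calendar date
    diagnosis: str = ""


@dataclass(frozen=True)
class AttributeValue:
    """One supplied value, addressed by its (group, loop?, attribute) path."""

    path: AttributePath
    value: Any

    def __post_init__(self):
        object.__setattr__(self, "path", tuple(self.path))


@dataclass(frozen=True)
class LoopInstance:
    """Iterations of a loop: an ordered list of iteration value lists."""

    path: tuple[str, str]  # (group, loop)
    iterations: tuple[tuple[AttributeValue, ...], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "path", tuple(self.path))
        object.__setattr__(
            self, "iterations", tuple(tuple(it) for it in self.iterations)
        )


@dataclass(frozen=True)
class FileRef:
    """A URI pointing at an associated payload file (never the payload)."""

    uri: str
    declared_format: Optional[str] = None
    checksum: Optional[str] = None

    def __post_init__(self):
        if not self.uri or not _is_uri(self.uri):
            raise ValueError(f"not a valid URI: {self.uri!r}")


def _is_uri(text: str) -> bool:
    try:
        parsed = urlparse(text)
    except ValueError:
        return False
    # absolute URI (scheme) or a plain relative path reference
    return bool(parsed.scheme or parsed.path)


@dataclass(frozen=True)
class DataInstance:
    """One record of a runtime-defined data type.

    ``subject_id`` may be None for study-level configuration records
    (e.g. a gene-screening setup) that do not belong to one participant.
    """

    instance_id: str
    datatype_name: str
    datatype_version: int
    subject_id: Optional[str]
    values: tuple[AttributeValue, ...] = ()
    loops: tuple[LoopInstance, ...] = ()
    files: tuple[FileRef, ...] = ()
    event_id: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "values", tuple(self.values))
        object.__setattr__(self, "loops", tuple(self.loops))
        object.__setattr__(self, "files", tuple(self.files))


@dataclass(frozen=True)
class Violation:
    """One validation problem, pinned to an attribute path."""

    path: str
    reason: str

    def __str__(self) -> str:  # pragma: no cover - display helper
        return f"{self.path}: {self.reason}"


# ---------------------------------------------------------------------------
# validation


def validate_instance(
    instance: DataInstance, schema: DataTypeSchema
) -> list[Violation]:
    """Check an instance against its pinned schema; return all violations.

    Raises :class:`ValidationUsageError` when the schema is not the one the
    instance names — that is a caller bug, not a data problem.
    """
    if instance.datatype_name.lower() != schema.name.lower() \
            or instance.datatype_version != schema.version:
        raise ValidationUsageError(
            f"instance pins {instance.datatype_name!r} v{instance.datatype_version}, "
            f"got schema {schema.name!r} v{schema.version}"
        )
    violations: list[Violation] = []
    supplied: set[AttributePath] = set()

    for av in instance.values:
        resolved = schema.resolve((av.path[0], av.path[1], av.path[2]))
        if av.path[1] is not None or resolved is None:
            violations.append(Violation(path_str(av.path), "unknown attribute path"))
            continue
        canonical, attr = resolved
        if canonical in supplied:
            violations.append(Violation(path_str(canonical), "duplicate value"))
            continue
        supplied.add(canonical)
        if not attr.accepts(av.value):
            violations.append(
                Violation(
                    path_str(canonical),
                    f"value {av.value!r} does not satisfy kind "
                    f"{attr.value_kind!r}"
                    + (
                        f" (allowed: {', '.join(attr.allowed_values)})"
                        if attr.value_kind == "enumeration"
                        else ""
                    ),
                )
            )

    seen_loops: set[tuple[str, str]] = set()
    for loop_inst in instance.loops:
        gname, lname = loop_inst.path
        loop_def = schema.resolve_loop(gname, lname)
        if loop_def is None:
            violations.append(
                Violation(f"{gname}.{lname}", "unknown loop path")
            )
            continue
        group = schema.group(gname)
        key = (group.name.lower(), loop_def.name.lower())
        if key in seen_loops:
            violations.append(
                Violation(f"{group.name}.{loop_def.name}", "duplicate loop block")
            )
            continue
        seen_loops.add(key)
        for i, iteration in enumerate(loop_inst.iterations):
            present: set[str] = set()
            for av in iteration:
                if (av.path[0].lower(), (av.path[1] or "").lower()) != key:
                    violations.append(
                        Violation(
                            path_str(av.path),
                            f"iteration value outside loop {group.name}.{loop_def.name}",
                        )
                    )
                    continue
                attr = loop_def.attribute(av.path[2])
                if attr is None:
                    violations.append(
                        Violation(path_str(av.path), "unknown attribute path")
                    )
                    continue
                if attr.name.lower() in present:
                    violations.append(
                        Violation(
                            f"{group.name}.{loop_def.name}.{attr.name}[{i}]",
                            "duplicate value in iteration",
                        )
                    )
                    continue
                present.add(attr.name.lower())
                if not attr.accepts(av.value):
                    violations.append(
                        Violation(
                            f"{group.name}.{loop_def.name}.{attr.name}[{i}]",
                            f"value {av.value!r} does not satisfy kind "
                            f"{attr.value_kind!r}",
                        )
                    )
            for attr in loop_def.attributes:
                if attr.required and attr.name.lower() not in present \
                        and attr.default is None:
                    violations.append(
                        Violation(
                            f"{group.name}.{loop_def.name}.{attr.name}[{i}]",
                            "required loop attribute missing",
                        )
                    )

    # required plain attributes
    for path, attr in schema.iter_paths():
        if path[1] is not None:
            continue
        if attr.required and path not in supplied and attr.default is None:
            violations.append(
                Violation(path_str(path), "required attribute missing")
            )

    if instance.files and not schema.header.file_associated:
        violations.append(
            Violation(
                "<files>",
                f"datatype {schema.name!r} is not file-associated",
            )
        )
    return violations


# ---------------------------------------------------------------------------
# file association


def attach_file(
    instance: DataInstance, file: FileRef, schema: DataTypeSchema
) -> DataInstance:
    """Return a copy of *instance* with *file* appended.

    Only file-associated data types (e.g. imaging) accept files; clinical
    data types do not, and attaching raises :class:`AssociationError`.
    """
    if not schema.header.file_associated:
        raise AssociationError(
            f"datatype {schema.name!r} is not file-associated; "
            "cannot attach files"
        )
    return replace(instance, files=instance.files + (file,))


# ---------------------------------------------------------------------------
# instance XML dialect


def serialize_instance(instance: DataInstance) -> bytes:
    """Serialize to the instance dialect (root ``data``, UTF-8)."""
    root = etree.Element(
        "data",
        datatype=instance.datatype_name,
        version=str(instance.datatype_version),
    )
    if instance.subject_id is not None:
        root.set("subject", instance.subject_id)
    if instance.event_id is not None:
        root.set("event", instance.event_id)
    # groups in first-appearance order, plain values then loops, each in
    # instance order: parse returns exactly this order, giving round-trip
    # identity for instances assembled group-by-group
    group_order: list[str] = []
    for av in instance.values:
        if av.path[0] not in group_order:
            group_order.append(av.path[0])
    for loop_inst in instance.loops:
        if loop_inst.path[0] not in group_order:
            group_order.append(loop_inst.path[0])
    for gname in group_order:
        group_el = etree.SubElement(root, "group", name=gname)
        for av in instance.values:
            if av.path[0] != gname:
                continue
            el = etree.SubElement(group_el, "attribute", name=av.path[2])
            el.text = _encode_for_xml(av)
        for loop_inst in instance.loops:
            if loop_inst.path[0] != gname:
                continue
            # canonical form: loop blocks and iterations without values are
            # omitted, keeping the XML and EAV projections equivalent
            if not any(loop_inst.iterations):
                continue
            loop_el = etree.SubElement(group_el, "loop", name=loop_inst.path[1])
            for iteration in loop_inst.iterations:
                if not iteration:
                    continue
                it_el = etree.SubElement(loop_el, "iteration")
                for av in iteration:
                    el = etree.SubElement(it_el, "attribute", name=av.path[2])
                    el.text = _encode_for_xml(av)
    for file_ref in instance.files:
        file_el = etree.SubElement(root, "file", uri=file_ref.uri)
        if file_ref.declared_format:
            file_el.set("format", file_ref.declared_format)
        if file_ref.checksum:
            file_el.set("checksum", file_ref.checksum)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _encode_for_xml(av: AttributeValue) -> str:
    # the XML layer stores the canonical text encoding; kind comes from the
    # schema at parse time
    from .values import check_value

    for kind in ("boolean", "integer", "decimal", "date"):
        if check_value(kind, av.value):
            return encode_value(kind, av.value)
    return str(av.value)


def parse_instance(
    doc: Union[bytes, str],
    schema: DataTypeSchema,
    instance_id: str = "",
) -> DataInstance:
    """Parse an instance document and validate it against *schema*.

    Raises :class:`SchemaParseError` on malformed documents, datatype
    mismatch, kind violations or any validation violation — a parsed
    instance is always a valid one.
    """
    try:
        root = etree.fromstring(doc.encode() if isinstance(doc, str) else doc)
    except etree.XMLSyntaxError as exc:
        raise SchemaParseError(f"not well-formed XML: {exc}") from exc
    if root.tag != "data":
        raise SchemaParseError(f"expected root element 'data', got {root.tag!r}")
    datatype = root.get("datatype", "")
    if datatype.lower() != schema.name.lower():
        raise SchemaParseError(
            f"document datatype {datatype!r} does not match schema {schema.name!r}"
        )
    try:
        version = int(root.get("version", "0"))
    except ValueError:
        raise SchemaParseError("data/@version is not an integer")
    if version != schema.version:
        raise SchemaParseError(
            f"document pins version {version}, schema is v{schema.version}"
        )
    values: list[AttributeValue] = []
    loops: list[LoopInstance] = []
    files: list[FileRef] = []
    for child in root:
        if child.tag == "group":
            gname = child.get("name", "")
            for member_el in child:
                if member_el.tag == "attribute":
                    values.append(
                        _parse_value_el(schema, gname, None, member_el)
                    )
                elif member_el.tag == "loop":
                    lname = member_el.get("name", "")
                    iterations = []
                    for it_el in member_el:
                        if it_el.tag != "iteration":
                            raise SchemaParseError(
                                f"unknown element 'loop/{it_el.tag}'"
                            )
                        iteration = []
                        for attr_el in it_el:
                            if attr_el.tag != "attribute":
                                raise SchemaParseError(
                                    f"unknown element 'iteration/{attr_el.tag}'"
                                )
                            iteration.append(
                                _parse_value_el(schema, gname, lname, attr_el)
                            )
                        iterations.append(tuple(iteration))
                    loops.append(
                        LoopInstance(path=(gname, lname), iterations=tuple(iterations))
                    )
                else:
                    raise SchemaParseError(
                        f"unknown element 'group/{member_el.tag}'"
                    )
        elif child.tag == "file":
            uri = child.get("uri", "")
            if not uri:
                raise SchemaParseError("file element without uri")
            files.append(
                FileRef(
                    uri=uri,
                    declared_format=child.get("format"),
                    checksum=child.get("checksum"),
                )
            )
        else:
            raise SchemaParseError(f"unknown element 'data/{child.tag}'")
    instance = DataInstance(
        instance_id=instance_id,
        datatype_name=datatype,
        datatype_version=version,
        subject_id=root.get("subject"),
        event_id=root.get("event"),
        values=tuple(values),
        loops=tuple(loops),
        files=tuple(files),
    )
    report = validate_instance(instance, schema)
    if report:
        raise SchemaParseError(
            "instance document fails validation: "
            + "; ".join(str(v) for v in report)
        )
    return instance


def _parse_value_el(
    schema: DataTypeSchema,
    gname: str,
    lname: Optional[str],
    el: etree._Element,
) -> AttributeValue:
    aname = el.get("name", "")
    resolved = schema.resolve((gname, lname, aname))
    if resolved is None:
        raise SchemaParseError(
            f"unknown attribute path {path_str((gname, lname, aname))}"
        )
    canonical, attr = resolved
    text = el.text or ""
    try:
        value = parse_value(attr.value_kind, text)
    except ValueError as exc:
        raise SchemaParseError(
            f"{path_str(canonical)}: {exc} (kind {attr.value_kind!r})"
        ) from exc
    return AttributeValue(path=canonical, value=value)
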