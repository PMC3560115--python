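"""Runtime-definable data types: the "meta" data model.

A *data type* is the minimum set of information describing one data
instance (a clinical evaluation, the parameters of an MRI scan, a serum
biomarker panel...).  Users define data types at run time — no schema
migration, no application rebuild — as a header plus one or more *groups*
of typed attributes and *loops*.  A loop is a repeatable block of
attributes for information whose shape is known but whose multiplicity is
not: one iteration per reagent in an assay, one per cardiovascular risk
factor in an anamnesis.

Data types serialize to a small XML dialect (root ``datatype``,
``dialect="xtens-1"``) with a deterministic element order, so that
serialize → parse is the identity and re-serialization is byte-identical.

Schema *evolution* is additive-only once instances exist: attributes,
loops, groups and enumeration labels can be added, and required attributes
relaxed to optional, without invalidating any stored instance.  Attribute
names may be auto-completed from OBO ontologies (e.g. OBI, SO) through a
prefix-suggestion catalog, encouraging standard annotations.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from typing import Any, Iterator, Optional, Sequence, Union

from lxml import etree

from .exceptions import EvolutionError, SchemaParseError, SchemaStructureError
from .values import VALUE_KINDS, check_value, encode_value, parse_value

DIALECT = "xtens-1"

#: a fully qualified attribute path: (group, loop-or-None, attribute)
AttributePath = tuple[str, Optional[str], str]


def path_str(path: AttributePath) -> str:
    group, loop, attr = path
    return f"{group}.{loop}.{attr}" if loop else f"{group}.{attr}"


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class OntologyTermRef:
    """A pointer to a term in a loaded ontology (e.g. OBI, SO)."""

    ontology_id: str
    term_id: str
    label: str

    def __post_init__(self):
        if not self.term_id or not self.label:
            raise SchemaStructureError(
                "ontology term reference needs a non-empty term_id and label"
            )


@dataclass(frozen=True)
class AttributeDef:
    """One metadata attribute: a named, typed, optionally constrained slot."""

    name: str
    value_kind: str = "text"
    required: bool = False
    allowed_values: tuple[str, ...] = ()
    unit: Optional[str] = None
    ontology_ref: Optional[OntologyTermRef] = None
    default: Any = None

    def __post_init__(self):
        if not self.name:
            raise SchemaStructureError("attribute name must be non-empty")
        if self.value_kind not in VALUE_KINDS:
            raise SchemaStructureError(
                f"attribute {self.name!r}: unknown value kind {self.value_kind!r}"
            )
        object.__setattr__(self, "allowed_values", tuple(self.allowed_values))
        if self.value_kind == "enumeration":
            distinct = {v for v in self.allowed_values}
            if not distinct:
                raise SchemaStructureError(
                    f"enumeration attribute {self.name!r} needs >=1 allowed value"
                )
            if len(distinct) != len(self.allowed_values):
                raise SchemaStructureError(
                    f"enumeration attribute {self.name!r} repeats an allowed value"
                )
        elif self.allowed_values:
            raise SchemaStructureError(
                f"attribute {self.name!r}: allowed_values only apply to enumerations"
            )
        if self.default is not None:
            if not check_value(self.value_kind, self.default):
                raise SchemaStructureError(
                    f"attribute {self.name!r}: default {self.default!r} does not "
                    f"satisfy kind {self.value_kind!r}"
                )
            if self.value_kind == "enumeration" and self.default not in self.allowed_values:
                raise SchemaStructureError(
                    f"attribute {self.name!r}: default {self.default!r} is not an "
                    "allowed enumeration value"
                )

    def accepts(self, value: Any) -> bool:
        if not check_value(self.value_kind, value):
            return False
        if self.value_kind == "enumeration" and value not in self.allowed_values:
            return False
        return True


@dataclass(frozen=True)
class LoopDef:
    """A repeatable block of attributes (loops never nest)."""

    name: str
    attributes: tuple[AttributeDef, ...]

    def __post_init__(self):
        if not self.name:
            raise SchemaStructureError("loop name must be non-empty")
        object.__setattr__(self, "attributes", tuple(self.attributes))
        if not self.attributes:
            raise SchemaStructureError(f"loop {self.name!r} needs >=1 attribute")
        _check_unique((a.name for a in self.attributes), f"loop {self.name!r}")

    def attribute(self, name: str) -> Optional[AttributeDef]:
        lowered = name.lower()
        for a in self.attributes:
            if a.name.lower() == lowered:
                return a
        return None


@dataclass(frozen=True)
class MetadataGroup:
    """A named group of attributes and loops sharing one namespace."""

    name: str
    members: tuple[Union[AttributeDef, LoopDef], ...]

    def __post_init__(self):
        if not self.name:
            raise SchemaStructureError("group name must be non-empty")
        object.__setattr__(self, "members", tuple(self.members))
        if not self.members:
            raise SchemaStructureError(f"group {self.name!r} needs >=1 member")
        _check_unique((m.name for m in self.members), f"group {self.name!r}")

    @property
    def attributes(self) -> tuple[AttributeDef, ...]:
        return tuple(m for m in self.members if isinstance(m, AttributeDef))

    @property
    def loops(self) -> tuple[LoopDef, ...]:
        return tuple(m for m in self.members if isinstance(m, LoopDef))

    def member(self, name: str) -> Optional[Union[AttributeDef, LoopDef]]:
        lowered = name.lower()
        for m in self.members:
            if m.name.lower() == lowered:
                return m
        return None


@dataclass(frozen=True)
class SchemaHeader:
    """General information about a data type, independent of its structure."""

    datatype_name: str
    version: int = 1
    description: str = ""
    file_associated: bool = False
    created_by: str = ""
    created_at: str = ""

    def __post_init__(self):
        if not self.datatype_name:
            raise SchemaStructureError("datatype name must be non-empty")
        if self.version < 1:
            raise SchemaStructureError("schema version must be >= 1")
        if not self.created_at:
            object.__setattr__(
                self,
                "created_at",
                datetime.datetime.now().replace(microsecond=0).isoformat(),
            )


@dataclass(frozen=True)
class DataTypeSchema:
    """A validated runtime data type: header plus ordered metadata groups."""

    header: SchemaHeader
    groups: tuple[MetadataGroup, ...]

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        if not self.groups:
            raise SchemaStructureError(
                f"datatype {self.header.datatype_name!r} needs >=1 group"
            )
        _check_unique(
            (g.name for g in self.groups),
            f"datatype {self.header.datatype_name!r}",
        )
        # full path uniqueness is implied by per-level uniqueness, but check
        # anyway so no invalid schema can ever be constructed
        _check_unique(
            (path_str(p) for p, _ in self.iter_paths()),
            f"datatype {self.header.datatype_name!r}",
        )

    @property
    def name(self) -> str:
        return self.header.datatype_name

    @property
    def version(self) -> int:
        return self.header.version

    def iter_paths(self) -> Iterator[tuple[AttributePath, AttributeDef]]:
        """All (group, loop?, attribute) paths in stable definition order."""
        for group in self.groups:
            for member in group.members:
                if isinstance(member, AttributeDef):
                    yield (group.name, None, member.name), member
                else:
                    for attr in member.attributes:
                        yield (group.name, member.name, attr.name), attr

    def group(self, name: str) -> Optional[MetadataGroup]:
        lowered = name.lower()
        for g in self.groups:
            if g.name.lower() == lowered:
                return g
        return None

    def resolve(self, path: AttributePath) -> Optional[tuple[AttributePath, AttributeDef]]:
        """Case-insensitive path lookup; returns the canonical path + def."""
        group = self.group(path[0])
        if group is None:
            return None
        if path[1] is None:
            member = group.member(path[2])
            if isinstance(member, AttributeDef):
                return (group.name, None, member.name), member
            return None
        member = group.member(path[1])
        if not isinstance(member, LoopDef):
            return None
        attr = member.attribute(path[2])
        if attr is None:
            return None
        return (group.name, member.name, attr.name), attr

    def resolve_loop(self, group_name: str, loop_name: str) -> Optional[LoopDef]:
        group = self.group(group_name)
        if group is None:
            return None
        member = group.member(loop_name)
        return member if isinstance(member, LoopDef) else None


def _check_unique(names: Iterator[str] | Sequence[str], where: str) -> None:
    seen: dict[str, str] = {}
    for name in names:
        key = name.lower()
        if key in seen:
            raise SchemaStructureError(
                f"{where}: case-insensitive name collision between "
                f"{seen[key]!r} and {name!r}"
            )
        seen[key] = name


# ---------------------------------------------------------------------------
# definition


def define_datatype(header: SchemaHeader, groups: Sequence[MetadataGroup]) -> DataTypeSchema:
    """Validate and assemble a new data type, usable immediately.

    The version is forced to 1: new types always start a fresh lineage, and
    later structure changes go through :func:`evolve_datatype`.
    """
    header = replace(header, version=1)
    return DataTypeSchema(header=header, groups=tuple(groups))


# ---------------------------------------------------------------------------
# XML dialect

_BOOL = {"true": True, "false": False}


def serialize_schema(schema: DataTypeSchema) -> bytes:
    """Serialize to the ``xtens-1`` datatype dialect (UTF-8, deterministic)."""
    root = etree.Element("datatype", dialect=DIALECT)
    header = etree.SubElement(root, "header")
    h = schema.header
    etree.SubElement(header, "name").text = h.datatype_name
    etree.SubElement(header, "version").text = str(h.version)
    etree.SubElement(header, "description").text = h.description or ""
    etree.SubElement(header, "fileAssociated").text = (
        "true" if h.file_associated else "false"
    )
    etree.SubElement(header, "createdBy").text = h.created_by or ""
    etree.SubElement(header, "createdAt").text = h.created_at
    metadata = etree.SubElement(root, "metadata")
    for group in schema.groups:
        g = etree.SubElement(metadata, "group", name=group.name)
        for member in group.members:
            if isinstance(member, AttributeDef):
                _attr_element(g, member)
            else:
                loop = etree.SubElement(g, "loop", name=member.name)
                for attr in member.attributes:
                    _attr_element(loop, attr)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _attr_element(parent: etree._Element, attr: AttributeDef) -> None:
    el = etree.SubElement(
        parent,
        "attribute",
        name=attr.name,
        type=attr.value_kind,
        required="true" if attr.required else "false",
    )
    if attr.unit is not None:
        etree.SubElement(el, "unit").text = attr.unit
    for allowed in attr.allowed_values:
        etree.SubElement(el, "allowedValue").text = allowed
    if attr.ontology_ref is not None:
        onto = etree.SubElement(el, "ontology")
        etree.SubElement(onto, "source").text = attr.ontology_ref.ontology_id
        etree.SubElement(onto, "termId").text = attr.ontology_ref.term_id
        etree.SubElement(onto, "label").text = attr.ontology_ref.label
    if attr.default is not None:
        etree.SubElement(el, "default").text = encode_value(
            attr.value_kind, attr.default
        )


def parse_schema(doc: Union[bytes, str]) -> DataTypeSchema:
    """Parse a datatype document back into a validated schema."""
    try:
        root = etree.fromstring(doc.encode() if isinstance(doc, str) else doc)
    except etree.XMLSyntaxError as exc:
        raise SchemaParseError(f"not well-formed XML: {exc}") from exc
    if root.tag != "datatype":
        raise SchemaParseError(f"expected root element 'datatype', got {root.tag!r}")
    header_el = root.find("header")
    if header_el is None:
        raise SchemaParseError("missing 'header' section in datatype document")
    metadata_el = root.find("metadata")
    if metadata_el is None:
        raise SchemaParseError("missing 'metadata' section in datatype document")
    for child in root:
        if child.tag not in ("header", "metadata"):
            raise SchemaParseError(f"unknown element 'datatype/{child.tag}'")

    def _text(tag: str, default: str | None = None) -> str:
        el = header_el.find(tag)
        if el is None:
            if default is None:
                raise SchemaParseError(f"missing element 'header/{tag}'")
            return default
        return el.text or ""

    version_text = _text("version", "1")
    try:
        version = int(version_text)
    except ValueError:
        raise SchemaParseError(f"header/version is not an integer: {version_text!r}")
    try:
        header = SchemaHeader(
            datatype_name=_text("name"),
            version=version,
            description=_text("description", ""),
            file_associated=_BOOL.get(_text("fileAssociated", "false"), False),
            created_by=_text("createdBy", ""),
            created_at=_text("createdAt", ""),
        )
        groups = []
        for group_el in metadata_el:
            if group_el.tag != "group":
                raise SchemaParseError(f"unknown element 'metadata/{group_el.tag}'")
            members: list[Union[AttributeDef, LoopDef]] = []
            gname = group_el.get("name", "")
            for member_el in group_el:
                if member_el.tag == "attribute":
                    members.append(_parse_attr(member_el, f"group '{gname}'"))
                elif member_el.tag == "loop":
                    lname = member_el.get("name", "")
                    attrs = []
                    for attr_el in member_el:
                        if attr_el.tag != "attribute":
                            raise SchemaParseError(
                                f"unknown element 'loop/{attr_el.tag}' in loop {lname!r}"
                            )
                        attrs.append(_parse_attr(attr_el, f"loop '{lname}'"))
                    members.append(LoopDef(name=lname, attributes=tuple(attrs)))
                else:
                    raise SchemaParseError(
                        f"unknown element 'group/{member_el.tag}' in group {gname!r}"
                    )
            groups.append(MetadataGroup(name=gname, members=tuple(members)))
        return DataTypeSchema(header=header, groups=tuple(groups))
    except SchemaStructureError as exc:
        raise SchemaParseError(f"invalid schema content: {exc}") from exc


def _parse_attr(el: etree._Element, where: str) -> AttributeDef:
    name = el.get("name", "")
    kind = el.get("type", "text")
    required = _BOOL.get(el.get("required", "false"), False)
    unit = None
    allowed: list[str] = []
    ontology = None
    default_text = None
    for child in el:
        if child.tag == "unit":
            unit = child.text or ""
        elif child.tag == "allowedValue":
            allowed.append(child.text or "")
        elif child.tag == "ontology":
            ontology = OntologyTermRef(
                ontology_id=(child.findtext("source") or ""),
                term_id=(child.findtext("termId") or ""),
                label=(child.findtext("label") or ""),
            )
        elif child.tag == "default":
            default_text = child.text or ""
        else:
            raise SchemaParseError(
                f"unknown element 'attribute/{child.tag}' on {name!r} in {where}"
            )
    default = None
    if default_text is not None:
        try:
            default = parse_value(kind, default_text)
        except ValueError as exc:
            raise SchemaParseError(
                f"attribute {name!r} in {where}: bad default: {exc}"
            ) from exc
    return AttributeDef(
        name=name,
        value_kind=kind,
        required=required,
        allowed_values=tuple(allowed),
        unit=unit,
        ontology_ref=ontology,
        default=default,
    )


# ---------------------------------------------------------------------------
# evolution

# additive changes -----------------------------------------------------------


@dataclass(frozen=True)
class AddGroup:
    group: MetadataGroup


@dataclass(frozen=True)
class AddAttribute:
    group: str
    attribute: AttributeDef
    loop: Optional[str] = None


@dataclass(frozen=True)
class AddLoop:
    group: str
    loop: LoopDef


@dataclass(frozen=True)
class AddEnumValue:
    path: AttributePath
    value: str


@dataclass(frozen=True)
class RelaxRequired:
    path: AttributePath


# destructive changes (rejected once instances exist) ------------------------


@dataclass(frozen=True)
class RemovePath:
    path: AttributePath


@dataclass(frozen=True)
class ChangeKind:
    path: AttributePath
    value_kind: str


@dataclass(frozen=True)
class MakeRequired:
    path: AttributePath


SchemaChange = Union[
    AddGroup, AddAttribute, AddLoop, AddEnumValue, RelaxRequired,
    RemovePath, ChangeKind, MakeRequired,
]

_DESTRUCTIVE = (RemovePath, ChangeKind, MakeRequired)


def evolve_datatype(
    schema: DataTypeSchema,
    changes: Sequence[SchemaChange],
    has_instances: bool = False,
) -> DataTypeSchema:
    """Apply schema changes, returning a new schema one version higher.

    With *has_instances* true (the store holds data of this type) only
    additive changes are allowed, and added attributes must be optional or
    carry a default — the guarantee that makes "extend the model after
    inserting data, with no database rebuild" safe.  An empty change list
    returns the schema unchanged (version included).
    """
    if not changes:
        return schema
    groups = list(schema.groups)
    for change in changes:
        if isinstance(change, _DESTRUCTIVE) and has_instances:
            raise EvolutionError(
                f"destructive change {type(change).__name__} rejected: "
                "instances of this datatype exist"
            )
        groups = _apply_change(schema, groups, change)
    new_header = replace(schema.header, version=schema.header.version + 1)
    try:
        return DataTypeSchema(header=new_header, groups=tuple(groups))
    except SchemaStructureError as exc:
        raise EvolutionError(f"evolved schema is invalid: {exc}") from exc


def _require_safe_addition(attr: AttributeDef) -> None:
    if attr.required and attr.default is None:
        raise EvolutionError(
            f"cannot add required attribute {attr.name!r} without a default: "
            "existing instances would become invalid"
        )


def _apply_change(
    schema: DataTypeSchema,
    groups: list[MetadataGroup],
    change: SchemaChange,
) -> list[MetadataGroup]:
    def _group_index(name: str) -> int:
        lowered = name.lower()
        for i, g in enumerate(groups):
            if g.name.lower() == lowered:
                return i
        raise EvolutionError(f"unknown group {name!r}")

    if isinstance(change, AddGroup):
        for attr in (
            a for m in change.group.members
            for a in (m.attributes if isinstance(m, LoopDef) else (m,))
        ):
            _require_safe_addition(attr)
        return groups + [change.group]

    if isinstance(change, AddAttribute):
        _require_safe_addition(change.attribute)
        i = _group_index(change.group)
        group = groups[i]
        if change.loop is None:
            new_group = MetadataGroup(
                name=group.name, members=group.members + (change.attribute,)
            )
        else:
            member = group.member(change.loop)
            if not isinstance(member, LoopDef):
                raise EvolutionError(
                    f"unknown loop {change.loop!r} in group {change.group!r}"
                )
            new_loop = LoopDef(
                name=member.name, attributes=member.attributes + (change.attribute,)
            )
            new_group = MetadataGroup(
                name=group.name,
                members=tuple(
                    new_loop if m is member else m for m in group.members
                ),
            )
        return groups[:i] + [new_group] + groups[i + 1:]

    if isinstance(change, AddLoop):
        for attr in change.loop.attributes:
            _require_safe_addition(attr)
        i = _group_index(change.group)
        group = groups[i]
        new_group = MetadataGroup(name=group.name, members=group.members + (change.loop,))
        return groups[:i] + [new_group] + groups[i + 1:]

    if isinstance(change, (AddEnumValue, RelaxRequired, RemovePath, ChangeKind, MakeRequired)):
        return _rewrite_path(groups, change)

    raise EvolutionError(f"unknown change type {type(change).__name__}")


def _rewrite_path(groups: list[MetadataGroup], change) -> list[MetadataGroup]:
    path = change.path
    gname, lname, aname = path

    def rewrite_attr(attr: AttributeDef) -> Optional[AttributeDef]:
        if isinstance(change, AddEnumValue):
            if attr.value_kind != "enumeration":
                raise EvolutionError(
                    f"cannot add enumeration value on non-enumeration {path_str(path)}"
                )
            if change.value in attr.allowed_values:
                return attr
            return replace(attr, allowed_values=attr.allowed_values + (change.value,))
        if isinstance(change, RelaxRequired):
            return replace(attr, required=False)
        if isinstance(change, RemovePath):
            return None
        if isinstance(change, ChangeKind):
            return replace(
                attr, value_kind=change.value_kind, allowed_values=(), default=None
            )
        if isinstance(change, MakeRequired):
            return replace(attr, required=True)
        raise EvolutionError(f"unknown change type {type(change).__name__}")

    found = False
    new_groups: list[MetadataGroup] = []
    for group in groups:
        if group.name.lower() != gname.lower():
            new_groups.append(group)
            continue
        members: list[Union[AttributeDef, LoopDef]] = []
        for member in group.members:
            if lname is None and isinstance(member, AttributeDef) \
                    and member.name.lower() == aname.lower():
                found = True
                rewritten = rewrite_attr(member)
                if rewritten is not None:
                    members.append(rewritten)
            elif lname is not None and isinstance(member, LoopDef) \
                    and member.name.lower() == lname.lower():
                attrs: list[AttributeDef] = []
                for attr in member.attributes:
                    if attr.name.lower() == aname.lower():
                        found = True
                        rewritten = rewrite_attr(attr)
                        if rewritten is not None:
                            attrs.append(rewritten)
                    else:
                        attrs.append(attr)
                if attrs:
                    members.append(LoopDef(name=member.name, attributes=tuple(attrs)))
            else:
                members.append(member)
        if members:
            new_groups.append(MetadataGroup(name=group.name, members=tuple(members)))
    if not found:
        raise EvolutionError(f"unknown path {path_str(path)}")
    return new_groups


# ---------------------------------------------------------------------------
# ontology-backed attribute-name suggestion


class OntologyCatalog:
    """A loaded ontology term list used to suggest attribute names.

    Only the ``id:`` and ``name:`` lines of ``[Term]`` stanzas in an OBO
    file are consumed; everything else in the ontology is ignored.
    """

    def __init__(self, ontology_id: str, terms: Sequence[OntologyTermRef]):
        self.ontology_id = ontology_id
        self.terms = tuple(terms)

    @classmethod
    def from_obo(cls, path, ontology_id: Optional[str] = None) -> "OntologyCatalog":
        import obonet

        graph = obonet.read_obo(str(path))
        oid = ontology_id or graph.graph.get("ontology", "") or "unknown"
        terms = [
            OntologyTermRef(ontology_id=oid, term_id=term_id, label=data["name"])
            for term_id, data in graph.nodes(data=True)
            if data.get("name")
        ]
        return cls(oid, terms)


def suggest_terms(
    prefix: str,
    ontology: Optional[OntologyCatalog],
    limit: int = 20,
) -> list[OntologyTermRef]:
    """Terms whose label starts with *prefix* (case-insensitive).

    Results are ordered lexicographically by label and capped at *limit*.
    With no ontology loaded the suggestion list is simply empty.
    """
    if ontology is None or not prefix:
        return []
    lowered = prefix.lower()
    matches = [t for t in ontology.terms if t.label.lower().startswith(lowered)]
    matches.sort(key=lambda t: (t.label.lower(), t.term_id))
    return matches[:limit]


# ---------------------------------------------------------------------------
# entry-form rendering


def render_entry_form(schema: DataTypeSchema) -> str:
    """Render an HTML entry form for a data type.

    One input control per attribute; enumerations become ``<select>``
    lists; required attributes are marked; each loop renders as a
    repeatable row template (``fieldset class="loop"``) that a dynamic
    front end can clone per iteration.
    """
    form = etree.Element("form", attrib={"class": "datatype-entry",
                                         "data-datatype": schema.name,
                                         "data-version": str(schema.version)})
    title = etree.SubElement(form, "h2")
    title.text = schema.name
    for group in schema.groups:
        fs = etree.SubElement(form, "fieldset", attrib={"class": "group"})
        etree.SubElement(fs, "legend").text = group.name
        for member in group.members:
            if isinstance(member, AttributeDef):
                _control(fs, group.name, None, member)
            else:
                loop_fs = etree.SubElement(
                    fs, "fieldset",
                    attrib={"class": "loop", "data-loop": member.name},
                )
                etree.SubElement(loop_fs, "legend").text = member.name
                row = etree.SubElement(
                    loop_fs, "div", attrib={"class": "loop-row"}
                )
                for attr in member.attributes:
                    _control(row, group.name, member.name, attr)
    return etree.tostring(form, pretty_print=True, encoding="unicode")


_INPUT_TYPE = {
    "text": "text",
    "integer": "number",
    "decimal": "number",
    "date": "date",
}


def _control(parent: etree._Element, group: str, loop: Optional[str],
             attr: AttributeDef) -> None:
    field_name = path_str((group, loop, attr.name))
    label = etree.SubElement(parent, "label")
    label.text = attr.name
    if attr.unit:
        label.text += f" ({attr.unit})"
    if attr.required:
        etree.SubElement(label, "span", attrib={"class": "required"}).text = "*"
    if attr.value_kind == "enumeration":
        select = etree.SubElement(parent, "select", name=field_name)
        if attr.required:
            select.set("required", "required")
        for value in attr.allowed_values:
            option = etree.SubElement(select, "option", value=value)
            option.text = value
            if attr.default == value:
                option.set("selected", "selected")
    elif attr.value_kind == "boolean":
        control = etree.SubElement(
            parent, "input", type="checkbox", name=field_name
        )
        if attr.default is True:
            control.set("checked", "checked")
    else:
        control = etree.SubElement(
            parent, "input", type=_INPUT_TYPE[attr.value_kind], name=field_name
        )
        if attr.value_kind == "decimal":
            control.set("step", "any")
        if attr.required:
            control.set("required", "required")
        if attr.default is not None:
            control.set("value", encode_value(attr.value_kind, attr.default))
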