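"""Process-event provenance: a hierarchical taxonomy of what was done.

A *process* is a group of sequential events and/or sub-processes related
to one activity (a pre-surgical analysis, a baseline visit); an *event*
is an atomic operation — an acquisition, a processing step, a blood draw,
an administrative action — and always belongs to exactly one process.
Processes nest into a forest; children are ordered by insertion, which is
the sequence in which the steps were performed.

The structure maps onto the XCEDE experiment hierarchy: ``visit`` and
``study`` become parent/child processes, ``episode`` and ``acquisition``
collapse into events, while ``project`` and ``subject`` are context
around the tree rather than nodes in it.

Custom process and event types, and which child types a process type
admits, are registered at run time; an empty allowed-child-type list
means "any", mirroring free taxonomy building.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional, Sequence, Union

from lxml import etree

from .exceptions import IntegrityError, TaxonomyError


@dataclass(frozen=True)
class ProcessType:
    type_name: str
    description: str = ""
    allowed_child_types: tuple[str, ...] = ()  # empty = any


@dataclass(frozen=True)
class EventType:
    type_name: str
    description: str = ""


@dataclass
class Event:
    """An atomic leaf operation carrying data references."""

    event_id: str
    type_name: str
    process: "Process"
    occurred_at: str = ""
    data: tuple[str, ...] = ()  # DataInstance ids
    note: Optional[str] = None


@dataclass
class Process:
    """An ordered container of sub-processes and events."""

    process_id: str
    type_name: str
    label: str
    subject_id: Optional[str] = None
    parent: Optional["Process"] = None
    children: list[Union["Process", Event]] = field(default_factory=list)
    started_at: Optional[str] = None
    ended_at: Optional[str] = None

    def ancestors(self) -> Iterator["Process"]:
        node = self.parent
        while node is not None:
            yield node
            node = node.parent


#: XCEDE hierarchy levels and how they map onto this model
XCEDE_LEVELS = {
    "project": "context",
    "subject": "context",
    "visit": "process",
    "study": "process",
    "episode": "event",
    "acquisition": "event",
}


def xcede_level_kind(level: str) -> str:
    """Map an XCEDE hierarchy level onto this model's node kind.

    visit/study → process (father-son), episode/acquisition → event,
    project/subject → surrounding context.
    """
    try:
        return XCEDE_LEVELS[level.lower()]
    except KeyError:
        raise TaxonomyError(f"unknown XCEDE level {level!r}") from None


class Taxonomy:
    """A registry of process/event types plus the forest built from them.

    When *instance_resolver* is given (a callable returning True iff a
    data-instance id exists), event data references are checked at
    ``add_event`` time and dangling references rejected.
    """

    def __init__(self, instance_resolver: Optional[Callable[[str], bool]] = None):
        self.process_types: dict[str, ProcessType] = {}
        self.event_types: dict[str, EventType] = {}
        self.roots: list[Process] = []
        self._ids = itertools.count(1)
        # id allocation is pluggable so a persistent store can hand out
        # ids from its own sequence (fresh taxonomies over an existing
        # store must not reuse persisted ids)
        self._id_alloc: Callable[[str], str] = \
            lambda prefix: f"{prefix}{next(self._ids)}"
        self._instance_resolver = instance_resolver
        self._event_sink: Optional[Callable[[Event], None]] = None
        self._process_sink: Optional[Callable[[Process], None]] = None

    # -- type registry ------------------------------------------------------

    def register_process_type(
        self,
        type_name: str,
        description: str = "",
        allowed_child_types: Sequence[str] = (),
    ) -> ProcessType:
        if type_name.lower() in {n.lower() for n in self.process_types} \
                or type_name.lower() in {n.lower() for n in self.event_types}:
            raise TaxonomyError(f"type {type_name!r} already registered")
        pt = ProcessType(type_name, description, tuple(allowed_child_types))
        self.process_types[type_name] = pt
        return pt

    def register_event_type(self, type_name: str, description: str = "") -> EventType:
        if type_name.lower() in {n.lower() for n in self.process_types} \
                or type_name.lower() in {n.lower() for n in self.event_types}:
            raise TaxonomyError(f"type {type_name!r} already registered")
        et = EventType(type_name, description)
        self.event_types[type_name] = et
        return et

    def _process_type(self, name: str) -> ProcessType:
        for key, pt in self.process_types.items():
            if key.lower() == name.lower():
                return pt
        raise TaxonomyError(f"unknown process type {name!r}")

    def _event_type(self, name: str) -> EventType:
        for key, et in self.event_types.items():
            if key.lower() == name.lower():
                return et
        raise TaxonomyError(f"unknown event type {name!r}")

    # -- tree building ------------------------------------------------------

    def create_process(
        self,
        type_name: str,
        label: str,
        parent: Optional[Process] = None,
        subject_id: Optional[str] = None,
        started_at: Optional[str] = None,
    ) -> Process:
        """Append a new process under *parent* (or as a new root).

        Every call mints a fresh node, so the forest invariant (no node is
        its own ancestor) holds by construction.
        """
        ptype = self._process_type(type_name)
        if parent is not None:
            parent_type = self._process_type(parent.type_name)
            if parent_type.allowed_child_types and not any(
                t.lower() == ptype.type_name.lower()
                for t in parent_type.allowed_child_types
            ):
                raise TaxonomyError(
                    f"process type {ptype.type_name!r} not allowed under "
                    f"{parent_type.type_name!r}"
                )
        process = Process(
            process_id=self._id_alloc("P"),
            type_name=ptype.type_name,
            label=label,
            subject_id=subject_id,
            parent=parent,
            started_at=started_at,
        )
        if self._process_sink is not None:
            self._process_sink(process)
        if parent is None:
            self.roots.append(process)
        else:
            parent.children.append(process)
        return process

    def add_event(
        self,
        process: Process,
        type_name: str,
        occurred_at: str = "",
        data: Sequence[str] = (),
        note: Optional[str] = None,
    ) -> Event:
        """Append an atomic event to *process*, in sequence order."""
        etype = self._event_type(type_name)
        if self._instance_resolver is not None:
            for instance_id in data:
                if not self._instance_resolver(instance_id):
                    raise IntegrityError(
                        f"event data reference {instance_id!r} does not resolve"
                    )
        event = Event(
            event_id=self._id_alloc("E"),
            type_name=etype.type_name,
            process=process,
            occurred_at=occurred_at,
            data=tuple(data),
            note=note,
        )
        if self._event_sink is not None:
            # persistence first: a failed save must leave the tree untouched
            self._event_sink(event)
        process.children.append(event)
        return event

    # -- traversal ----------------------------------------------------------

    def timeline(self, process: Process) -> list[Event]:
        """All events in *process*'s subtree, depth-first in sequence order.

        Children order within each process governs; each event carries its
        own ``occurred_at`` timestamp for callers that want a chronological
        re-sort instead of the structural order.
        """
        events: list[Event] = []

        def walk(node: Process) -> None:
            for child in node.children:
                if isinstance(child, Event):
                    events.append(child)
                else:
                    walk(child)

        walk(process)
        return events

    # -- export -------------------------------------------------------------

    def to_xml(self, process: Process) -> bytes:
        """Serialize a process subtree to the XML dialect family."""

        def build(node: Process, parent_el: Optional[etree._Element]) -> etree._Element:
            el = etree.Element("process") if parent_el is None \
                else etree.SubElement(parent_el, "process")
            el.set("id", node.process_id)
            el.set("type", node.type_name)
            el.set("label", node.label)
            if node.subject_id:
                el.set("subject", node.subject_id)
            for child in node.children:
                if isinstance(child, Event):
                    ev = etree.SubElement(el, "event")
                    ev.set("id", child.event_id)
                    ev.set("type", child.type_name)
                    if child.occurred_at:
                        ev.set("occurredAt", child.occurred_at)
                    for ref in child.data:
                        etree.SubElement(ev, "dataRef", instance=ref)
                    if child.note:
                        etree.SubElement(ev, "note").text = child.note
                else:
                    build(child, el)
            return el

        root = build(process, None)
        return etree.tostring(
            root, xml_declaration=True, encoding="UTF-8", pretty_print=True
        )

    def to_outline(self, process: Process, indent: str = "  ") -> str:
        """Indented text outline of a process subtree (CLI display)."""
        lines: list[str] = []

        def walk(node: Union[Process, Event], depth: int) -> None:
            pad = indent * depth
            if isinstance(node, Event):
                when = f" @ {node.occurred_at}" if node.occurred_at else ""
                refs = f" [{', '.join(node.data)}]" if node.data else ""
                lines.append(f"{pad}* {node.type_name}{when}{refs}")
            else:
                lines.append(f"{pad}{node.label} ({node.type_name})")
                for child in node.children:
                    walk(child, depth + 1)

        walk(process, 0)
        return "\n".join(lines)
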