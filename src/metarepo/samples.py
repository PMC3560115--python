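"""Freezer inventory: biosample placement, movement and courier tracking.

Freezers hold racks; racks hold numbered slots; each slot holds one
sample box with a uniform x-y grid.  A sample (blood, DNA, RNA...) is
registered against a subject, placed at a coordinate, moved between
coordinates, and shipped — shipment clears the location (the sample is
in transit with a courier mailing number) until it is placed again at
the destination site's freezer.  Every action appends to the sample's
append-only history, so the location trail is reconstructible at any
time and always resolvable back to the subject's data.

Coordinates are 1-based in every axis (slot index, column x, row y);
``coordinate_label`` offers the A1-style display biologists write on
boxes.  At any moment the coordinate→sample mapping is injective:
placing onto an occupied coordinate is an error, enforced both in logic
and by a unique index in the store.
"""

from __future__ import annotations

import datetime
import string
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .exceptions import ConflictError, NotFoundError, OccupancyError
from .storage import Store

MATERIALS = ("blood", "DNA", "RNA", "other")
TEMPERATURE_CLASSES = ("-80C", "-45C")


@dataclass(frozen=True)
class FreezerLayout:
    freezer_id: str
    temperature_class: str  # -80C | -45C
    racks: tuple[tuple[str, int], ...]  # (rack_id, slot count)
    box_grid: tuple[int, int]  # (columns, rows), uniform per freezer

    def __post_init__(self):
        object.__setattr__(self, "racks", tuple(tuple(r) for r in self.racks))
        if self.temperature_class not in TEMPERATURE_CLASSES:
            raise ValueError(
                f"temperature class must be one of {TEMPERATURE_CLASSES}"
            )
        if not self.racks:
            raise ValueError("freezer needs >=1 rack")
        for rack_id, slots in self.racks:
            if slots < 1:
                raise ValueError(f"rack {rack_id!r} needs >=1 slot")
        cols, rows = self.box_grid
        if cols < 1 or rows < 1:
            raise ValueError("box grid must be at least 1x1")

    def capacity(self) -> int:
        """Total sample positions: sum of slots x columns x rows."""
        cols, rows = self.box_grid
        return sum(slots for _, slots in self.racks) * cols * rows


@dataclass(frozen=True)
class SlotCoordinate:
    """freezer / rack / slot / box-x / box-y, all 1-based."""

    freezer_id: str
    rack_id: str
    slot_index: int
    x: int
    y: int


def coordinate_label(coord: SlotCoordinate) -> str:
    """A1-style display: column letter + row number within the box."""
    col = ""
    x = coord.x
    while x > 0:
        x, rem = divmod(x - 1, 26)
        col = string.ascii_uppercase[rem] + col
    return (
        f"{coord.freezer_id}/{coord.rack_id}/slot{coord.slot_index}/"
        f"{col}{coord.y}"
    )


@dataclass(frozen=True)
class Sample:
    sample_id: str
    material: str
    subject_id: str
    location: Optional[SlotCoordinate] = None
    courier_number: Optional[str] = None
    history: tuple[tuple[str, str, Optional[SlotCoordinate]], ...] = ()


# ---------------------------------------------------------------------------
# freezer configuration


def configure_freezer(store: Store, layout: FreezerLayout) -> str:
    """Persist a freezer layout; reconfiguration never strands a sample.

    Re-running with the same freezer id replaces the layout, but only if
    every currently located sample still fits inside the new bounds.
    """
    with store.transaction():
        exists = store._conn.execute(
            "SELECT 1 FROM freezer WHERE freezer_id = ?", (layout.freezer_id,)
        ).fetchone()
        if exists:
            for sample_id, rack_id, slot_index, x, y in store._conn.execute(
                "SELECT sample_id, rack_id, slot_index, x, y FROM sample "
                "WHERE freezer_id = ?",
                (layout.freezer_id,),
            ).fetchall():
                coord = SlotCoordinate(layout.freezer_id, rack_id,
                                       slot_index, x, y)
                if not _in_bounds(layout, coord):
                    raise OccupancyError(
                        f"reconfiguration rejected: sample {sample_id!r} "
                        f"at {coordinate_label(coord)} would fall out of bounds"
                    )
            store._conn.execute(
                "DELETE FROM rack WHERE freezer_id = ?", (layout.freezer_id,)
            )
            store._conn.execute(
                "UPDATE freezer SET temperature_class = ?, box_cols = ?, "
                "box_rows = ? WHERE freezer_id = ?",
                (layout.temperature_class, layout.box_grid[0],
                 layout.box_grid[1], layout.freezer_id),
            )
        else:
            store._conn.execute(
                "INSERT INTO freezer (freezer_id, temperature_class, "
                "box_cols, box_rows) VALUES (?, ?, ?, ?)",
                (layout.freezer_id, layout.temperature_class,
                 layout.box_grid[0], layout.box_grid[1]),
            )
        for rack_id, slots in layout.racks:
            store._conn.execute(
                "INSERT INTO rack (freezer_id, rack_id, slots) VALUES (?, ?, ?)",
                (layout.freezer_id, rack_id, slots),
            )
    store.log("configure_freezer", layout.freezer_id)
    return layout.freezer_id


def load_freezer(store: Store, freezer_id: str) -> FreezerLayout:
    row = store._conn.execute(
        "SELECT temperature_class, box_cols, box_rows FROM freezer "
        "WHERE freezer_id = ?",
        (freezer_id,),
    ).fetchone()
    if row is None:
        raise NotFoundError(f"unknown freezer {freezer_id!r}")
    racks = tuple(
        (rack_id, slots)
        for rack_id, slots in store._conn.execute(
            "SELECT rack_id, slots FROM rack WHERE freezer_id = ? "
            "ORDER BY rack_id",
            (freezer_id,),
        )
    )
    return FreezerLayout(
        freezer_id=freezer_id,
        temperature_class=row[0],
        racks=racks,
        box_grid=(row[1], row[2]),
    )


def _in_bounds(layout: FreezerLayout, coord: SlotCoordinate) -> bool:
    cols, rows = layout.box_grid
    for rack_id, slots in layout.racks:
        if rack_id == coord.rack_id:
            return (
                1 <= coord.slot_index <= slots
                and 1 <= coord.x <= cols
                and 1 <= coord.y <= rows
            )
    return False


# ---------------------------------------------------------------------------
# sample lifecycle


def register_sample(
    store: Store,
    sample_id: str,
    material: str,
    subject_id: str,
    timestamp: Optional[str] = None,
) -> Sample:
    """Register a new, unplaced sample for a subject."""
    if material not in MATERIALS:
        raise ValueError(f"material must be one of {MATERIALS}")
    if not store.has_subject(subject_id):
        raise NotFoundError(f"unknown subject {subject_id!r}")
    with store.transaction():
        if store._conn.execute(
            "SELECT 1 FROM sample WHERE sample_id = ?", (sample_id,)
        ).fetchone():
            raise ConflictError(f"sample {sample_id!r} already registered")
        store._conn.execute(
            "INSERT INTO sample (sample_id, material, subject_id) "
            "VALUES (?, ?, ?)",
            (sample_id, material, subject_id),
        )
        _append_history(store, sample_id, "registered", None, timestamp)
    store.log("register_sample", f"{sample_id} ({material}, {subject_id})")
    return locate_sample(store, sample_id)


def place_sample(
    store: Store,
    sample_id: str,
    coordinate: SlotCoordinate,
    timestamp: Optional[str] = None,
) -> Sample:
    """Put an unplaced (or newly arrived) sample at a free coordinate."""
    return _relocate(store, sample_id, coordinate, "placed", timestamp)


def move_sample(
    store: Store,
    sample_id: str,
    coordinate: SlotCoordinate,
    timestamp: Optional[str] = None,
) -> Sample:
    """Move a located sample to a new free coordinate (old one is freed)."""
    return _relocate(store, sample_id, coordinate, "moved", timestamp)


def _relocate(
    store: Store,
    sample_id: str,
    coordinate: SlotCoordinate,
    action: str,
    timestamp: Optional[str],
) -> Sample:
    _require_sample(store, sample_id)
    layout = load_freezer(store, coordinate.freezer_id)
    if not _in_bounds(layout, coordinate):
        raise OccupancyError(
            f"coordinate {coordinate_label(coordinate)} outside the "
            f"configured layout of freezer {coordinate.freezer_id!r}"
        )
    with store.transaction():
        occupant = store._conn.execute(
            "SELECT sample_id FROM sample WHERE freezer_id = ? AND "
            "rack_id = ? AND slot_index = ? AND x = ? AND y = ?",
            (coordinate.freezer_id, coordinate.rack_id,
             coordinate.slot_index, coordinate.x, coordinate.y),
        ).fetchone()
        if occupant is not None and occupant[0] != sample_id:
            raise OccupancyError(
                f"coordinate {coordinate_label(coordinate)} already holds "
                f"sample {occupant[0]!r}"
            )
        store._conn.execute(
            "UPDATE sample SET freezer_id = ?, rack_id = ?, slot_index = ?, "
            "x = ?, y = ? WHERE sample_id = ?",
            (coordinate.freezer_id, coordinate.rack_id,
             coordinate.slot_index, coordinate.x, coordinate.y, sample_id),
        )
        _append_history(store, sample_id, action, coordinate, timestamp)
    store.log(action, f"{sample_id} -> {coordinate_label(coordinate)}")
    return locate_sample(store, sample_id)


def register_shipment(
    store: Store,
    sample_id: str,
    courier_number: str,
    timestamp: Optional[str] = None,
) -> Sample:
    """Ship a sample: the slot is freed, the courier number retained.

    The sample is "in transit" (located nowhere) until placed again at
    the destination freezer.
    """
    _require_sample(store, sample_id)
    with store.transaction():
        store._conn.execute(
            "UPDATE sample SET freezer_id = NULL, rack_id = NULL, "
            "slot_index = NULL, x = NULL, y = NULL, courier_number = ? "
            "WHERE sample_id = ?",
            (courier_number, sample_id),
        )
        _append_history(store, sample_id, "shipped", None, timestamp)
    store.log("register_shipment", f"{sample_id} via {courier_number}")
    return locate_sample(store, sample_id)


def locate_sample(store: Store, sample_id: str) -> Sample:
    """Current coordinate (or in-transit/unplaced) plus the full history."""
    row = store._conn.execute(
        "SELECT material, subject_id, freezer_id, rack_id, slot_index, x, y, "
        "courier_number FROM sample WHERE sample_id = ?",
        (sample_id,),
    ).fetchone()
    if row is None:
        raise NotFoundError(f"unknown sample {sample_id!r}")
    material, subject_id, freezer_id, rack_id, slot_index, x, y, courier = row
    location = (
        SlotCoordinate(freezer_id, rack_id, slot_index, x, y)
        if freezer_id is not None
        else None
    )
    history = tuple(
        (
            timestamp,
            action,
            SlotCoordinate(h_freezer, h_rack, h_slot, h_x, h_y)
            if h_freezer is not None
            else None,
        )
        for timestamp, action, h_freezer, h_rack, h_slot, h_x, h_y
        in store._conn.execute(
            "SELECT timestamp, action, freezer_id, rack_id, slot_index, x, y "
            "FROM sample_history WHERE sample_id = ? ORDER BY seq",
            (sample_id,),
        )
    )
    return Sample(
        sample_id=sample_id,
        material=material,
        subject_id=subject_id,
        location=location,
        courier_number=courier,
        history=history,
    )


def list_samples(store: Store, subject_id: Optional[str] = None) -> list[str]:
    if subject_id is None:
        rows = store._conn.execute(
            "SELECT sample_id FROM sample ORDER BY sample_id"
        )
    else:
        rows = store._conn.execute(
            "SELECT sample_id FROM sample WHERE subject_id = ? "
            "ORDER BY sample_id",
            (subject_id,),
        )
    return [r[0] for r in rows]


def _require_sample(store: Store, sample_id: str) -> None:
    if store._conn.execute(
        "SELECT 1 FROM sample WHERE sample_id = ?", (sample_id,)
    ).fetchone() is None:
        raise NotFoundError(f"unknown sample {sample_id!r}")


def _append_history(
    store: Store,
    sample_id: str,
    action: str,
    coordinate: Optional[SlotCoordinate],
    timestamp: Optional[str],
) -> None:
    seq = store._conn.execute(
        "SELECT COALESCE(MAX(seq), 0) + 1 FROM sample_history "
        "WHERE sample_id = ?",
        (sample_id,),
    ).fetchone()[0]
    store._conn.execute(
        "INSERT INTO sample_history (sample_id, seq, timestamp, action, "
        "freezer_id, rack_id, slot_index, x, y) "
        "VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?)",
        (
            sample_id,
            seq,
            timestamp or _now(),
            action,
            coordinate.freezer_id if coordinate else None,
            coordinate.rack_id if coordinate else None,
            coordinate.slot_index if coordinate else None,
            coordinate.x if coordinate else None,
            coordinate.y if coordinate else None,
        ),
    )


def _now() -> str:
    return datetime.datetime.now().isoformat()
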