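"""Freezer layout capacity, occupancy invariants, movement history."""

import random

import pytest

from metarepo import samples
from metarepo.exceptions import ConflictError, NotFoundError, OccupancyError
from metarepo.records import Subject
from metarepo.samples import (
    FreezerLayout,
    SlotCoordinate,
    configure_freezer,
    coordinate_label,
    list_samples,
    locate_sample,
    move_sample,
    place_sample,
    register_sample,
    register_shipment,
)


@pytest.fixture()
def freezer_store(store):
    store.save_subject(Subject("S001", "female", "1945-03-03", "AD"))
    store.save_subject(Subject("S002", "male", "1950-07-07", "Control"))
    configure_freezer(
        store, FreezerLayout("GENOA-80", "-80C", (("R1", 2),), (9, 9))
    )
    return store


def _coord(slot=1, x=1, y=1, freezer="GENOA-80", rack="R1"):
    return SlotCoordinate(freezer, rack, slot, x, y)


class TestLayout:
    def test_capacity_matches_enumeration(self):
        layout = FreezerLayout("F", "-80C", (("R1", 2),), (9, 9))
        enumerated = sum(
            1
            for _rack, slots in layout.racks
            for _slot in range(slots)
            for _x in range(layout.box_grid[0])
            for _y in range(layout.box_grid[1])
        )
        assert layout.capacity() == enumerated == 162

    def test_zero_slot_rack_rejected(self):
        with pytest.raises(ValueError, match="slot"):
            FreezerLayout("F", "-80C", (("R1", 0),), (9, 9))

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            FreezerLayout("F", "-45C", (("R1", 1),), (0, 5))

    def test_shrinking_reconfiguration_cannot_strand_samples(
        self, freezer_store
    ):
        register_sample(freezer_store, "B1", "blood", "S001")
        place_sample(freezer_store, "B1", _coord(slot=2, x=9, y=9))
        with pytest.raises(OccupancyError, match="out of bounds"):
            configure_freezer(
                freezer_store,
                FreezerLayout("GENOA-80", "-80C", (("R1", 1),), (9, 9)),
            )
        # compatible reconfiguration is fine
        configure_freezer(
            freezer_store,
            FreezerLayout("GENOA-80", "-80C", (("R1", 3),), (9, 9)),
        )


class TestPlacement:
    def test_place_then_locate(self, freezer_store):
        register_sample(freezer_store, "B1", "blood", "S001")
        place_sample(freezer_store, "B1", _coord())
        assert locate_sample(freezer_store, "B1").location == _coord()

    def test_occupied_coordinate_rejected(self, freezer_store):
        register_sample(freezer_store, "B1", "blood", "S001")
        register_sample(freezer_store, "B2", "DNA", "S002")
        place_sample(freezer_store, "B1", _coord())
        with pytest.raises(OccupancyError, match="already holds"):
            place_sample(freezer_store, "B2", _coord())

    def test_out_of_bounds_coordinate_rejected(self, freezer_store):
        register_sample(freezer_store, "B1", "blood", "S001")
        with pytest.raises(OccupancyError):
            place_sample(freezer_store, "B1", _coord(x=10))

    def test_move_frees_previous_coordinate(self, freezer_store):
        register_sample(freezer_store, "B1", "blood", "S001")
        register_sample(freezer_store, "B2", "RNA", "S002")
        place_sample(freezer_store, "B1", _coord())
        move_sample(freezer_store, "B1", _coord(x=2))
        place_sample(freezer_store, "B2", _coord())  # old slot reusable

    def test_history_grows_in_timestamp_order(self, freezer_store):
        register_sample(freezer_store, "B1", "blood", "S001",
                        timestamp="2012-02-01T08:00:00")
        place_sample(freezer_store, "B1", _coord(),
                     timestamp="2012-02-01T09:00:00")
        move_sample(freezer_store, "B1", _coord(x=2),
                    timestamp="2012-02-01T10:00:00")
        move_sample(freezer_store, "B1", _coord(x=3),
                    timestamp="2012-02-01T11:00:00")
        history = locate_sample(freezer_store, "B1").history
        assert [h[1] for h in history] == \
            ["registered", "placed", "moved", "moved"]
        stamps = [h[0] for h in history]
        assert stamps == sorted(stamps)

    def test_duplicate_registration_conflicts(self, freezer_store):
        register_sample(freezer_store, "B1", "blood", "S001")
        with pytest.raises(ConflictError):
            register_sample(freezer_store, "B1", "blood", "S001")


class TestShipment:
    def test_shipping_frees_slot_and_keeps_courier_number(self, freezer_store):
        register_sample(freezer_store, "B1", "blood", "S001")
        place_sample(freezer_store, "B1", _coord())
        register_shipment(freezer_store, "B1", "CN123456789")
        sample = locate_sample(freezer_store, "B1")
        assert sample.location is None
        assert sample.courier_number == "CN123456789"
        register_sample(freezer_store, "B2", "blood", "S002")
        place_sample(freezer_store, "B2", _coord())  # slot was freed

    def test_ship_then_place_at_destination(self, freezer_store):
        configure_freezer(
            freezer_store,
            FreezerLayout("LUBBOCK-80", "-80C", (("R1", 1),), (9, 9)),
        )
        register_sample(freezer_store, "B1", "blood", "S001")
        place_sample(freezer_store, "B1", _coord())
        register_shipment(freezer_store, "B1", "CN42")
        place_sample(freezer_store, "B1", _coord(freezer="LUBBOCK-80"))
        actions = [h[1] for h in locate_sample(freezer_store, "B1").history]
        assert actions == ["registered", "placed", "shipped", "placed"]

    def test_ship_unknown_sample_not_found(self, freezer_store):
        with pytest.raises(NotFoundError):
            register_shipment(freezer_store, "B404", "CN1")


class TestInvariants:
    def test_random_operations_preserve_occupancy_and_history(
        self, freezer_store
    ):
        rng = random.Random(2012)
        layout = samples.load_freezer(freezer_store, "GENOA-80")
        coords = [
            SlotCoordinate("GENOA-80", "R1", slot, x, y)
            for slot in (1, 2)
            for x in range(1, 10)
            for y in range(1, 10)
        ]
        ids = [f"B{i}" for i in range(30)]
        for i, sample_id in enumerate(ids):
            register_sample(freezer_store, sample_id, "blood",
                            rng.choice(("S001", "S002")),
                            timestamp=f"2012-02-01T00:{i:02d}:00")
        history_lengths = {i: 1 for i in ids}
        t = 0
        for _ in range(300):
            t += 1
            timestamp = f"2012-02-02T{t // 60:02d}:{t % 60:02d}:00"
            sample_id = rng.choice(ids)
            action = rng.choice(("place", "move", "ship"))
            coord = rng.choice(coords)
            try:
                if action == "ship":
                    register_shipment(freezer_store, sample_id, f"CN{t}",
                                      timestamp=timestamp)
                elif action == "move":
                    move_sample(freezer_store, sample_id, coord,
                                timestamp=timestamp)
                else:
                    place_sample(freezer_store, sample_id, coord,
                                 timestamp=timestamp)
                history_lengths[sample_id] += 1
            except OccupancyError:
                continue
            occupied = [
                locate_sample(freezer_store, i).location for i in ids
            ]
            occupied = [c for c in occupied if c is not None]
            assert len(occupied) == len(set(occupied)), "occupancy violated"
        for sample_id in ids:
            sample = locate_sample(freezer_store, sample_id)
            assert len(sample.history) == history_lengths[sample_id]
            stamps = [h[0] for h in sample.history]
            assert stamps == sorted(stamps)
        located = sum(
            1 for i in ids if locate_sample(freezer_store, i).location
        )
        in_transit = sum(
            1 for i in ids
            if locate_sample(freezer_store, i).location is None
            and locate_sample(freezer_store, i).courier_number
        )
        unplaced = len(ids) - located - in_transit
        assert located + in_transit + unplaced == len(ids)
        assert set(list_samples(freezer_store)) == set(ids)


def test_coordinate_label_is_a1_style():
    assert coordinate_label(SlotCoordinate("F", "R1", 2, 1, 5)) == \
        "F/R1/slot2/A5"
    assert coordinate_label(SlotCoordinate("F", "R1", 1, 27, 1)) == \
        "F/R1/slot1/AA1"
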