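"""Independent brute-force oracles used to check the engine's answers.

Everything here deliberately avoids the code paths under test: the query
oracle filters plain Python objects in memory (never SQL), the
flattening count oracle enumerates values by hand, the traversal oracle
re-walks trees naively.
"""

from __future__ import annotations

from metarepo.query import QuerySpec
from metarepo.records import DataInstance, Subject
from metarepo.storage import Store


def snapshot(store: Store):
    """Load every subject and instance into memory once."""
    subjects = store.list_subjects()
    instances: dict[str, list[DataInstance]] = {s.subject_id: [] for s in subjects}
    for instance_id in store.list_instances():
        instance = store.load_instance(instance_id)
        if instance.subject_id in instances:
            instances[instance.subject_id].append(instance)
    return subjects, instances


def brute_force_query(snap, spec: QuerySpec) -> list[str]:
    """In-memory filter with the documented query semantics."""
    subjects, instances = snap
    result = []
    for subject in subjects:
        if all(_subject_ok(subject, c) for c in spec.subject_conditions) and all(
            _data_ok(instances[subject.subject_id], c)
            for c in spec.data_conditions
        ):
            result.append(subject.subject_id)
    return sorted(result)


def _subject_ok(subject: Subject, cond) -> bool:
    value = getattr(subject, cond.field)
    if cond.field == "birth_date":
        if value is None:
            return False
        ops = {
            "eq": value == cond.value, "ne": value != cond.value,
            "lt": value < cond.value, "le": value <= cond.value,
            "gt": value > cond.value, "ge": value >= cond.value,
        }
        return ops[cond.operator]
    lowered, target = (value or "").lower(), cond.value.lower()
    if cond.operator == "eq":
        return lowered == target
    if cond.operator == "ne":
        return lowered != target
    return target in lowered  # contains


def _data_ok(subject_instances: list[DataInstance], cond) -> bool:
    matching_type = [
        i for i in subject_instances
        if i.datatype_name.lower() == cond.datatype_name.lower()
    ]
    if cond.mode == "exists":
        return bool(matching_type)
    return any(_instance_matches(i, cond) for i in matching_type)


def _instance_matches(instance: DataInstance, cond) -> bool:
    group, loop, attribute = cond.path
    candidates = []
    if loop is None:
        for av in instance.values:
            if av.path[0].lower() == group.lower() \
                    and av.path[2].lower() == attribute.lower():
                candidates.append(av.value)
    else:
        for loop_inst in instance.loops:
            if loop_inst.path[0].lower() != group.lower() \
                    or loop_inst.path[1].lower() != loop.lower():
                continue
            for iteration in loop_inst.iterations:
                for av in iteration:
                    if av.path[2].lower() == attribute.lower():
                        candidates.append(av.value)
    return any(_value_matches(v, cond.operator, cond.value) for v in candidates)


def _value_matches(value, operator, target) -> bool:
    import datetime
    from decimal import Decimal

    if operator == "in":
        return any(_value_matches(value, "eq", t) for t in target)
    if isinstance(value, str):
        lowered = value.lower()
        t = target.lower() if isinstance(target, str) else target
        if operator == "eq":
            return lowered == t
        if operator == "ne":
            return lowered != t
        if operator == "contains":
            return isinstance(t, str) and t in lowered
        return False
    if isinstance(value, bool):
        return (value == target) if operator == "eq" else (value != target)
    if isinstance(value, (int, Decimal)):
        # mirror the engine's numeric comparison at float precision
        left, right = float(value), float(target)
        return {
            "eq": left == right, "ne": left != right, "lt": left < right,
            "le": left <= right, "gt": left > right, "ge": left >= right,
        }[operator]
    if isinstance(value, datetime.date):
        left, right = value.isoformat(), (
            target.isoformat() if isinstance(target, datetime.date) else target
        )
        return {
            "eq": left == right, "ne": left != right, "lt": left < right,
            "le": left <= right, "gt": left > right, "ge": left >= right,
        }[operator]
    raise AssertionError(f"unexpected value type {type(value)}")


def count_supplied_values(instance: DataInstance) -> int:
    """Flattening oracle: plain values plus all non-empty loop iteration values."""
    n = len(instance.values)
    for loop_inst in instance.loops:
        for iteration in loop_inst.iterations:
            n += len(iteration)
    return n


def all_events_flat(process) -> list:
    """Traversal oracle: naive recursive event collection."""
    from metarepo.process_event import Event

    out = []
    for child in process.children:
        if isinstance(child, Event):
            out.append(child)
        else:
            out.extend(all_events_flat(child))
    return out
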