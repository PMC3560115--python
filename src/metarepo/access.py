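"""Groups, permissions and field-level masking of personal data.

Users belong to groups; groups hold permissions on resources.  A
resource is one of:

* ``datatype:<name>`` — a runtime-defined data type;
* ``function:<name>`` — a registered engine function (query, insert...);
* ``subject_personal_data`` — the subject's personal fields.

Checks are default-deny: a user may perform an action iff some group of
theirs holds the permission.  Authentication is out of scope — the engine
trusts the caller-supplied user identity.

Subjects are already anonymous (opaque ids, no name field), but birth
date is still personal: users without ``subject_personal_data`` view
permission receive a *masked view* in which the configured personal
fields are replaced by a marker that survives every serialization —
e.g. geneticists see a subject's diagnosis but never the birth date.

Every mutating call appends one line to the store's operation log.
"""

from __future__ import annotations

import json
from dataclasses import replace
from typing import Iterable, Optional

from .exceptions import AccessError
from .records import Subject
from .storage import Store

ACTIONS = ("view", "insert", "modify")
MASKED = "***masked***"

#: subject fields treated as personal data; sex and diagnosis are clinical
DEFAULT_PERSONAL_FIELDS = frozenset({"birth_date"})

#: engine functions registrable as permission resources
DEFAULT_FUNCTIONS = (
    "query", "insert_data", "define_datatype", "sample_manager",
    "imaging_upload",
)


def create_group(store: Store, group_name: str, description: str = "") -> None:
    with store.transaction():
        store._conn.execute(
            "INSERT INTO ugroup (group_name, description) VALUES (?, ?) "
            "ON CONFLICT(group_name) DO NOTHING",
            (group_name, description),
        )
    store.log("create_group", group_name)


def add_user(store: Store, user_id: str, group_name: str) -> None:
    _require_group(store, group_name)
    with store.transaction():
        store._conn.execute(
            "INSERT INTO group_member (group_name, user_id) VALUES (?, ?) "
            "ON CONFLICT DO NOTHING",
            (group_name, user_id),
        )
    store.log("add_user", f"{user_id} -> {group_name}")


def user_groups(store: Store, user_id: str) -> list[str]:
    return [
        r[0]
        for r in store._conn.execute(
            "SELECT group_name FROM group_member WHERE user_id = ? "
            "ORDER BY group_name",
            (user_id,),
        )
    ]


def register_function(store: Store, name: str) -> None:
    with store.transaction():
        store._conn.execute(
            "INSERT INTO function (name) VALUES (?) ON CONFLICT DO NOTHING",
            (name,),
        )


def _require_group(store: Store, group_name: str) -> None:
    if store._conn.execute(
        "SELECT 1 FROM ugroup WHERE group_name = ?", (group_name,)
    ).fetchone() is None:
        raise AccessError(f"unknown group {group_name!r}")


def _require_resource(store: Store, resource: str) -> None:
    if resource == "subject_personal_data":
        return
    kind, _, name = resource.partition(":")
    if kind == "datatype" and name:
        if not store.has_datatype(name):
            raise AccessError(f"unknown datatype in resource {resource!r}")
        return
    if kind == "function" and name:
        known = {r[0] for r in store._conn.execute("SELECT name FROM function")}
        known.update(DEFAULT_FUNCTIONS)
        if name not in known:
            raise AccessError(f"unknown function in resource {resource!r}")
        return
    raise AccessError(f"malformed resource {resource!r}")


def grant(store: Store, group_name: str, resource: str, action: str) -> None:
    """Record a permission (idempotent)."""
    if action not in ACTIONS:
        raise AccessError(f"unknown action {action!r}")
    _require_group(store, group_name)
    _require_resource(store, resource)
    with store.transaction():
        store._conn.execute(
            "INSERT INTO permission (group_name, resource, action) "
            "VALUES (?, ?, ?) ON CONFLICT DO NOTHING",
            (group_name, resource, action),
        )
    store.log("grant", f"{group_name}: {action} on {resource}")


def revoke(store: Store, group_name: str, resource: str, action: str) -> None:
    _require_group(store, group_name)
    with store.transaction():
        store._conn.execute(
            "DELETE FROM permission WHERE group_name = ? AND resource = ? "
            "AND action = ?",
            (group_name, resource, action),
        )
    store.log("revoke", f"{group_name}: {action} on {resource}")


def check_access(store: Store, user_id: str, resource: str, action: str) -> bool:
    """True iff some group of the user holds the permission. Default deny."""
    row = store._conn.execute(
        "SELECT 1 FROM permission p JOIN group_member m "
        "ON m.group_name = p.group_name "
        "WHERE m.user_id = ? AND p.resource = ? AND p.action = ? LIMIT 1",
        (user_id, resource, action),
    ).fetchone()
    return row is not None


def masked_view(
    store: Store,
    user_id: str,
    subject: Subject,
    personal_fields: Iterable[str] = DEFAULT_PERSONAL_FIELDS,
) -> Subject:
    """The subject as *user_id* is allowed to see it.

    Without ``subject_personal_data`` view permission, each configured
    personal field is replaced by the :data:`MASKED` marker.  The
    anonymous subject id is always visible.
    """
    if check_access(store, user_id, "subject_personal_data", "view"):
        return subject
    masked = subject
    for field_name in personal_fields:
        if getattr(masked, field_name, None) is not None:
            masked = replace(masked, **{field_name: MASKED})
    return masked


# ---------------------------------------------------------------------------
# ACL export / import


def export_acl(store: Store) -> dict:
    return {
        "groups": [
            {"group_name": name, "description": description}
            for name, description in store._conn.execute(
                "SELECT group_name, description FROM ugroup ORDER BY group_name"
            )
        ],
        "members": [
            {"group_name": g, "user_id": u}
            for g, u in store._conn.execute(
                "SELECT group_name, user_id FROM group_member "
                "ORDER BY group_name, user_id"
            )
        ],
        "permissions": [
            {"group_name": g, "resource": r, "action": a}
            for g, r, a in store._conn.execute(
                "SELECT group_name, resource, action FROM permission "
                "ORDER BY group_name, resource, action"
            )
        ],
    }


def import_acl(store: Store, document: dict) -> None:
    with store.transaction():
        for group in document.get("groups", ()):
            create_group(store, group["group_name"],
                         group.get("description", ""))
        for member in document.get("members", ()):
            add_user(store, member["user_id"], member["group_name"])
        for perm in document.get("permissions", ()):
            grant(store, perm["group_name"], perm["resource"], perm["action"])


def export_acl_json(store: Store) -> str:
    return json.dumps(export_acl(store), indent=2, sort_keys=True)
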