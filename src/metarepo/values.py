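"""Typed attribute values and their canonical text encoding.

Every attribute in a runtime-defined data type carries one of six value
kinds.  The same kinds drive instance validation, the XML dialects and the
flattened entity-attribute-value (EAV) rows, so the text encoding must be
canonical and injective per kind: encoding a value and parsing it back
always recovers an equal value, and two different values never share an
encoding.  That injectivity is what makes the XML-blob and EAV-row
representations of an instance checkable against each other.

Encodings: integers base-10; decimals with exact decimal semantics,
normalised with no trailing zeros and no exponent; dates ISO-8601 calendar
dates; booleans ``true``/``false``; text and enumeration labels verbatim.
"""

from __future__ import annotations

import datetime
from decimal import Decimal, InvalidOperation
from typing import Any

VALUE_KINDS = ("text", "integer", "decimal", "date", "boolean", "enumeration")

#: kinds whose values have a meaningful total order usable in range queries
ORDERED_KINDS = frozenset({"integer", "decimal", "date"})


def is_valid_kind(kind: str) -> bool:
    return kind in VALUE_KINDS


def check_value(kind: str, value: Any) -> bool:
    """Return True iff *value* is an acceptable in-memory value for *kind*."""
    if kind == "text" or kind == "enumeration":
        return isinstance(value, str)
    if kind == "integer":
        return isinstance(value, int) and not isinstance(value, bool)
    if kind == "decimal":
        return isinstance(value, Decimal) and value.is_finite()
    if kind == "date":
        return isinstance(value, datetime.date) and not isinstance(
            value, datetime.datetime
        )
    if kind == "boolean":
        return isinstance(value, bool)
    raise ValueError(f"unknown value kind: {kind!r}")


def encode_value(kind: str, value: Any) -> str:
    """Canonical text encoding of *value* under *kind* (injective per kind)."""
    if not check_value(kind, value):
        raise ValueError(f"value {value!r} does not satisfy kind {kind!r}")
    if kind in ("text", "enumeration"):
        return value
    if kind == "integer":
        return str(value)
    if kind == "decimal":
        return _decimal_text(value)
    if kind == "date":
        return value.isoformat()
    if kind == "boolean":
        return "true" if value else "false"
    raise ValueError(f"unknown value kind: {kind!r}")


def parse_value(kind: str, text: str) -> Any:
    """Parse a text encoding back into a typed value.

    Raises ValueError when the text is not a valid encoding for *kind*.
    """
    if not isinstance(text, str):
        raise ValueError(f"expected text, got {type(text).__name__}")
    if kind in ("text", "enumeration"):
        return text
    if kind == "integer":
        stripped = text.strip()
        try:
            return int(stripped, 10)
        except ValueError:
            raise ValueError(f"{text!r} is not an integer") from None
    if kind == "decimal":
        try:
            value = Decimal(text.strip())
        except InvalidOperation:
            raise ValueError(f"{text!r} is not a decimal number") from None
        if not value.is_finite():
            raise ValueError(f"{text!r} is not a finite decimal")
        return value
    if kind == "date":
        try:
            return datetime.date.fromisoformat(text.strip())
        except ValueError:
            raise ValueError(f"{text!r} is not an ISO-8601 date") from None
    if kind == "boolean":
        lowered = text.strip().lower()
        if lowered == "true":
            return True
        if lowered == "false":
            return False
        raise ValueError(f"{text!r} is not a boolean (true/false)")
    raise ValueError(f"unknown value kind: {kind!r}")


def numeric_value(kind: str, value: Any) -> float | None:
    """A float projection for range queries, or None for unordered kinds.

    Decimal values compare exactly during validation; the float projection
    is only used for SQL range predicates, where round-off at float
    precision is acceptable for the magnitudes clinical metadata carries.
    """
    if kind == "integer":
        return float(value)
    if kind == "decimal":
        return float(value)
    return None


def values_equal(kind: str, a: Any, b: Any) -> bool:
    """Kind-aware equality: decimals by numeric value, text case-sensitively."""
    if kind == "decimal":
        return a == b  # Decimal equality is numeric, 1.10 == 1.1
    return a == b


def _decimal_text(value: Decimal) -> str:
    # plain notation, trailing zeros stripped; Decimal.normalize alone would
    # switch to exponent notation for e.g. 120 -> 1.2E+2
    s = format(value, "f")
    if "." in s:
        s = s.rstrip("0").rstrip(".")
    if s in ("-0", ""):
        s = "0"
    return s
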