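"""Runtime values and the string-with-coercion semantics of the logic language.

Every value in the language is text.  When a value takes part in a
comparison or in arithmetic, a *read-only numeric view* is attempted: if
the text parses as a decimal number it is compared/combined numerically,
otherwise textually.  Booleans stay as the strings ``"true"``/``"false"``.
The stored raw text is never rewritten by evaluation.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from decimal import Decimal, InvalidOperation
from typing import Optional


@dataclass(frozen=True)
class Value:
    raw: str
    is_null: bool = False

    def as_number(self) -> Optional[Decimal]:
        """Numeric view, or None when the text is not a number."""
        if self.is_null:
            return None
        text = self.raw.strip()
        if not text:
            return None
        try:
            return Decimal(text)
        except InvalidOperation:
            return None

    def as_date(self) -> Optional[date]:
        """ISO-8601 calendar-date view (date-picker entities store these)."""
        if self.is_null:
            return None
        try:
            return date.fromisoformat(self.raw.strip())
        except ValueError:
            return None

    def as_bool(self) -> bool:
        return self.raw == "true"


NULL = Value("", is_null=True)
TRUE = Value("true")
FALSE = Value("false")


def from_bool(flag: bool) -> Value:
    return TRUE if flag else FALSE


def render_number(num: Decimal) -> str:
    """Canonical text for a numeric result: no exponent, no trailing zeros."""
    if num == num.to_integral_value():
        return str(num.quantize(Decimal(1)))
    return format(num.normalize(), "f")
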