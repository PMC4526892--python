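"""Built-in API functions callable from logic scripts.

A function receives the engine context and the already-evaluated
argument values and returns a :class:`Value`.  Lookup is
case-insensitive (printed scripts mix ``message`` and ``Message``);
registration rejects duplicates, so built-ins cannot be shadowed.
Native extensions register through :meth:`FunctionRegistry.register`.
"""
from __future__ import annotations

from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable

from ..context import EngineContext
from ..errors import ConfigError, RuntimeLogicError
from .values import NULL, Value

BuiltinImpl = Callable[[EngineContext, list[Value]], Value]

LIST_SEPARATOR = "|"  # scripts see multi-value query results joined by this


class FunctionRegistry:
    """Name -> implementation map with case-insensitive dispatch."""

    def __init__(self):
        self._functions: dict[str, BuiltinImpl] = {}

    def register(self, name: str, impl: BuiltinImpl) -> None:
        key = name.lower()
        if key in self._functions:
            raise ConfigError(f"function {name!r} is already registered")
        self._functions[key] = impl

    def resolve(self, name: str) -> BuiltinImpl:
        impl = self._functions.get(name.lower())
        if impl is None:
            raise RuntimeLogicError(f"call to unregistered function {name!r}")
        return impl

    def names(self) -> set[str]:
        return set(self._functions)

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._functions


# --- implementations ------------------------------------------------------

def _message(ctx: EngineContext, args: list[Value]) -> Value:
    ctx.emit_message(" ".join(a.raw for a in args))
    return NULL


def _format_number(ctx: EngineContext, args: list[Value]) -> Value:
    if len(args) != 2:
        raise RuntimeLogicError("formatNumber expects (value, decimals)")
    number = args[0].as_number()
    decimals = args[1].as_number()
    if number is None:
        raise RuntimeLogicError(
            f"formatNumber: {args[0].raw!r} is not a number")
    if decimals is None or decimals < 0 or decimals != int(decimals):
        raise RuntimeLogicError(
            f"formatNumber: invalid decimal count {args[1].raw!r}")
    places = int(decimals)
    quantum = Decimal(1).scaleb(-places)
    rounded = number.quantize(quantum, rounding=ROUND_HALF_UP)
    return Value(f"{rounded:.{places}f}")


def _calculate_age_in_months(ctx: EngineContext, args: list[Value]) -> Value:
    if len(args) != 1:
        raise RuntimeLogicError("calculateAgeInMonths expects one ISO date")
    birthday = args[0].as_date()
    if birthday is None:
        raise RuntimeLogicError(
            f"calculateAgeInMonths: {args[0].raw!r} is not an ISO date")
    today = ctx.now.date() if hasattr(ctx.now, "date") else ctx.now
    months = (today.year - birthday.year) * 12 + (today.month - birthday.month)
    if months >= 0 and today.day < birthday.day:
        months -= 1    # last month not yet completed
    elif months < 0 and today.day > birthday.day:
        months += 1
    if birthday > today:
        # validation logic tests "< 0" to catch future birthdays, so even
        # a birthday later this month must read negative
        months = min(months, -1)
    return Value(str(months))


def _generate_collection_id(ctx: EngineContext, args: list[Value]) -> Value:
    return Value(ctx.next_collection_id())


def _require_scheduler(ctx: EngineContext):
    if ctx.scheduler is None:
        raise RuntimeLogicError("no scheduler attached to this context")
    return ctx.scheduler


def _schedule_task(ctx: EngineContext, args: list[Value]) -> Value:
    scheduler = _require_scheduler(ctx)
    if not args:
        raise RuntimeLogicError("scheduleTask expects at least a task id")
    task_id = args[0].raw
    if len(args) == 1:
        scheduler.schedule_task(task_id)
    else:
        start = None if args[1].is_null else args[1].raw
        end = None if len(args) < 3 or args[2].is_null else args[2].raw
        rrule = None if len(args) < 4 or args[3].is_null else args[3].raw
        scheduler.schedule_task(task_id, start, end, rrule, now=ctx.now)
    return NULL


def _hide(ctx: EngineContext, args: list[Value]) -> Value:
    _require_scheduler(ctx).hide(args[0].raw)
    return NULL


def _show(ctx: EngineContext, args: list[Value]) -> Value:
    _require_scheduler(ctx).show(args[0].raw)
    return NULL


def _require_datastore(ctx: EngineContext):
    if ctx.datastore is None:
        raise RuntimeLogicError("no datastore attached to this context")
    return ctx.datastore


def _find_latest(ctx: EngineContext, args: list[Value]) -> Value:
    value = _require_datastore(ctx).find_latest(args[0].raw)
    return Value(value) if value is not None else Value("")


def _find_latest_n(ctx: EngineContext, args: list[Value]) -> Value:
    n = args[1].as_number()
    values = _require_datastore(ctx).find_latest_n(
        args[0].raw, int(n) if n is not None else 0)
    return Value(LIST_SEPARATOR.join(values))


def _find_by_date(ctx: EngineContext, args: list[Value]) -> Value:
    lo, hi = args[1].as_date(), args[2].as_date()
    if lo is None or hi is None:
        raise RuntimeLogicError("findByDate expects two ISO dates")
    values = _require_datastore(ctx).find_by_date(args[0].raw, lo, hi)
    return Value(LIST_SEPARATOR.join(values))


def _find_by_placement(ctx: EngineContext, args: list[Value]) -> Value:
    lo, hi = args[1].as_number(), args[2].as_number()
    values = _require_datastore(ctx).find_by_placement(
        args[0].raw,
        int(lo) if lo is not None else 0,
        int(hi) if hi is not None else 0)
    return Value(LIST_SEPARATOR.join(values))


def _save_value(ctx: EngineContext, args: list[Value]) -> Value:
    """Append one record for ``variable`` (split at the first underscore
    into instrument/entity) to the session's pending records."""
    if len(args) != 2:
        raise RuntimeLogicError("saveValue expects (variable, value)")
    variable, value = args[0].raw, args[1].raw
    instrument, _, entity = variable.partition("_")
    if not entity:
        raise RuntimeLogicError(
            f"saveValue: {variable!r} is not of the form object_name")
    ctx.pending_records.append((instrument, entity, value, value))
    return NULL


def default_registry() -> FunctionRegistry:
    registry = FunctionRegistry()
    for name, impl in [
        ("message", _message),
        ("formatNumber", _format_number),
        ("calculateAgeInMonths", _calculate_age_in_months),
        ("generateCollectionId", _generate_collection_id),
        ("scheduleTask", _schedule_task),
        ("hide", _hide),
        ("show", _show),
        ("findLatest", _find_latest),
        ("findLatestN", _find_latest_n),
        ("findByDate", _find_by_date),
        ("findByPlacement", _find_by_placement),
        ("saveValue", _save_value),
    ]:
        registry.register(name, impl)
    return registry
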