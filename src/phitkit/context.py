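"""Shared execution context: the global variable store and effect sinks.

One :class:`EngineContext` models one app session on a device: variables
written by any script are visible to every other script until the
session ends, exactly like the single global namespace the
``instrument_entity`` naming convention guarantees.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from typing import Callable, Optional

log = logging.getLogger("phitkit.logic")


class VariableStore:
    """Global map of ``object_name`` -> raw text value.

    Lookups never mutate; every write is appended to :attr:`writes` so
    callers (sessions, advisor runs) can attribute effects to a run.
    """

    def __init__(self, initial: Optional[dict[str, str]] = None):
        self._values: dict[str, str] = dict(initial or {})
        self.writes: list[tuple[str, str]] = []
        self.listeners: list[Callable[[str, str], None]] = []

    def get(self, name: str) -> Optional[str]:
        return self._values.get(name)

    def lookup(self, name: str) -> str:
        """Value of ``name``; undefined names read as "" with a warning."""
        value = self._values.get(name)
        if value is None:
            log.warning("undefined variable {%s} read as empty string", name)
            return ""
        return value

    def set(self, name: str, value: str) -> None:
        self._values[name] = value
        self.writes.append((name, value))
        for listener in self.listeners:
            listener(name, value)

    def __contains__(self, name: str) -> bool:
        return name in self._values

    def as_dict(self) -> dict[str, str]:
        return dict(self._values)


@dataclass
class EngineContext:
    """Variable store, function registry, clock, and effect sinks."""

    store: VariableStore = field(default_factory=VariableStore)
    registry: "FunctionRegistry" = None  # filled in __post_init__
    now: datetime = field(default_factory=datetime.now)
    scheduler: Optional[object] = None          # phitkit.scheduler.Scheduler
    datastore: Optional[object] = None          # phitkit.datastore.DataStore
    messages: list[str] = field(default_factory=list)
    pending_records: list = field(default_factory=list)
    _collection_counter: int = 0
    collection_id_source: Optional[Callable[[], str]] = None

    def __post_init__(self):
        if self.registry is None:
            from .logic.builtins import default_registry
            self.registry = default_registry()

    def next_collection_id(self) -> str:
        """Monotonic per-session id; injectable for tests via
        :attr:`collection_id_source`."""
        if self.collection_id_source is not None:
            return self.collection_id_source()
        value = self._collection_counter
        self._collection_counter += 1
        return str(value)

    def emit_message(self, text: str) -> None:
        self.messages.append(text)
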