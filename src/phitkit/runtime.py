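"""Headless instrument execution.

A :class:`Session` replays an interactive instrument without a UI: a
*response provider* stands in for the touch screen, answering each
entity in layout order, and the runner dispatches the lifecycle events
in the same order the device would:

    onInstrumentEnter
      (onFormEnter -> value changes -> onValidate -> onFormExit)*
    onInstrumentExit

Value-change events go to the entity first, then bubble to the form.
Validation runs entity blocks first, then the form block; a ``goto``
raised during validation repositions the cursor (the re-entry pattern
used for "birthday must be before today"-style checks).  A missing
required answer blocks navigation: the session stops, incomplete, with
the violation recorded.

The transcript is line-oriented (``EVENT``/``SET``/``MSG`` lines) for
golden-file testing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol

from .context import EngineContext
from .errors import RuntimeLogicError
from .instrument import EntityDef, FormDef, InstrumentDef, qualified_name
from .logic.interpreter import NORMAL, Signal, execute

MAX_FORM_VISITS = 1_000
CHECKBOX_SEPARATOR = "|"
SKIP = "skip"


class ResponseProvider(Protocol):
    def __call__(self, form: str, entity: str,
                 definition: EntityDef) -> Optional[str]: ...


class ScriptedProvider:
    """Answers read from plain text, one per line: ``form.entity=code``.

    Lines are consumed in order per (form, entity) key, so a form that
    is re-entered via ``goto`` can receive a corrected answer from a
    later line.  Entities with no remaining line are skipped.
    """

    def __init__(self, text: str):
        self._queues: dict[tuple[str, str], list[str]] = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key_part, sep, code = line.partition("=")
            if not sep or "." not in key_part:
                raise ValueError(f"bad answer line {raw!r} "
                                 f"(expected form.entity=code)")
            form, _, entity = key_part.strip().partition(".")
            self._queues.setdefault((form, entity.strip()),
                                    []).append(code.strip())

    def __call__(self, form: str, entity: str,
                 definition: EntityDef) -> Optional[str]:
        queue = self._queues.get((form, entity))
        if queue:
            return queue.pop(0)
        return None


@dataclass
class ValidationResult:
    violations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


@dataclass
class Session:
    instrument: InstrumentDef
    ctx: EngineContext
    form_cursor: int = 0
    completed: bool = False
    blocked: bool = False
    violations: list[tuple[str, str]] = field(default_factory=list)
    transcript: list[str] = field(default_factory=list)
    _message_mark: int = 0
    _code_violations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def messages(self) -> list[str]:
        return self.ctx.messages

    # --- transcript helpers ---------------------------------------------
    def _log(self, line: str) -> None:
        self.transcript.append(line)

    def _drain_messages(self) -> None:
        for msg in self.ctx.messages[self._message_mark:]:
            self._log(f"MSG {msg}")
        self._message_mark = len(self.ctx.messages)

    def _fire(self, event: str, scope_label: str, blocks) -> Signal:
        """Run all logic blocks for one event; stop at the first control
        signal."""
        self._log(f"EVENT {event} {scope_label}")
        for block in blocks:
            signal = execute(block.program, self.ctx)
            self._drain_messages()
            if signal.kind != "normal":
                return signal
        self._drain_messages()
        return NORMAL


def _store_listener(session: Session) -> Callable[[str, str], None]:
    return lambda name, value: session._log(f"SET {name} {value}")


def set_entity_value(session: Session, form: FormDef, entity: EntityDef,
                     code: str) -> Signal:
    """Record an answer: write the code into the store and fire
    onValueChanged on the entity, then on the form."""
    defn = session.instrument
    if entity.type in ("radio", "likert"):
        if code not in entity.codes():
            session._code_violations.append(
                (entity.name, f"code {code!r} not in codebook"))
            return NORMAL
    elif entity.type == "checkbox":
        parts = code.split(CHECKBOX_SEPARATOR)
        bad = [p for p in parts if p not in entity.codes()]
        if bad:
            session._code_violations.append(
                (entity.name, f"codes {bad!r} not in codebook"))
            return NORMAL
    session.ctx.store.set(qualified_name(defn.name, entity.name), code)
    signal = session._fire("onValueChanged", f"entity:{entity.name}",
                           entity.blocks("onValueChanged"))
    if signal.kind != "normal":
        return signal
    return session._fire("onValueChanged", f"form:{form.name}",
                         form.blocks("onValueChanged"))


def validate_form(session: Session, form: FormDef
                  ) -> tuple[ValidationResult, Signal]:
    """Required-field and codebook checks plus author onValidate logic.

    Entity-level blocks run before the form-level block; the first
    control signal (typically a corrective ``goto``) wins.
    """
    result = ValidationResult()
    result.violations.extend(session._code_violations)
    store = session.ctx.store
    for entity in form.entities:
        if entity.required:
            value = store.get(qualified_name(session.instrument.name,
                                             entity.name))
            if not value:
                result.violations.append((entity.name, "required"))
    for entity in form.entities:
        signal = session._fire("onValidate", f"entity:{entity.name}",
                               entity.blocks("onValidate"))
        if signal.kind != "normal":
            return result, signal
    signal = session._fire("onValidate", f"form:{form.name}",
                           form.blocks("onValidate"))
    return result, signal


def _label_for(entity: EntityDef, code: str) -> str:
    if entity.type in ("radio", "likert"):
        for item in entity.items:
            if item.code == code:
                return item.label
    elif entity.type == "checkbox":
        labels = []
        for part in code.split(CHECKBOX_SEPARATOR):
            for item in entity.items:
                if item.code == part:
                    labels.append(item.label)
        return CHECKBOX_SEPARATOR.join(labels)
    return code


def _flush_form_records(session: Session, form: FormDef) -> None:
    """Queue one pending record per answered, saveable entity (and per
    named static text marked save)."""
    defn = session.instrument
    for entity in form.entities:
        if not entity.save:
            continue
        code = session.ctx.store.get(qualified_name(defn.name, entity.name))
        if code is None:
            continue        # never answered: nothing to save
        session.ctx.pending_records.append(
            (defn.name, entity.name, code, _label_for(entity, code)))
    for node in _static_saves(form):
        session.ctx.pending_records.append(
            (defn.name, node.name, node.text, node.text))


def _static_saves(form: FormDef):
    def walk(node):
        if node is None:
            return
        if node.kind == "staticText" and node.save and node.name:
            yield node
        for child in node.children:
            yield from walk(child)
    yield from walk(form.layout)


def _goto_cursor(defn: InstrumentDef, label: str) -> int:
    for i, form in enumerate(defn.forms):
        if form.name == label:
            return i
    raise RuntimeLogicError(f"goto target {label!r} names no form in "
                            f"{defn.name!r}")


def run_instrument(defn: InstrumentDef, provider: ResponseProvider,
                   ctx: EngineContext,
                   max_form_visits: int = MAX_FORM_VISITS) -> Session:
    """Run an interactive instrument end to end; returns the session."""
    if defn.kind != "interactive":
        raise RuntimeLogicError(
            f"{defn.name!r} is a script instrument; use "
            f"run_script_instrument")
    session = Session(instrument=defn, ctx=ctx)
    listener = _store_listener(session)
    ctx.store.listeners.append(listener)
    try:
        _run_interactive(session, defn, provider, max_form_visits)
    finally:
        ctx.store.listeners.remove(listener)
    return session


def _run_interactive(session: Session, defn: InstrumentDef,
                     provider: ResponseProvider, max_form_visits: int):
    signal = session._fire("onInstrumentEnter", f"instrument:{defn.name}",
                           defn.blocks("onInstrumentEnter"))
    cursor = 0
    if signal.kind == "goto":
        cursor = _goto_cursor(defn, signal.label)
    elif signal.kind == "exit":
        cursor = len(defn.forms)

    visits = 0
    while 0 <= cursor < len(defn.forms):
        visits += 1
        if visits > max_form_visits:
            raise RuntimeLogicError(
                f"{defn.name}: exceeded {max_form_visits} form visits "
                f"(navigation loop?)")
        form = defn.forms[cursor]
        session.form_cursor = cursor
        session._code_violations = []

        signal = session._fire("onFormEnter", f"form:{form.name}",
                               form.blocks("onFormEnter"))
        if signal.kind == "goto":
            cursor = _goto_cursor(defn, signal.label)
            continue
        if signal.kind == "exit":
            break

        interrupted = None
        for entity in form.entities:
            answer = provider(form.name, entity.name, entity)
            if answer is None or answer == SKIP:
                continue            # skipped: variable stays unset
            signal = set_entity_value(session, form, entity, answer)
            if signal.kind in ("goto", "exit"):
                interrupted = signal
                break
        if interrupted is not None:
            if interrupted.kind == "exit":
                break
            cursor = _goto_cursor(defn, interrupted.label)
            continue

        result, signal = validate_form(session, form)
        if signal.kind == "goto":
            cursor = _goto_cursor(defn, signal.label)
            continue
        if signal.kind == "exit":
            break
        # required violations block navigation; codebook violations are
        # recorded but defer to author logic (the answer was never stored)
        session.violations.extend(result.violations)
        if any(reason == "required" for _, reason in result.violations):
            session.blocked = True
            session._log(f"BLOCKED {form.name}")
            return                  # abandoned: no onInstrumentExit

        _flush_form_records(session, form)
        signal = session._fire("onFormExit", f"form:{form.name}",
                               form.blocks("onFormExit"))
        if signal.kind == "goto":
            cursor = _goto_cursor(defn, signal.label)
            continue
        if signal.kind == "exit":
            break
        cursor += 1                 # normal advance and nextForm alike

    session._fire("onInstrumentExit", f"instrument:{defn.name}",
                  defn.blocks("onInstrumentExit"))
    session.completed = True


def run_script_instrument(defn: InstrumentDef,
                          ctx: EngineContext) -> Session:
    """Run a background (form-less) instrument: enter then exit logic."""
    if defn.kind != "script":
        raise RuntimeLogicError(f"{defn.name!r} is not a script instrument")
    session = Session(instrument=defn, ctx=ctx)
    listener = _store_listener(session)
    ctx.store.listeners.append(listener)
    try:
        signal = session._fire("onInstrumentEnter",
                               f"instrument:{defn.name}",
                               defn.blocks("onInstrumentEnter"))
        if signal.kind != "exit":
            pass                    # goto/nextForm are meaningless here
        session._fire("onInstrumentExit", f"instrument:{defn.name}",
                      defn.blocks("onInstrumentExit"))
        session.completed = True
    finally:
        ctx.store.listeners.remove(listener)
    return session
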