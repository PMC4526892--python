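"""Task scheduling: a VEVENT-flavoured subset of RFC5545 plus extensions.

Supported rule surface: DTSTART (absolute ISO datetime or the offset
grammar below), DTEND, DURATION, and RRULE restricted to
``FREQ``/``INTERVAL``/``BYDAY`` with DAILY/WEEKLY/MONTHLY frequencies.
RRULE text is accepted in both the standard semicolon dialect
(``FREQ=DAILY;INTERVAL=3``) and the comma dialect used in advisor
scripts (``FREQ=DAILY,INTERVAL=3``); commas are normalized to
semicolons internally.

Offset-anchor start grammar (an extension, not part of RFC5545)::

    P<n>D          n days from "now", same clock time
    P<n>DTA<h>H    n days from "now", anchored to h:00 local

so ``"P1DTA8H"`` with a recurrence of every 3 days means "starting
tomorrow at 8 am, then every 3rd day at 8 am".  The grammar is
reverse-engineered from that usage and is flagged as such in the
package docs.  All datetimes are timezone-naive local times.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from typing import Optional

from .errors import ScheduleError

WEEKDAY_CODES = {"MO": 0, "TU": 1, "WE": 2, "TH": 3, "FR": 4, "SA": 5, "SU": 6}
_CODE_FOR_WEEKDAY = {v: k for k, v in WEEKDAY_CODES.items()}

FREQUENCIES = ("DAILY", "WEEKLY", "MONTHLY")

_OFFSET_RE = re.compile(r"^P(\d+)D(?:TA(\d+)H)?$")


@dataclass(frozen=True)
class Recurrence:
    freq: str
    interval: int = 1
    by_day: frozenset[int] = frozenset()   # weekday numbers, Monday=0


@dataclass(frozen=True)
class ScheduleRule:
    task_id: str
    start: datetime
    end: Optional[datetime] = None
    duration: Optional[timedelta] = None
    recurrence: Optional[Recurrence] = None


@dataclass
class TaskEntry:
    task_id: str
    title: str = ""
    description: str = ""
    icon_ref: str = ""
    menu_index: int = 0


@dataclass(frozen=True)
class Occurrence:
    task_id: str
    at: datetime


def parse_start_spec(spec: str, now: datetime) -> datetime:
    """Resolve a DTSTART spec: ISO datetime verbatim, or offset-anchor."""
    m = _OFFSET_RE.match(spec.strip())
    if m:
        days = int(m.group(1))
        start = now + timedelta(days=days)
        if m.group(2) is not None:
            hour = int(m.group(2))
            if hour > 23:
                raise ScheduleError(f"anchor hour out of range in {spec!r}")
            start = datetime.combine(start.date(), time(hour, 0))
        return start.replace(second=0, microsecond=0)
    try:
        return datetime.fromisoformat(spec.strip())
    except ValueError:
        raise ScheduleError(f"unparseable start spec {spec!r}")


def parse_rrule(text: str) -> Recurrence:
    """Parse an RRULE body (semicolon or comma dialect) to a Recurrence."""
    normalized = text.strip()
    if ";" not in normalized:
        normalized = normalized.replace(",", ";")
    freq: Optional[str] = None
    interval = 1
    by_day: set[int] = set()
    for part in filter(None, (p.strip() for p in normalized.split(";"))):
        key, sep, value = part.partition("=")
        if not sep:
            raise ScheduleError(f"malformed RRULE part {part!r}")
        key = key.upper()
        if key == "FREQ":
            if value.upper() not in FREQUENCIES:
                raise ScheduleError(f"unsupported FREQ {value!r}")
            freq = value.upper()
        elif key == "INTERVAL":
            try:
                interval = int(value)
            except ValueError:
                raise ScheduleError(f"INTERVAL must be an integer: {value!r}")
            if interval < 1:
                raise ScheduleError("INTERVAL must be >= 1")
        elif key == "BYDAY":
            for code in value.upper().split(","):
                if code not in WEEKDAY_CODES:
                    raise ScheduleError(f"unknown BYDAY code {code!r}")
                by_day.add(WEEKDAY_CODES[code])
        else:
            raise ScheduleError(f"unsupported RRULE key {key!r}")
    if freq is None:
        raise ScheduleError("RRULE is missing FREQ")
    return Recurrence(freq=freq, interval=interval, by_day=frozenset(by_day))


def _add_months(day: date, months: int) -> Optional[date]:
    month0 = day.month - 1 + months
    year, month = day.year + month0 // 12, month0 % 12 + 1
    try:
        return date(year, month, day.day)
    except ValueError:
        return None     # e.g. Jan 31 + 1 month: month is skipped (RFC rule)


def occurrences(rule: ScheduleRule,
                window: tuple[datetime, datetime]) -> list[Occurrence]:
    """Expand a rule's occurrence datetimes within ``window`` (inclusive).

    The first occurrence is the resolved start; later ones follow the
    recurrence.  Strictly increasing; bounded above by the rule's end.
    """
    lo, hi = window
    if hi < lo:
        return []
    limit = min(hi, rule.end) if rule.end is not None else hi
    result: list[Occurrence] = []
    for at in _generate(rule, limit):
        if at > limit:
            break
        if at >= lo:
            result.append(Occurrence(rule.task_id, at))
    return result


def _generate(rule: ScheduleRule, limit: datetime):
    start = rule.start
    rec = rule.recurrence
    if rec is None:
        yield start
        return
    if rec.freq == "DAILY":
        at = start
        while at <= limit:
            yield at
            at += timedelta(days=rec.interval)
    elif rec.freq == "WEEKLY":
        by_day = rec.by_day or frozenset({start.weekday()})
        # week index counts Monday-started weeks from the start's week
        start_week = start.date() - timedelta(days=start.weekday())
        day = start.date()
        while True:
            at = datetime.combine(day, start.time())
            if at > limit:
                return
            weeks = (day - timedelta(days=day.weekday()) - start_week).days // 7
            if at >= start and day.weekday() in by_day \
                    and weeks % rec.interval == 0:
                yield at
            day += timedelta(days=1)
    elif rec.freq == "MONTHLY":
        months = 0
        while True:
            day = _add_months(start.date(), months)
            months += rec.interval
            if day is None:
                continue
            at = datetime.combine(day, start.time())
            if at > limit:
                return
            yield at
    else:                                            # pragma: no cover
        raise ScheduleError(f"unsupported frequency {rec.freq!r}")


def _end_of_day(at: datetime) -> datetime:
    return datetime.combine(at.date(), time(23, 59, 59))


class Scheduler:
    """Task registry: entries, schedule rules, and hide/show overrides.

    Visibility at an instant ``now``: a task must not be hidden, and must
    either have been shown ad hoc (one-argument scheduleTask, or the
    ``show`` command) or have an active occurrence window covering
    ``now`` (occurrence time to occurrence + duration; default duration
    runs to the end of the occurrence's calendar day).
    """

    def __init__(self):
        self.entries: dict[str, TaskEntry] = {}
        self.rules: dict[str, ScheduleRule] = {}
        self._hidden: set[str] = set()
        self._adhoc: set[str] = set()

    def add_task(self, entry: TaskEntry) -> None:
        self.entries[entry.task_id] = entry

    def _require_task(self, task_id: str) -> TaskEntry:
        entry = self.entries.get(task_id)
        if entry is None:
            raise ScheduleError(f"unknown task id {task_id!r}")
        return entry

    def schedule_task(self, task_id: str, start: Optional[str] = None,
                      end: Optional[str] = None,
                      rrule_text: Optional[str] = None,
                      now: Optional[datetime] = None
                      ) -> Optional[ScheduleRule]:
        """One argument: show the task now (ad hoc).  With a start spec:
        install (or replace) a full schedule rule."""
        self._require_task(task_id)
        if start is None:
            self._adhoc.add(task_id)
            self._hidden.discard(task_id)
            return None
        now = now or datetime.now()
        rule = ScheduleRule(
            task_id=task_id,
            start=parse_start_spec(start, now),
            end=None if end is None else parse_start_spec(end, now),
            recurrence=None if rrule_text is None else parse_rrule(rrule_text),
        )
        if rule.end is not None and rule.end < rule.start:
            raise ScheduleError(f"{task_id}: end precedes start")
        self.rules[task_id] = rule      # re-scheduling replaces the rule
        return rule

    def hide(self, task_id: str) -> None:
        self._require_task(task_id)
        self._hidden.add(task_id)
        self._adhoc.discard(task_id)

    def show(self, task_id: str) -> None:
        self._require_task(task_id)
        self._hidden.discard(task_id)
        self._adhoc.add(task_id)

    def is_hidden(self, task_id: str) -> bool:
        return task_id in self._hidden

    def occurrences(self, task_id: str,
                    window: tuple[datetime, datetime]) -> list[Occurrence]:
        rule = self.rules.get(task_id)
        return occurrences(rule, window) if rule else []

    def _active_now(self, rule: ScheduleRule, now: datetime) -> bool:
        # scan occurrences starting the day before `now` so a window that
        # opened yesterday but carries a long duration is still caught
        horizon = rule.duration or timedelta(days=1)
        lo = now - horizon - timedelta(days=1)
        for occ in occurrences(rule, (lo, now)):
            window_end = occ.at + rule.duration if rule.duration \
                else _end_of_day(occ.at)
            if occ.at <= now <= window_end:
                return True
        return False

    def visible_tasks(self, now: datetime) -> list[TaskEntry]:
        visible = []
        for task_id, entry in self.entries.items():
            if task_id in self._hidden:
                continue
            if task_id in self._adhoc:
                visible.append(entry)
                continue
            rule = self.rules.get(task_id)
            if rule is not None and self._active_now(rule, now):
                visible.append(entry)
        return sorted(visible, key=lambda e: (e.menu_index, e.title))

    # --- persistence -----------------------------------------------------

    def serialize_rule(self, task_id: str) -> str:
        """iCalendar-like text block for one rule (DTSTART/DTEND/RRULE)."""
        rule = self.rules[task_id]
        lines = [f"TASK:{task_id}", f"DTSTART:{rule.start.isoformat()}"]
        if rule.end is not None:
            lines.append(f"DTEND:{rule.end.isoformat()}")
        if rule.duration is not None:
            lines.append(f"DURATION:{int(rule.duration.total_seconds())}S")
        if rule.recurrence is not None:
            rec = rule.recurrence
            parts = [f"FREQ={rec.freq}", f"INTERVAL={rec.interval}"]
            if rec.by_day:
                codes = ",".join(_CODE_FOR_WEEKDAY[d]
                                 for d in sorted(rec.by_day))
                parts.append(f"BYDAY={codes}")
            lines.append("RRULE:" + ";".join(parts))
        return "\n".join(lines)

    def load_rule(self, block: str) -> ScheduleRule:
        task_id, start, end, duration, rec = None, None, None, None, None
        for line in filter(None, (ln.strip() for ln in block.splitlines())):
            key, _, value = line.partition(":")
            if key == "TASK":
                task_id = value
            elif key == "DTSTART":
                start = datetime.fromisoformat(value)
            elif key == "DTEND":
                end = datetime.fromisoformat(value)
            elif key == "DURATION":
                duration = timedelta(seconds=int(value.rstrip("S")))
            elif key == "RRULE":
                rec = parse_rrule(value)
            else:
                raise ScheduleError(f"unknown rule line {key!r}")
        if task_id is None or start is None:
            raise ScheduleError("rule block needs TASK and DTSTART lines")
        rule = ScheduleRule(task_id, start, end, duration, rec)
        self.rules[task_id] = rule
        return rule
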