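"""Recurrence expansion and task-list visibility."""
from datetime import datetime, timedelta

import pytest
from dateutil import rrule as du_rrule
from hypothesis import given, settings, strategies as st

from phitkit import (Recurrence, ScheduleError, ScheduleRule, Scheduler,
                     TaskEntry, occurrences, parse_rrule, parse_start_spec)

from conftest import make_scheduler

NOW = datetime(2024, 3, 10, 14, 0)


# --- start specs ----------------------------------------------------------

@pytest.mark.parametrize("spec,now,expected", [
    ("P1DTA8H", NOW, datetime(2024, 3, 11, 8, 0)),
    ("2024-03-10T08:00", NOW, datetime(2024, 3, 10, 8, 0)),
    ("P0DTA8H", datetime(2024, 3, 10, 6, 0), datetime(2024, 3, 10, 8, 0)),
    ("P3D", NOW, datetime(2024, 3, 13, 14, 0)),   # no anchor: keep time
])
def test_parse_start_spec(spec, now, expected):
    assert parse_start_spec(spec, now) == expected


@pytest.mark.parametrize("bad", ["PXD", "P1DTA99H", "sometime", "P1DT8H"])
def test_bad_start_spec(bad):
    with pytest.raises(ScheduleError):
        parse_start_spec(bad, NOW)


# --- rrule parsing --------------------------------------------------------

def test_parse_rrule_comma_dialect():
    rec = parse_rrule("FREQ=DAILY,INTERVAL=3")
    assert rec == Recurrence("DAILY", 3)


def test_parse_rrule_semicolon_dialect_with_byday():
    rec = parse_rrule("FREQ=WEEKLY;BYDAY=FR")
    assert rec.freq == "WEEKLY" and rec.interval == 1
    assert rec.by_day == frozenset({4})


def test_parse_rrule_default_interval():
    assert parse_rrule("FREQ=DAILY") == Recurrence("DAILY", 1)


@pytest.mark.parametrize("bad", ["INTERVAL=3", "FREQ=HOURLY",
                                 "FREQ=DAILY;COUNT=2", "FREQ=DAILY;BAD"])
def test_parse_rrule_errors(bad):
    with pytest.raises(ScheduleError):
        parse_rrule(bad)


# --- occurrence expansion -------------------------------------------------

def test_every_third_day_at_eight():
    start = datetime(2024, 3, 11, 8, 0)
    rule = ScheduleRule("PSQI", start, recurrence=Recurrence("DAILY", 3))
    occ = occurrences(rule, (start, start + timedelta(days=10)))
    assert [o.at for o in occ] == [start + timedelta(days=d)
                                   for d in (0, 3, 6, 9)]
    assert all(o.at.hour == 8 for o in occ)


def test_each_friday_at_eight():
    start = datetime(2024, 3, 10, 8, 0)           # a Sunday
    rule = ScheduleRule("t", start,
                        recurrence=Recurrence("WEEKLY", 1,
                                              frozenset({4})))
    occ = occurrences(rule, (start, start + timedelta(days=21)))
    assert len(occ) == 3
    assert all(o.at.weekday() == 4 and o.at.hour == 8 for o in occ)
    assert occ[1].at - occ[0].at == timedelta(days=7)


def test_empty_window():
    rule = ScheduleRule("t", NOW, recurrence=Recurrence("DAILY", 1))
    assert occurrences(rule, (NOW, NOW - timedelta(days=1))) == []


def test_end_bounds_expansion():
    start = datetime(2024, 3, 1, 8, 0)
    rule = ScheduleRule("t", start, end=datetime(2024, 3, 5, 8, 0),
                        recurrence=Recurrence("DAILY", 1))
    occ = occurrences(rule, (start, datetime(2024, 3, 31)))
    assert len(occ) == 5


@settings(max_examples=50, deadline=None, derandomize=True)
@given(k=st.integers(min_value=1, max_value=7))
def test_daily_interval_exactness(k):
    rule = ScheduleRule("t", NOW, recurrence=Recurrence("DAILY", k))
    occ = occurrences(rule, (NOW, NOW + timedelta(days=90)))
    deltas = {(b.at - a.at) for a, b in zip(occ, occ[1:])}
    assert deltas == {timedelta(days=k)}
    assert [o.at for o in occ] == sorted(o.at for o in occ)


@pytest.mark.parametrize("freq,interval,byday", [
    ("DAILY", 1, None), ("DAILY", 3, None), ("DAILY", 7, None),
    ("WEEKLY", 1, None), ("WEEKLY", 2, None),
    ("WEEKLY", 1, ("FR",)), ("WEEKLY", 1, ("MO", "WE", "FR")),
    ("WEEKLY", 2, ("TU", "SA")),
    ("MONTHLY", 1, None), ("MONTHLY", 2, None),
])
def test_agrees_with_reference_rfc5545_expander(freq, interval, byday):
    """On the shared FREQ/INTERVAL/BYDAY subset the expansion matches an
    established recurrence library."""
    start = datetime(2024, 3, 15, 8, 0)
    horizon = start + timedelta(days=180)
    rec = Recurrence(freq, interval,
                     frozenset() if byday is None else
                     frozenset({"MO TU WE TH FR SA SU".split().index(d)
                                for d in byday}))
    rule = ScheduleRule("t", start, recurrence=rec)
    ours = [o.at for o in occurrences(rule, (start, horizon))]

    du_freq = {"DAILY": du_rrule.DAILY, "WEEKLY": du_rrule.WEEKLY,
               "MONTHLY": du_rrule.MONTHLY}[freq]
    kwargs = dict(freq=du_freq, interval=interval, dtstart=start,
                  until=horizon)
    if byday is not None:
        kwargs["byweekday"] = ["MO TU WE TH FR SA SU".split().index(d)
                               for d in byday]
    theirs = list(du_rrule.rrule(**kwargs))
    assert ours == theirs


# --- scheduler task registry ----------------------------------------------

def test_schedule_task_one_argument_shows_now():
    scheduler = make_scheduler()
    scheduler.schedule_task("sleep%environment")
    visible = [e.task_id for e in scheduler.visible_tasks(NOW)]
    assert visible == ["sleep%environment"]


def test_schedule_task_full_rule_and_replacement():
    scheduler = make_scheduler()
    rule = scheduler.schedule_task("PSQI", "P1DTA8H", None,
                                   "FREQ=DAILY,INTERVAL=3", now=NOW)
    assert rule.recurrence.interval == 3
    replacement = scheduler.schedule_task("PSQI", "P2D", None,
                                          "FREQ=DAILY", now=NOW)
    assert scheduler.rules["PSQI"] is replacement    # replaces, not dup


def test_schedule_unknown_task_errors():
    with pytest.raises(ScheduleError, match="nosuch"):
        make_scheduler().schedule_task("nosuch")


def test_visibility_window_is_rest_of_day():
    scheduler = make_scheduler()
    scheduler.schedule_task("PSQI", "P1DTA8H", None,
                            "FREQ=DAILY,INTERVAL=3", now=NOW)
    day = datetime(2024, 3, 11)
    assert [e.task_id for e in scheduler.visible_tasks(
        day.replace(hour=9))] == ["PSQI"]
    assert scheduler.visible_tasks(day.replace(hour=7)) == []   # pre-anchor
    next_day = day + timedelta(days=1)
    assert scheduler.visible_tasks(next_day.replace(hour=9)) == []


def test_hide_show_semantics():
    scheduler = make_scheduler()
    scheduler.schedule_task("PSQI")         # ad hoc show
    scheduler.hide("PSQI")
    scheduler.hide("PSQI")                  # idempotent
    assert scheduler.visible_tasks(NOW) == []
    scheduler.show("PSQI")
    assert [e.task_id for e in scheduler.visible_tasks(NOW)] == ["PSQI"]
    scheduler.hide("PSQI")                  # last command wins
    assert scheduler.visible_tasks(NOW) == []


def test_task_list_ordered_by_menu_index_then_title():
    scheduler = Scheduler()
    for task_id, menu in [("b", 2), ("a", 1), ("c", 1)]:
        scheduler.add_task(TaskEntry(task_id=task_id, title=task_id,
                                     menu_index=menu))
        scheduler.show(task_id)
    assert [e.task_id for e in scheduler.visible_tasks(NOW)] == \
        ["a", "c", "b"]


def test_rule_serialization_round_trip():
    scheduler = make_scheduler()
    scheduler.schedule_task("PSQI", "P1DTA8H", None,
                            "FREQ=DAILY,INTERVAL=3", now=NOW)
    block = scheduler.serialize_rule("PSQI")
    fresh = make_scheduler()
    assert fresh.load_rule(block) == scheduler.rules["PSQI"]
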