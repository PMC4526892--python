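"""Headless session execution: events, validation, skip logic."""
import random

import pytest

from phitkit import (RuntimeLogicError, ScriptedProvider, parse_instrument,
                     run_instrument, run_script_instrument, set_entity_value,
                     validate_form)
from phitkit.fixtures import (BATTERY_SCRIPT_XML, EMPTY_SCRIPT_XML,
                              PCL_FORM1_XML, PTHX_XML, pcl17_xml)
from phitkit.respondents import SyntheticRespondent, generate_answers

from conftest import make_ctx

PCL17 = parse_instrument(pcl17_xml())


def run_pcl_form1(answer):
    ctx = make_ctx()
    ctx.store.set("PCL_Bcount", "0")
    inst = parse_instrument(PCL_FORM1_XML)
    provider = ScriptedProvider(f"F1.Q1={answer}\n" if answer else "")
    session = run_instrument(inst, provider, ctx)
    return ctx, session


def test_moderately_increments_bcount():
    ctx, session = run_pcl_form1("3")
    assert ctx.store.get("PCL_Bcount") == "1"
    assert ctx.store.get("PCL_Q1") == "3"
    assert session.completed and not session.blocked


@pytest.mark.parametrize("code", ["1", "2", "3", "4", "5"])
def test_bcount_increments_exactly_for_codes_3_4_5(code):
    ctx, _ = run_pcl_form1(code)
    expected = "1" if code in ("3", "4", "5") else "0"
    assert ctx.store.get("PCL_Bcount") == expected


def test_required_skip_blocks_navigation():
    ctx, session = run_pcl_form1(None)
    assert session.blocked and not session.completed
    assert ("Q1", "required") in session.violations
    # abandoned sessions never reach the instrument-exit logic
    assert "EVENT onInstrumentExit instrument:PCL" not in session.transcript


def test_answer_outside_codebook_is_violation_not_exception():
    ctx, session = run_pcl_form1("9")
    assert ctx.store.get("PCL_Q1") is None
    assert any("codebook" in reason for _, reason in session.violations)


def test_set_entity_value_fires_events_in_order():
    xml = ('<instrument name="t"><form name="f">'
           '<entity name="q" type="radio">'
           '<item code="1">one</item>'
           '<logic event="onValueChanged"><![CDATA['
           'set {t_entityHits} = "{t_entityHits}" + "1";]]></logic>'
           '</entity>'
           '<logic event="onValueChanged"><![CDATA['
           'set {t_formHits} = "{t_formHits}" + "1";]]></logic>'
           '</form></instrument>')
    inst = parse_instrument(xml)
    ctx = make_ctx()
    ctx.store.set("t_entityHits", "0")
    ctx.store.set("t_formHits", "0")
    from phitkit.runtime import Session
    session = Session(instrument=inst, ctx=ctx)
    form = inst.forms[0]
    set_entity_value(session, form, form.entities[0], "1")
    set_entity_value(session, form, form.entities[0], "1")
    assert ctx.store.get("t_entityHits") == "2"   # same value fires twice
    assert ctx.store.get("t_formHits") == "2"
    entity_idx = session.transcript.index("EVENT onValueChanged entity:q")
    form_idx = session.transcript.index("EVENT onValueChanged form:f")
    assert entity_idx < form_idx


def test_validate_form_required_and_optional():
    inst = parse_instrument(PCL_FORM1_XML)
    ctx = make_ctx()
    from phitkit.runtime import Session
    session = Session(instrument=inst, ctx=ctx)
    result, _ = validate_form(session, inst.forms[0])
    assert result.violations == [("Q1", "required")]
    ctx.store.set("PCL_Q1", "2")
    session2 = Session(instrument=inst, ctx=ctx)
    result2, _ = validate_form(session2, inst.forms[0])
    assert result2.ok


def test_validation_goto_reenters_form_with_corrected_answer():
    """Future birthday triggers the corrective message + goto; the
    re-entered form accepts the next scripted answer."""
    inst = parse_instrument(PTHX_XML)
    ctx = make_ctx()          # engine clock 2024-03-10
    provider = ScriptedProvider(
        "F0_PtID.ptID=P001\n"
        "F1_Birthday.birthday=2030-01-01\n"     # future: rejected
        "F1_Birthday.birthday=1990-01-01\n")    # corrected on re-entry
    session = run_instrument(inst, provider, ctx)
    assert session.completed
    assert session.messages == ["User's birthday must be before today."]
    assert ctx.store.get("ptHx_birthday") == "1990-01-01"
    assert int(ctx.store.get("ptHx_ageMonths")) > 0


def test_goto_unknown_form_raises():
    xml = ('<instrument name="t"><form name="f">'
           '<logic event="onFormExit"><![CDATA[goto F9;]]></logic>'
           '</form></instrument>')
    with pytest.raises(RuntimeLogicError, match="F9"):
        run_instrument(parse_instrument(xml), ScriptedProvider(""),
                       make_ctx())


def test_exit_skips_to_instrument_exit():
    xml = ('<instrument name="t">'
           '<form name="a"><logic event="onFormExit"><![CDATA[exit;]]>'
           '</logic></form>'
           '<form name="b"><logic event="onFormEnter"><![CDATA['
           'set {t_reached} = "yes";]]></logic></form>'
           '<logic event="onInstrumentExit"><![CDATA['
           'set {t_exited} = "yes";]]></logic>'
           '</instrument>')
    ctx = make_ctx()
    session = run_instrument(parse_instrument(xml), ScriptedProvider(""),
                             ctx)
    assert session.completed
    assert ctx.store.get("t_exited") == "yes"
    assert ctx.store.get("t_reached") is None


# --- script (background) instruments --------------------------------------

def test_battery_script_saves_one_record():
    ctx = make_ctx()
    ctx.store.set("sys_batteryLevel", "87")
    session = run_script_instrument(parse_instrument(BATTERY_SCRIPT_XML),
                                    ctx)
    assert session.completed
    assert ctx.store.get("battery_level") == "87"
    assert ctx.pending_records == [("battery", "level", "87", "87")]


def test_empty_script_instrument_completes_without_effects():
    ctx = make_ctx()
    session = run_script_instrument(parse_instrument(EMPTY_SCRIPT_XML), ctx)
    assert session.completed
    assert ctx.store.as_dict() == {} and ctx.pending_records == []


def test_repeating_script_runs_once_per_scheduler_tick():
    from datetime import datetime, timedelta
    from phitkit import ScheduleRule, Recurrence, occurrences
    # "every 5 minutes" style repetition driven by the scheduler
    rule = ScheduleRule("battery", datetime(2024, 3, 10, 8, 0),
                        recurrence=Recurrence("DAILY", 1))
    ticks = occurrences(rule, (datetime(2024, 3, 10), datetime(2024, 3, 13)))
    ctx = make_ctx()
    ctx.store.set("sys_batteryLevel", "50")
    inst = parse_instrument(BATTERY_SCRIPT_XML)
    for _ in ticks:
        run_script_instrument(inst, ctx)
    assert len(ctx.pending_records) == len(ticks) == 3


# --- properties over the 17-item fixture ----------------------------------

def expected_event_sequence(n_forms):
    events = ["onInstrumentEnter"]
    for _ in range(n_forms):
        events += ["onFormEnter", "onValidate", "onFormExit"]
    events.append("onInstrumentExit")
    return events


@pytest.mark.parametrize("seed", range(200))
def test_event_order_and_bcount_oracle(seed):
    """Event ordering is instrumentEnter (formEnter, changes, validate,
    formExit)* instrumentExit, and the exit-logic count equals a direct
    count of answers >= 3, across randomized answer scripts."""
    answers = generate_answers(PCL17, SyntheticRespondent(seed=seed))
    ctx = make_ctx()
    session = run_instrument(PCL17, ScriptedProvider(answers), ctx)
    assert session.completed

    codes = [int(line.split("=")[1]) for line in answers.splitlines()]
    assert ctx.store.get("PCL_Bcount") == str(sum(c >= 3 for c in codes))

    form_events = [line.split()[1] for line in session.transcript
                   if line.startswith("EVENT") and
                   ("form:" in line or "instrument:" in line)
                   and "onValueChanged" not in line]
    assert form_events == expected_event_sequence(len(PCL17.forms))


def test_no_store_writes_for_unanswered_entities():
    ctx = make_ctx()
    inst = parse_instrument(PCL_FORM1_XML)
    # make Q1 optional so skipping is allowed to complete the run
    inst.forms[0].entities[0].required = False
    session = run_instrument(inst, ScriptedProvider(""), ctx)
    assert session.completed
    assert "PCL_Q1" not in ctx.store.as_dict()


def test_uniform_answers_bcount_is_binomial():
    """Across seeds, the count of answers >= 3 behaves as
    Binomial(17, 3/5): the sample mean stays within 3 standard errors."""
    n_seeds, p, n_items = 500, 3 / 5, 17
    total = 0
    for seed in range(n_seeds):
        answers = generate_answers(PCL17, SyntheticRespondent(seed=seed))
        total += sum(int(line.split("=")[1]) >= 3
                     for line in answers.splitlines())
    mean = total / n_seeds
    expected = n_items * p
    stderr = (n_items * p * (1 - p) / n_seeds) ** 0.5
    assert abs(mean - expected) < 3 * stderr
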