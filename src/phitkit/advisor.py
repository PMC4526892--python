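"""Intelligent virtual advisor: assessment/plan scripts and risk alerts.

The advisor is a forward-chaining rules layer over the global variable
store.  Its XML groups logic by health *domain* (sleep, alcohol, ...);
each ``<assess>`` block holds one logic program that stratifies risk
from screener scores and — in its plan section — schedules intervention
tasks and reassessments through the scheduler.  Reassessment frequency
is not advisor state: it is whatever schedule the study gives the
advisor task itself.

Risk alerts are data, not code: ``<alert>`` elements pair a score
variable with a strictly-greater threshold, so studies can override the
shipped thresholds without touching the engine.
"""
from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Optional

from .context import EngineContext
from .errors import DefinitionError, LexError, LogicParseError, PhitError
from .logic import Program, parse_logic
from .logic.interpreter import execute


@dataclass
class AssessBlock:
    domain: str
    source: str
    program: Program


@dataclass
class RiskAlertRule:
    domain: str
    score_variable: str
    threshold: Decimal
    message: str


@dataclass
class AdvisorScript:
    assess_blocks: list[AssessBlock] = field(default_factory=list)
    alert_rules: list[RiskAlertRule] = field(default_factory=list)


@dataclass
class AssessmentOutcome:
    variables_written: dict[str, str] = field(default_factory=dict)
    tasks_scheduled: list[str] = field(default_factory=list)
    alerts_raised: list[tuple[str, str]] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)


def parse_advisor(xml_text: str) -> AdvisorScript:
    """Parse advisor XML: ``<advisor>`` wrapping ``<assess domain=...>``
    blocks (a bare ``<assess>`` root is accepted for single-domain
    scripts) plus optional ``<alert>`` rules."""
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        line, col = exc.position
        raise DefinitionError(
            f"malformed advisor XML at line {line}, column {col}") from exc
    script = AdvisorScript()
    if root.tag == "assess":
        elements = [root]
    elif root.tag == "advisor":
        elements = list(root)
    else:
        raise DefinitionError(
            f"expected <advisor> or <assess> root, got <{root.tag}>")
    for elem in elements:
        if elem.tag == "assess":
            script.assess_blocks.append(_parse_assess(elem))
        elif elem.tag == "alert":
            script.alert_rules.append(_parse_alert(elem))
        else:
            raise DefinitionError(
                f"unexpected element <{elem.tag}> in advisor")
    return script


def _parse_assess(elem: ET.Element) -> AssessBlock:
    domain = elem.get("domain", "")
    if not domain:
        raise DefinitionError("assess block without a domain")
    logic = elem.find("logic")
    source = (logic.text if logic is not None else elem.text) or ""
    try:
        program = parse_logic(source)
    except (LexError, LogicParseError) as exc:
        raise DefinitionError(
            f"domain {domain!r}: logic fails to parse: {exc}") from exc
    return AssessBlock(domain=domain, source=source, program=program)


def _parse_alert(elem: ET.Element) -> RiskAlertRule:
    try:
        threshold = Decimal(elem.get("threshold", ""))
    except ArithmeticError:
        raise DefinitionError(
            f"alert for {elem.get('domain')!r}: bad threshold")
    return RiskAlertRule(
        domain=elem.get("domain", ""),
        score_variable=elem.get("score", ""),
        threshold=threshold,
        message=elem.get("message", ""))


def evaluate_risk_alerts(rules: list[RiskAlertRule],
                         store) -> list[tuple[str, str]]:
    """Alerts for every rule whose score variable is present, numeric,
    and *strictly* greater than the threshold."""
    alerts = []
    for rule in rules:
        raw = store.get(rule.score_variable)
        if raw is None:
            continue
        try:
            score = Decimal(raw.strip())
        except ArithmeticError:
            continue
        if score > rule.threshold:
            alerts.append((rule.domain, rule.message))
    return alerts


def run_advisor(script: AdvisorScript, ctx: EngineContext,
                extra_alert_rules: Optional[list[RiskAlertRule]] = None
                ) -> AssessmentOutcome:
    """Execute every assess block in document order against the context.

    All effects of the run — variables written, tasks scheduled, alerts,
    messages — are captured in the returned outcome.  Runtime errors are
    annotated with the domain they arose in.
    """
    outcome = AssessmentOutcome()
    write_mark = len(ctx.store.writes)
    message_mark = len(ctx.messages)
    scheduled: list[str] = []
    if ctx.scheduler is not None:
        original = ctx.scheduler.schedule_task

        def tracking(task_id, *args, **kwargs):
            scheduled.append(task_id)
            return original(task_id, *args, **kwargs)
        ctx.scheduler.schedule_task = tracking
    try:
        for block in script.assess_blocks:
            try:
                execute(block.program, ctx)
            except PhitError as exc:
                raise type(exc)(f"domain {block.domain!r}: {exc}") from exc
    finally:
        if ctx.scheduler is not None:
            ctx.scheduler.schedule_task = original
    outcome.variables_written = dict(ctx.store.writes[write_mark:])
    outcome.tasks_scheduled = scheduled
    outcome.messages = list(ctx.messages[message_mark:])
    rules = list(script.alert_rules) + list(extra_alert_rules or [])
    outcome.alerts_raised = evaluate_risk_alerts(rules, ctx.store)
    for domain, message in outcome.alerts_raised:
        ctx.emit_message(f"RISK ALERT [{domain}]: {message}")
    return outcome
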