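"""App configuration: studies, protocols, and task resolution.

An app is a project holding one or more studies; each study holds one
or more protocols; each protocol names the instruments it administers
and may add an advisor and interventions.  Treatment arms are simply
different protocols over the same instrument pool — e.g. protocol A
runs the advisor and interventions while protocol B only collects data.

Task identifiers of the form ``a%b`` (intervention ``a``, section
``b``) resolve through the protocol's task map; every id any advisor
plan schedules must resolve at load time, never at run time.  File
paths are relative to the configuration file's directory so fixture
bundles stay portable.
"""
from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .advisor import AdvisorScript, parse_advisor
from .errors import ConfigError, DefinitionError
from .instrument import InstrumentDef, parse_instrument, validate_definition
from .logic import ast
from .logic.builtins import default_registry
from .scheduler import Scheduler, TaskEntry, parse_rrule, parse_start_spec


@dataclass
class TaskRef:
    task_id: str
    file: str
    title: str = ""
    icon_ref: str = ""
    menu_index: int = 0
    section: str = ""
    schedule_start: Optional[str] = None
    schedule_end: Optional[str] = None
    schedule_rrule: Optional[str] = None
    definition: Optional[InstrumentDef] = None


@dataclass
class TaskTarget:
    definition: InstrumentDef
    section: str = ""


@dataclass
class ProtocolConfig:
    protocol_id: str
    instrument_refs: list[TaskRef] = field(default_factory=list)
    intervention_refs: list[TaskRef] = field(default_factory=list)
    task_map: dict[str, TaskRef] = field(default_factory=dict)
    advisor_file: Optional[str] = None
    advisor: Optional[AdvisorScript] = None

    def all_refs(self) -> dict[str, TaskRef]:
        refs: dict[str, TaskRef] = {}
        for ref in self.instrument_refs + self.intervention_refs:
            refs[ref.task_id] = ref
        refs.update(self.task_map)
        return refs


@dataclass
class StudyConfig:
    study_id: str
    protocols: list[ProtocolConfig] = field(default_factory=list)

    def protocol(self, protocol_id: str) -> ProtocolConfig:
        for p in self.protocols:
            if p.protocol_id == protocol_id:
                return p
        raise ConfigError(f"unknown protocol {protocol_id!r} in study "
                          f"{self.study_id!r}")


@dataclass
class AppConfig:
    project_id: str
    studies: list[StudyConfig] = field(default_factory=list)

    def study(self, study_id: str) -> StudyConfig:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise ConfigError(f"unknown study {study_id!r}")


def _parse_task_ref(elem: ET.Element) -> TaskRef:
    task_id = elem.get("taskId") or elem.get("id") or ""
    file = elem.get("file", "")
    if not task_id or not file:
        raise ConfigError(
            f"<{elem.tag}> needs taskId (or id) and file attributes")
    ref = TaskRef(
        task_id=task_id, file=file,
        title=elem.get("title", ""), icon_ref=elem.get("icon", ""),
        menu_index=int(elem.get("menuIndex", "0")),
        section=elem.get("section", ""))
    schedule = elem.find("schedule")
    if schedule is not None:
        ref.schedule_start = schedule.get("start")
        ref.schedule_end = schedule.get("end")
        ref.schedule_rrule = schedule.get("rrule")
    return ref


def load_app_config(xml_text: str, base_dir: str = ".") -> AppConfig:
    """Parse an app configuration and eagerly load every referenced file.

    All cross-references (task ids scheduled by advisors, goto labels,
    called functions) are validated; a single :class:`ConfigError`
    lists every dangling reference found.
    """
    base = Path(base_dir)
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        line, col = exc.position
        raise ConfigError(
            f"malformed app config XML at line {line}, column {col}") from exc
    if root.tag != "app":
        raise ConfigError(f"expected <app> root, got <{root.tag}>")
    project_id = root.get("project", "")
    if not project_id:
        raise ConfigError("app config without a project id")
    config = AppConfig(project_id=project_id)
    for study_elem in root.findall("study"):
        study = StudyConfig(study_id=study_elem.get("id", ""))
        if not study.study_id:
            raise ConfigError("study without an id")
        for proto_elem in study_elem.findall("protocol"):
            study.protocols.append(_load_protocol(proto_elem, base))
        if not study.protocols:
            raise ConfigError(
                f"study {study.study_id!r} must contain at least one "
                f"protocol")
        study_ids = [p.protocol_id for p in study.protocols]
        if len(study_ids) != len(set(study_ids)):
            raise ConfigError(
                f"duplicate protocol ids in study {study.study_id!r}")
        config.studies.append(study)
    if not config.studies:
        raise ConfigError("app config must contain at least one study")
    ids = [s.study_id for s in config.studies]
    if len(ids) != len(set(ids)):
        raise ConfigError("duplicate study ids")
    _cross_validate(config)
    return config


def _load_protocol(elem: ET.Element, base: Path) -> ProtocolConfig:
    protocol = ProtocolConfig(protocol_id=elem.get("id", ""))
    if not protocol.protocol_id:
        raise ConfigError("protocol without an id")
    for child in elem:
        if child.tag in ("instrument", "intervention", "task"):
            ref = _parse_task_ref(child)
            try:
                ref.definition = parse_instrument(
                    (base / ref.file).read_text())
            except FileNotFoundError:
                raise ConfigError(
                    f"protocol {protocol.protocol_id!r}: file not found "
                    f"for task {ref.task_id!r}: {ref.file}")
            except DefinitionError as exc:
                raise ConfigError(
                    f"protocol {protocol.protocol_id!r}, task "
                    f"{ref.task_id!r}: {exc}") from exc
            if child.tag == "instrument":
                protocol.instrument_refs.append(ref)
            elif child.tag == "intervention":
                protocol.intervention_refs.append(ref)
            else:
                protocol.task_map[ref.task_id] = ref
        elif child.tag == "advisor":
            protocol.advisor_file = child.get("file", "")
            try:
                protocol.advisor = parse_advisor(
                    (base / protocol.advisor_file).read_text())
            except FileNotFoundError:
                raise ConfigError(
                    f"protocol {protocol.protocol_id!r}: advisor file "
                    f"not found: {protocol.advisor_file}")
        else:
            raise ConfigError(
                f"protocol {protocol.protocol_id!r}: unexpected element "
                f"<{child.tag}>")
    return protocol


def _scheduled_task_ids(program) -> list[str]:
    """Task ids scheduled with literal arguments (statically resolvable)."""
    ids = []

    def walk(statements):
        for stmt in statements:
            if isinstance(stmt, ast.Call) and \
                    stmt.fn.lower() in ("scheduletask", "hide", "show"):
                if stmt.args and isinstance(stmt.args[0], ast.Literal):
                    ids.append(stmt.args[0].text)
            elif isinstance(stmt, ast.If):
                walk([stmt.then])
            elif isinstance(stmt, (ast.While, ast.Block)):
                walk(stmt.statements if isinstance(stmt, ast.Block)
                     else stmt.body.statements)
    walk(program.statements)
    return ids


def _cross_validate(config: AppConfig) -> None:
    dangling: list[str] = []
    functions = default_registry().names()
    for study in config.studies:
        for protocol in study.protocols:
            refs = protocol.all_refs()
            known = set(refs)
            if protocol.advisor is not None:
                for block in protocol.advisor.assess_blocks:
                    for task_id in _scheduled_task_ids(block.program):
                        if task_id not in known:
                            dangling.append(
                                f"{study.study_id}/{protocol.protocol_id}: "
                                f"advisor domain {block.domain!r} schedules "
                                f"unknown task {task_id!r}")
            for ref in refs.values():
                if ref.definition is None:
                    continue
                for issue in validate_definition(ref.definition, functions):
                    dangling.append(
                        f"{study.study_id}/{protocol.protocol_id}/"
                        f"{ref.task_id}: {issue}")
    if dangling:
        raise ConfigError("unresolved references:\n  " +
                          "\n  ".join(dangling))


def resolve_task(protocol: ProtocolConfig, task_id: str) -> TaskTarget:
    """Look up a task id (including ``a%b`` forms) in the protocol."""
    ref = protocol.all_refs().get(task_id)
    if ref is None or ref.definition is None:
        raise ConfigError(
            f"protocol {protocol.protocol_id!r}: unknown task {task_id!r}")
    return TaskTarget(definition=ref.definition, section=ref.section)


def build_scheduler(protocol: ProtocolConfig, now=None) -> Scheduler:
    """Scheduler pre-registered with every task the protocol knows,
    with any config-declared schedule rules installed."""
    scheduler = Scheduler()
    for task_id, ref in protocol.all_refs().items():
        title = ref.title or (ref.definition.title if ref.definition else "")
        icon = ref.icon_ref or (ref.definition.icon_ref
                                if ref.definition else "")
        menu = ref.menu_index or (ref.definition.menu_index
                                  if ref.definition else 0)
        scheduler.add_task(TaskEntry(task_id=task_id, title=title,
                                     description=(ref.definition.description
                                                  if ref.definition else ""),
                                     icon_ref=icon, menu_index=menu))
        if ref.schedule_start:
            scheduler.schedule_task(task_id, ref.schedule_start,
                                    ref.schedule_end, ref.schedule_rrule,
                                    now=now)
    return scheduler
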