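"""Instrument definitions: parse the XML dialect into executable objects.

An *instrument* is one unit of data collection or intervention: an
ordered list of *forms* (screens), each holding *entities* (questions /
widgets) laid out in vertical/horizontal containers, plus logic blocks
attached to lifecycle events.  Background ("script") instruments have no
forms, only the instrument enter/exit events.

Two printed layout dialects are accepted and normalized: entities
directly under ``<form>``, or nested inside ``<vertical>`` /
``<horizontal>`` containers.  Either way the parsed form carries a
layout tree whose ``entityRef`` leaves, in document order, define the
data-entry order.
"""
from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Optional

from .errors import DefinitionError
from .logic import Program, parse_logic
from .errors import LexError, LogicParseError

ENTITY_TYPES = frozenset({
    "radio", "checkbox", "text", "likert", "date",
    "audioPlayback", "imageDisplay", "chart", "reactionTime",
})
CHOICE_TYPES = frozenset({"radio", "checkbox", "likert"})

EVENTS = frozenset({
    "onInstrumentEnter", "onInstrumentExit",
    "onFormEnter", "onFormExit", "onValueChanged", "onValidate",
})
SCRIPT_EVENTS = frozenset({"onInstrumentEnter", "onInstrumentExit"})


@dataclass
class LogicBlock:
    event: str
    scope: str                      # instrument | form | entity
    source: str
    program: Program


@dataclass
class ItemDef:
    code: str
    label: str


@dataclass
class LayoutNode:
    kind: str                       # vertical | horizontal | staticText | entityRef
    style_name: str = ""
    children: list["LayoutNode"] = field(default_factory=list)
    entity: str = ""                # entityRef leaves
    text: str = ""                  # staticText content
    name: str = ""                  # staticText optional name (for save)
    save: bool = False              # staticText only


@dataclass
class EntityDef:
    name: str
    type: str
    required: bool = False
    layout_hint: str = ""
    style_name: str = ""
    prompt: str = ""
    items: list[ItemDef] = field(default_factory=list)
    save: bool = True
    logic_blocks: list[LogicBlock] = field(default_factory=list)

    def codes(self) -> list[str]:
        return [item.code for item in self.items]

    def blocks(self, event: str) -> list[LogicBlock]:
        return [b for b in self.logic_blocks if b.event == event]


@dataclass
class FormDef:
    name: str
    title: str = ""
    layout: Optional[LayoutNode] = None
    entities: list[EntityDef] = field(default_factory=list)
    logic_blocks: list[LogicBlock] = field(default_factory=list)

    def entity(self, name: str) -> Optional[EntityDef]:
        for e in self.entities:
            if e.name == name:
                return e
        return None

    def blocks(self, event: str) -> list[LogicBlock]:
        return [b for b in self.logic_blocks if b.event == event]


@dataclass
class InstrumentDef:
    name: str
    title: str = ""
    description: str = ""
    icon_ref: str = ""
    menu_index: int = 0
    kind: str = "interactive"       # interactive | script
    forms: list[FormDef] = field(default_factory=list)
    logic_blocks: list[LogicBlock] = field(default_factory=list)

    def form(self, name: str) -> Optional[FormDef]:
        for f in self.forms:
            if f.name == name:
                return f
        return None

    def blocks(self, event: str) -> list[LogicBlock]:
        return [b for b in self.logic_blocks if b.event == event]


def qualified_name(instrument: str, entity: str) -> str:
    """Global variable name for an entity: ``<instrument>_<entity>``."""
    if not instrument or not entity:
        raise DefinitionError("instrument and entity names must be non-empty")
    return f"{instrument}_{entity}"


# --- parsing --------------------------------------------------------------

def _parse_bool(value: Optional[str], default: bool) -> bool:
    if value is None:
        return default
    return value == "true"


def _parse_logic_block(elem: ET.Element, scope: str, where: str) -> LogicBlock:
    event = elem.get("event", "")
    if event not in EVENTS:
        raise DefinitionError(f"{where}: unknown logic event {event!r}")
    source = elem.text or ""        # ElementTree unwraps CDATA transparently
    try:
        program = parse_logic(source)
    except (LexError, LogicParseError) as exc:
        raise DefinitionError(f"{where}: logic for {event} fails to parse: "
                              f"{exc}") from exc
    return LogicBlock(event=event, scope=scope, source=source, program=program)


def _parse_entity(elem: ET.Element, where: str) -> EntityDef:
    name = elem.get("name")
    if not name:
        raise DefinitionError(f"{where}: entity without a name")
    etype = elem.get("type", "")
    if etype not in ENTITY_TYPES:
        raise DefinitionError(
            f"{where}: entity {name!r} has unknown type {etype!r}")
    entity = EntityDef(
        name=name, type=etype,
        required=_parse_bool(elem.get("required"), False),
        layout_hint=elem.get("layout", ""),
        style_name=elem.get("styleName", ""),
        save=_parse_bool(elem.get("save"), True),
    )
    for child in elem:
        if child.tag == "text":
            entity.prompt = " ".join((child.text or "").split())
        elif child.tag == "item":
            code = child.get("code", "")
            if not code:
                raise DefinitionError(
                    f"{where}: entity {name!r} item with empty code")
            entity.items.append(ItemDef(code=code, label=child.text or ""))
        elif child.tag == "logic":
            entity.logic_blocks.append(
                _parse_logic_block(child, "entity", f"{where}/{name}"))
        else:
            raise DefinitionError(
                f"{where}: unexpected element <{child.tag}> in entity "
                f"{name!r}")
    if entity.type in CHOICE_TYPES and not entity.items:
        raise DefinitionError(
            f"{where}: {entity.type} entity {name!r} needs at least one item")
    codes = entity.codes()
    if len(codes) != len(set(codes)):
        raise DefinitionError(
            f"{where}: duplicate item codes in entity {name!r}")
    return entity


def _parse_layout(elem: ET.Element, form: FormDef, where: str) -> LayoutNode:
    if elem.tag in ("vertical", "horizontal"):
        node = LayoutNode(kind=elem.tag, style_name=elem.get("styleName", ""))
        for child in elem:
            node.children.append(_parse_layout(child, form, where))
        return node
    if elem.tag == "text":
        return LayoutNode(
            kind="staticText", style_name=elem.get("styleName", ""),
            text=" ".join((elem.text or "").split()),
            name=elem.get("name", ""),
            save=_parse_bool(elem.get("save"), False))
    if elem.tag == "entity":
        entity = _parse_entity(elem, where)
        form.entities.append(entity)
        return LayoutNode(kind="entityRef", entity=entity.name)
    raise DefinitionError(f"{where}: unexpected layout element <{elem.tag}>")


def _parse_form(elem: ET.Element, where: str) -> FormDef:
    name = elem.get("name")
    if not name:
        raise DefinitionError(f"{where}: form without a name")
    form = FormDef(name=name, title=elem.get("title", ""))
    root = LayoutNode(kind="vertical")
    for child in elem:
        if child.tag == "logic":
            form.logic_blocks.append(
                _parse_logic_block(child, "form", f"{where}/{name}"))
        else:
            root.children.append(
                _parse_layout(child, form, f"{where}/{name}"))
    form.layout = root
    return form


def parse_instrument(xml_text: str) -> InstrumentDef:
    """Parse instrument XML into an :class:`InstrumentDef`.

    Raises :class:`DefinitionError` for malformed XML (with line number),
    duplicate names, unknown entity types, or unparseable logic.
    """
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        line, col = exc.position
        raise DefinitionError(
            f"malformed XML at line {line}, column {col}: {exc}") from exc
    if root.tag != "instrument":
        raise DefinitionError(
            f"expected <instrument> root, got <{root.tag}>")
    name = root.get("name")
    if not name:
        raise DefinitionError("instrument without a name")
    try:
        menu_index = int(root.get("menuIndex", "0"))
    except ValueError:
        raise DefinitionError(f"{name}: menuIndex must be an integer")
    if menu_index < 0:
        raise DefinitionError(f"{name}: menuIndex must be >= 0")
    kind = root.get("kind", "interactive")
    if kind not in ("interactive", "script"):
        raise DefinitionError(f"{name}: unknown instrument kind {kind!r}")
    instrument = InstrumentDef(
        name=name, title=root.get("title", ""),
        description=root.get("description", ""),
        icon_ref=root.get("icon", ""), menu_index=menu_index, kind=kind)
    for child in root:
        if child.tag == "form":
            instrument.forms.append(_parse_form(child, name))
        elif child.tag == "logic":
            instrument.logic_blocks.append(
                _parse_logic_block(child, "instrument", name))
        else:
            raise DefinitionError(
                f"{name}: unexpected element <{child.tag}>")
    _check_invariants(instrument)
    return instrument


def _check_invariants(instrument: InstrumentDef) -> None:
    form_names = [f.name for f in instrument.forms]
    if len(form_names) != len(set(form_names)):
        raise DefinitionError(
            f"{instrument.name}: duplicate form names")
    entity_names = [e.name for f in instrument.forms for e in f.entities]
    if len(entity_names) != len(set(entity_names)):
        raise DefinitionError(
            f"{instrument.name}: duplicate entity names (entities key "
            f"global variables, so they must be unique per instrument)")
    if instrument.kind == "script":
        if instrument.forms:
            raise DefinitionError(
                f"{instrument.name}: script instruments may not have forms")
        for block in instrument.logic_blocks:
            if block.event not in SCRIPT_EVENTS:
                raise DefinitionError(
                    f"{instrument.name}: script instruments only support "
                    f"onInstrumentEnter/onInstrumentExit, not {block.event}")


# --- static validation ----------------------------------------------------

def _iter_programs(instrument: InstrumentDef):
    for block in instrument.logic_blocks:
        yield instrument.name, block
    for form in instrument.forms:
        for block in form.logic_blocks:
            yield f"{instrument.name}/{form.name}", block
        for entity in form.entities:
            for block in entity.logic_blocks:
                yield f"{instrument.name}/{form.name}/{entity.name}", block


def _walk_statements(statements):
    from .logic import ast
    for stmt in statements:
        yield stmt
        if isinstance(stmt, ast.If):
            yield from _walk_statements([stmt.then])
        elif isinstance(stmt, ast.While):
            yield from _walk_statements(stmt.body.statements)
        elif isinstance(stmt, ast.Block):
            yield from _walk_statements(stmt.statements)


def validate_definition(instrument: InstrumentDef,
                        known_functions: Optional[set[str]] = None
                        ) -> list[str]:
    """Cross-reference scan: returns a list of issue strings (empty = clean).

    Checks goto targets against form names, entity references in the
    layout tree, script-instrument event restrictions, and (when a
    function-name set is supplied) calls to unregistered functions.
    """
    from .logic import ast
    issues: list[str] = []
    form_names = {f.name for f in instrument.forms}
    for form in instrument.forms:
        referenced = _layout_entity_refs(form.layout)
        for entity in form.entities:
            if entity.name not in referenced:
                issues.append(
                    f"{form.name}: entity {entity.name!r} is not referenced "
                    f"by the layout tree")
    if instrument.kind == "script":
        for block in instrument.logic_blocks:
            if block.event not in SCRIPT_EVENTS:
                issues.append(
                    f"script instrument has a forbidden {block.event} block")
    if known_functions is not None:
        known = {n.lower() for n in known_functions}
    else:
        known = None
    for where, block in _iter_programs(instrument):
        for stmt in _walk_statements(block.program.statements):
            if isinstance(stmt, ast.Goto) and stmt.label not in form_names:
                issues.append(
                    f"{where}: goto {stmt.label!r} names no form")
            if known is not None:
                if isinstance(stmt, ast.Call) and stmt.fn.lower() not in known:
                    issues.append(
                        f"{where}: call to unregistered function {stmt.fn!r}")
                if isinstance(stmt, (ast.Set, ast.VarDecl)):
                    expr = stmt.expr
                    if isinstance(expr, ast.CallExpr) and \
                            expr.fn.lower() not in known:
                        issues.append(f"{where}: call to unregistered "
                                      f"function {expr.fn!r}")
    return issues


def _layout_entity_refs(node: Optional[LayoutNode]) -> list[str]:
    if node is None:
        return []
    if node.kind == "entityRef":
        return [node.entity]
    refs: list[str] = []
    for child in node.children:
        refs.extend(_layout_entity_refs(child))
    return refs


# --- serialization (round-trip support) -----------------------------------

def serialize(instrument: InstrumentDef) -> str:
    """Emit instrument XML that reparses to a structurally equal definition."""
    root = ET.Element("instrument", name=instrument.name, kind=instrument.kind)
    if instrument.title:
        root.set("title", instrument.title)
    if instrument.description:
        root.set("description", instrument.description)
    if instrument.icon_ref:
        root.set("icon", instrument.icon_ref)
    root.set("menuIndex", str(instrument.menu_index))
    for block in instrument.logic_blocks:
        _emit_logic(root, block)
    for form in instrument.forms:
        form_elem = ET.SubElement(root, "form", name=form.name)
        if form.title:
            form_elem.set("title", form.title)
        if form.layout is not None:
            for child in form.layout.children:
                _emit_layout(form_elem, child, form)
        for block in form.logic_blocks:
            _emit_logic(form_elem, block)
    return ET.tostring(root, encoding="unicode")


def _emit_logic(parent: ET.Element, block: LogicBlock) -> None:
    elem = ET.SubElement(parent, "logic", event=block.event)
    elem.text = block.source


def _emit_layout(parent: ET.Element, node: LayoutNode, form: FormDef) -> None:
    if node.kind in ("vertical", "horizontal"):
        elem = ET.SubElement(parent, node.kind)
        if node.style_name:
            elem.set("styleName", node.style_name)
        for child in node.children:
            _emit_layout(elem, child, form)
    elif node.kind == "staticText":
        elem = ET.SubElement(parent, "text")
        if node.name:
            elem.set("name", node.name)
        if node.save:
            elem.set("save", "true")
        if node.style_name:
            elem.set("styleName", node.style_name)
        elem.text = node.text
    elif node.kind == "entityRef":
        entity = form.entity(node.entity)
        elem = ET.SubElement(parent, "entity",
                             name=entity.name, type=entity.type)
        if entity.required:
            elem.set("required", "true")
        if entity.layout_hint:
            elem.set("layout", entity.layout_hint)
        if entity.style_name:
            elem.set("styleName", entity.style_name)
        if not entity.save:
            elem.set("save", "false")
        if entity.prompt:
            prompt = ET.SubElement(elem, "text")
            prompt.text = entity.prompt
        for item in entity.items:
            item_elem = ET.SubElement(elem, "item", code=item.code)
            item_elem.text = item.label
        for block in entity.logic_blocks:
            _emit_logic(elem, block)
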