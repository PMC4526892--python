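"""Evaluator for logic programs.

Evaluation semantics in brief:

* comparisons coerce both sides to numbers when both parse as numbers,
  otherwise compare text ordinally;
* ``+`` adds numerically when both operands are numeric, else
  concatenates; ``-`` requires numbers or two ISO dates (difference in
  days);
* ``&&``/``||`` short-circuit; truth is the string ``"true"``;
* control statements (``goto``/``nextForm``/``exit``) abort the rest of
  the program and surface as a :class:`Signal` for the session runner.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from ..context import EngineContext
from ..errors import RuntimeLogicError
from . import ast
from .values import FALSE, NULL, Value, from_bool, render_number

MAX_WHILE_ITERATIONS = 100_000

_INTERP_RE = re.compile(r"\{\s*([A-Za-z_][A-Za-z0-9_%.]*)\s*\}")


@dataclass(frozen=True)
class Signal:
    kind: str                 # normal | goto | nextForm | exit
    label: Optional[str] = None


NORMAL = Signal("normal")


def interpolate(template: str, store) -> str:
    """Replace every ``{name}`` in a literal with the store's raw value."""
    return _INTERP_RE.sub(lambda m: store.lookup(m.group(1)), template)


def coerce_compare(lhs: Value, op: str, rhs: Value) -> bool:
    """Numeric comparison when both sides are numbers, else ordinal text."""
    ln, rn = lhs.as_number(), rhs.as_number()
    if ln is not None and rn is not None:
        a, b = ln, rn
    else:
        a, b = lhs.raw, rhs.raw
    return {
        "==": a == b, "!=": a != b,
        "<": a < b, "<=": a <= b,
        ">": a > b, ">=": a >= b,
    }[op]


def evaluate(expr: ast.Expression, ctx: EngineContext) -> Value:
    if isinstance(expr, ast.Literal):
        return Value(interpolate(expr.text, ctx.store))
    if isinstance(expr, ast.Null):
        return NULL
    if isinstance(expr, ast.VarRef):
        return Value(ctx.store.lookup(expr.name))
    if isinstance(expr, ast.CallExpr):
        return _dispatch(expr.fn, expr.args, ctx)
    if isinstance(expr, ast.Binary):
        return _evaluate_binary(expr, ctx)
    raise RuntimeLogicError(f"cannot evaluate node {expr!r}")


def _evaluate_binary(expr: ast.Binary, ctx: EngineContext) -> Value:
    op = expr.op
    if op == "&&":
        if not evaluate(expr.lhs, ctx).as_bool():
            return FALSE          # short-circuit: rhs never evaluated
        return from_bool(evaluate(expr.rhs, ctx).as_bool())
    if op == "||":
        if evaluate(expr.lhs, ctx).as_bool():
            return from_bool(True)
        return from_bool(evaluate(expr.rhs, ctx).as_bool())

    lhs = evaluate(expr.lhs, ctx)
    rhs = evaluate(expr.rhs, ctx)
    if op in ("==", "!=", "<", "<=", ">", ">="):
        return from_bool(coerce_compare(lhs, op, rhs))
    if op == "+":
        ln, rn = lhs.as_number(), rhs.as_number()
        if ln is not None and rn is not None:
            return Value(render_number(ln + rn))
        return Value(lhs.raw + rhs.raw)
    if op == "-":
        ln, rn = lhs.as_number(), rhs.as_number()
        if ln is not None and rn is not None:
            return Value(render_number(ln - rn))
        ld, rd = lhs.as_date(), rhs.as_date()
        if ld is not None and rd is not None:
            return Value(str((ld - rd).days))
        raise RuntimeLogicError(
            f"operands of '-' are neither numbers nor ISO dates: "
            f"{lhs.raw!r}, {rhs.raw!r}")
    raise RuntimeLogicError(f"unknown operator {op!r}")


def _dispatch(fn: str, args: tuple[ast.Expression, ...],
              ctx: EngineContext) -> Value:
    impl = ctx.registry.resolve(fn)
    values = [evaluate(a, ctx) for a in args]
    return impl(ctx, values)


def execute(program: ast.Program, ctx: EngineContext) -> Signal:
    """Run a program; returns the control signal it finished with."""
    for stmt in program.statements:
        signal = _execute_stmt(stmt, ctx)
        if signal.kind != "normal":
            return signal
    return NORMAL


def _execute_stmt(stmt: ast.Statement, ctx: EngineContext) -> Signal:
    if isinstance(stmt, (ast.Set, ast.VarDecl)):
        target = stmt.target if isinstance(stmt, ast.Set) else stmt.name
        ctx.store.set(target, evaluate(stmt.expr, ctx).raw)
        return NORMAL
    if isinstance(stmt, ast.Call):
        _dispatch(stmt.fn, stmt.args, ctx)
        return NORMAL
    if isinstance(stmt, ast.If):
        if evaluate(stmt.cond, ctx).as_bool():
            return _execute_stmt(stmt.then, ctx)
        return NORMAL
    if isinstance(stmt, ast.Block):
        for inner in stmt.statements:
            signal = _execute_stmt(inner, ctx)
            if signal.kind != "normal":
                return signal
        return NORMAL
    if isinstance(stmt, ast.While):
        iterations = 0
        while evaluate(stmt.cond, ctx).as_bool():
            iterations += 1
            if iterations > MAX_WHILE_ITERATIONS:
                raise RuntimeLogicError(
                    f"while loop exceeded {MAX_WHILE_ITERATIONS} iterations")
            signal = _execute_stmt(stmt.body, ctx)
            if signal.kind != "normal":
                return signal
        return NORMAL
    if isinstance(stmt, ast.Goto):
        return Signal("goto", stmt.label)
    if isinstance(stmt, ast.NextForm):
        return Signal("nextForm")
    if isinstance(stmt, ast.Exit):
        return Signal("exit")
    raise RuntimeLogicError(f"cannot execute node {stmt!r}")
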