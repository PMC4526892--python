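"""AST node types for the logic language, plus an unparser.

Nodes are frozen dataclasses so structural equality comes for free; the
round-trip property (parse -> unparse -> parse is a fixed point) leans
on that.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

# --- expressions ----------------------------------------------------------


@dataclass(frozen=True)
class Literal:
    text: str


@dataclass(frozen=True)
class Null:
    pass


@dataclass(frozen=True)
class VarRef:
    name: str
    quoted: bool = False  # "{x}" (interpolating literal) vs bare {x}


@dataclass(frozen=True)
class Binary:
    op: str
    lhs: "Expression"
    rhs: "Expression"


@dataclass(frozen=True)
class CallExpr:
    fn: str
    args: tuple["Expression", ...]


Expression = Union[Literal, Null, VarRef, Binary, CallExpr]

# --- statements -----------------------------------------------------------


@dataclass(frozen=True)
class Set:
    target: str
    expr: Expression


@dataclass(frozen=True)
class VarDecl:
    name: str
    expr: Expression


@dataclass(frozen=True)
class Call:
    fn: str
    args: tuple[Expression, ...]


@dataclass(frozen=True)
class If:
    cond: Expression
    then: "Statement"


@dataclass(frozen=True)
class Goto:
    label: str


@dataclass(frozen=True)
class NextForm:
    pass


@dataclass(frozen=True)
class Exit:
    pass


@dataclass(frozen=True)
class While:
    cond: Expression
    body: "Block"


@dataclass(frozen=True)
class Block:
    statements: tuple["Statement", ...]


Statement = Union[Set, VarDecl, Call, If, Goto, NextForm, Exit, While, Block]


@dataclass(frozen=True)
class Program:
    statements: tuple[Statement, ...] = field(default_factory=tuple)


# --- unparser -------------------------------------------------------------

def unparse_expr(expr: Expression) -> str:
    if isinstance(expr, Literal):
        return f'"{expr.text}"'
    if isinstance(expr, Null):
        return "null"
    if isinstance(expr, VarRef):
        return f'"{{{expr.name}}}"' if expr.quoted else f"{{{expr.name}}}"
    if isinstance(expr, Binary):
        return f"({unparse_expr(expr.lhs)} {expr.op} {unparse_expr(expr.rhs)})"
    if isinstance(expr, CallExpr):
        args = ", ".join(unparse_expr(a) for a in expr.args)
        return f"call {expr.fn}({args})"
    raise TypeError(f"not an expression: {expr!r}")


def unparse_stmt(stmt: Statement) -> str:
    if isinstance(stmt, Set):
        return f"set {{{stmt.target}}} = {unparse_expr(stmt.expr)};"
    if isinstance(stmt, VarDecl):
        return f"var {{{stmt.name}}} = {unparse_expr(stmt.expr)};"
    if isinstance(stmt, Call):
        args = ", ".join(unparse_expr(a) for a in stmt.args)
        return f"call {stmt.fn}({args});"
    if isinstance(stmt, If):
        return f"if ({unparse_expr(stmt.cond)}) then {unparse_stmt(stmt.then)}"
    if isinstance(stmt, Goto):
        return f"goto {stmt.label};"
    if isinstance(stmt, NextForm):
        return "nextForm;"
    if isinstance(stmt, Exit):
        return "exit;"
    if isinstance(stmt, While):
        return f"while ({unparse_expr(stmt.cond)}) {unparse_stmt(stmt.body)}"
    if isinstance(stmt, Block):
        inner = " ".join(unparse_stmt(s) for s in stmt.statements)
        return f"begin; {inner} end;"
    raise TypeError(f"not a statement: {stmt!r}")


def unparse(program: Program) -> str:
    return "\n".join(unparse_stmt(s) for s in program.statements)
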