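"""Recursive-descent parser for the logic language.

Grammar (statements end with ";", including "begin;" and "end;"):

    stmt     := set {v} = rhs ;   | var {v} = rhs ;
              | call fn ( args ) ;
              | if ( expr ) then stmt
              | while ( expr ) block
              | begin ; stmt* end ;
              | goto IDENT ;      | nextForm ;      | exit ;
    rhs      := call fn ( args ) | expr
    expr     := or ; or := and (|| and)* ; and := cmp (&& cmp)*
    cmp      := add ((==|!=|<|<=|>|>=) add)?
    add      := primary ((+|-) primary)*
    primary  := STRING | NUMBER | {var} | null | ( expr )

Operator precedence, loosest to tightest: ``||``, ``&&``, comparisons,
``+``/``-``.  A string literal that is exactly one ``{name}`` is treated
as a quoted variable reference; any other string interpolates embedded
``{name}`` occurrences at evaluation time.
"""
from __future__ import annotations

import re

from ..errors import LogicParseError
from . import ast
from .lexer import Token, tokenize

_ONLY_VARREF_RE = re.compile(r"^\{\s*([A-Za-z_][A-Za-z0-9_%.]*)\s*\}$")

_COMPARISONS = {"==", "!=", "<", "<=", ">", ">="}


class _Parser:
    def __init__(self, tokens: list[Token]):
        self.tokens = tokens
        self.i = 0
        self.stmt_index = 0  # for error messages

    # token helpers ------------------------------------------------------
    def _peek(self) -> Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self) -> Token:
        tok = self._peek()
        if tok is None:
            self._fail("unexpected end of script")
        self.i += 1
        return tok

    def _expect(self, kind: str, value: str | None = None) -> Token:
        tok = self._next()
        if tok.kind != kind or (value is not None and tok.value != value):
            want = value or kind
            self._fail(f"expected {want!r}, got {tok.value!r}")
        return tok

    def _at(self, kind: str, value: str) -> bool:
        tok = self._peek()
        return tok is not None and tok.kind == kind and tok.value == value

    def _fail(self, msg: str):
        raise LogicParseError(f"statement {self.stmt_index}: {msg}")

    # statements ---------------------------------------------------------
    def parse_program(self) -> ast.Program:
        statements = []
        while self._peek() is not None:
            self.stmt_index = len(statements)
            statements.append(self.parse_statement())
        return ast.Program(tuple(statements))

    def parse_statement(self) -> ast.Statement:
        tok = self._peek()
        if tok is None:
            self._fail("unexpected end of script")
        if tok.kind == "keyword":
            handler = {
                "set": self._parse_set, "var": self._parse_var,
                "call": self._parse_call_stmt, "if": self._parse_if,
                "while": self._parse_while, "begin": self._parse_block,
                "goto": self._parse_goto,
                "nextForm": self._parse_nextform, "exit": self._parse_exit,
            }.get(tok.value)
            if handler:
                return handler()
        self._fail(f"cannot start a statement with {tok.value!r}")

    def _parse_set(self) -> ast.Set:
        self._expect("keyword", "set")
        target = self._expect("varref").value
        self._expect("op", "=")
        expr = self._parse_rhs()
        self._expect("punct", ";")
        return ast.Set(target, expr)

    def _parse_var(self) -> ast.VarDecl:
        self._expect("keyword", "var")
        name = self._expect("varref").value
        self._expect("op", "=")
        expr = self._parse_rhs()
        self._expect("punct", ";")
        return ast.VarDecl(name, expr)

    def _parse_rhs(self) -> ast.Expression:
        if self._at("keyword", "call"):
            return self._parse_call_expr()
        return self.parse_expression()

    def _parse_call_expr(self) -> ast.CallExpr:
        self._expect("keyword", "call")
        fn = self._expect("ident").value
        args = self._parse_arg_list()
        return ast.CallExpr(fn, args)

    def _parse_call_stmt(self) -> ast.Call:
        expr = self._parse_call_expr()
        self._expect("punct", ";")
        return ast.Call(expr.fn, expr.args)

    def _parse_arg_list(self) -> tuple[ast.Expression, ...]:
        self._expect("punct", "(")
        args: list[ast.Expression] = []
        if not self._at("punct", ")"):
            args.append(self.parse_expression())
            while self._at("punct", ","):
                self._next()
                args.append(self.parse_expression())
        self._expect("punct", ")")
        return tuple(args)

    def _parse_if(self) -> ast.If:
        self._expect("keyword", "if")
        self._expect("punct", "(")
        cond = self.parse_expression()
        self._expect("punct", ")")
        if not self._at("keyword", "then"):
            self._fail("missing 'then' after if condition")
        self._next()
        return ast.If(cond, self.parse_statement())

    def _parse_while(self) -> ast.While:
        self._expect("keyword", "while")
        self._expect("punct", "(")
        cond = self.parse_expression()
        self._expect("punct", ")")
        body = self.parse_statement()
        if not isinstance(body, ast.Block):
            body = ast.Block((body,))
        return ast.While(cond, body)

    def _parse_block(self) -> ast.Block:
        self._expect("keyword", "begin")
        self._expect("punct", ";")
        statements = []
        while not self._at("keyword", "end"):
            if self._peek() is None:
                self._fail("unbalanced begin: missing 'end;'")
            statements.append(self.parse_statement())
        self._expect("keyword", "end")
        self._expect("punct", ";")
        return ast.Block(tuple(statements))

    def _parse_goto(self) -> ast.Goto:
        self._expect("keyword", "goto")
        label = self._expect("ident").value
        self._expect("punct", ";")
        return ast.Goto(label)

    def _parse_nextform(self) -> ast.NextForm:
        self._expect("keyword", "nextForm")
        self._expect("punct", ";")
        return ast.NextForm()

    def _parse_exit(self) -> ast.Exit:
        self._expect("keyword", "exit")
        self._expect("punct", ";")
        return ast.Exit()

    # expressions --------------------------------------------------------
    def parse_expression(self) -> ast.Expression:
        return self._parse_or()

    def _parse_or(self) -> ast.Expression:
        node = self._parse_and()
        while self._at("op", "||"):
            self._next()
            node = ast.Binary("||", node, self._parse_and())
        return node

    def _parse_and(self) -> ast.Expression:
        node = self._parse_cmp()
        while self._at("op", "&&"):
            self._next()
            node = ast.Binary("&&", node, self._parse_cmp())
        return node

    def _parse_cmp(self) -> ast.Expression:
        node = self._parse_add()
        tok = self._peek()
        if tok is not None and tok.kind == "op" and tok.value in _COMPARISONS:
            self._next()
            node = ast.Binary(tok.value, node, self._parse_add())
        return node

    def _parse_add(self) -> ast.Expression:
        node = self._parse_primary()
        while True:
            tok = self._peek()
            if tok is not None and tok.kind == "op" and tok.value in ("+", "-"):
                self._next()
                node = ast.Binary(tok.value, node, self._parse_primary())
            else:
                return node

    def _parse_primary(self) -> ast.Expression:
        tok = self._next()
        if tok.kind == "string":
            m = _ONLY_VARREF_RE.match(tok.value)
            if m:
                return ast.VarRef(m.group(1), quoted=True)
            return ast.Literal(tok.value)
        if tok.kind == "number":
            return ast.Literal(tok.value)
        if tok.kind == "varref":
            return ast.VarRef(tok.value, quoted=False)
        if tok.kind == "keyword" and tok.value == "null":
            return ast.Null()
        if tok.kind == "keyword" and tok.value == "call":
            self.i -= 1          # call f(...) usable as a primary too
            return self._parse_call_expr()
        if tok.kind == "punct" and tok.value == "(":
            node = self.parse_expression()
            self._expect("punct", ")")
            return node
        self._fail(f"unexpected token {tok.value!r} in expression")


def parse_logic(source: str) -> ast.Program:
    """Parse a logic script into a :class:`Program`."""
    return _Parser(tokenize(source)).parse_program()
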