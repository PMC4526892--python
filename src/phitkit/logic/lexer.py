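"""Tokenizer for the logic language.

The language is line-noise tolerant by design: authors write it inside
CDATA blocks, often pasted from word processors, so typographic quotes
are normalized to ASCII and whitespace inside ``{variable}`` braces is
trimmed before the name is taken.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

from ..errors import LexError

KEYWORDS = {
    "set", "var", "call", "if", "then", "begin", "end",
    "goto", "while", "nextForm", "exit", "null",
}

# two-char operators must be matched before their one-char prefixes
_OPERATORS = ("==", "!=", "<=", ">=", "&&", "||", "<", ">", "+", "-", "=")

_QUOTE_MAP = str.maketrans({"“": '"', "”": '"',
                            "‘": "'", "’": "'"})

_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_%.]*")
_NUMBER_RE = re.compile(r"\d+(?:\.\d+)?")


@dataclass(frozen=True)
class Token:
    kind: str        # keyword | ident | varref | string | number | op | punct
    value: str
    pos: int         # character offset in the (normalized) source


def _strip_comments(source: str) -> str:
    # `//` to end of line; quotes never span lines so no string-aware scan
    # is needed for the printed dialect, but we keep one to be safe.
    out = []
    for line in source.splitlines():
        i, in_str = 0, False
        while i < len(line):
            ch = line[i]
            if ch == '"':
                in_str = not in_str
            elif ch == "/" and not in_str and line[i:i + 2] == "//":
                line = line[:i]
                break
            i += 1
        out.append(line)
    return "\n".join(out)


def tokenize(source: str) -> list[Token]:
    """Tokenize a logic script; raises :class:`LexError` with the offset."""
    text = _strip_comments(source.translate(_QUOTE_MAP))
    tokens: list[Token] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == '"':
            end = text.find('"', i + 1)
            if end < 0:
                raise LexError(f"unterminated string at offset {i}")
            tokens.append(Token("string", text[i + 1:end], i))
            i = end + 1
            continue
        if ch == "{":
            end = text.find("}", i + 1)
            if end < 0:
                raise LexError(f"unterminated variable reference at offset {i}")
            name = text[i + 1:end].strip()
            if not name:
                raise LexError(f"empty variable reference at offset {i}")
            tokens.append(Token("varref", name, i))
            i = end + 1
            continue
        if ch in "();,":
            tokens.append(Token("punct", ch, i))
            i += 1
            continue
        for op in _OPERATORS:
            if text.startswith(op, i):
                tokens.append(Token("op", op, i))
                i += len(op)
                break
        else:
            m = _NUMBER_RE.match(text, i)
            if m:
                tokens.append(Token("number", m.group(), i))
                i = m.end()
                continue
            m = _IDENT_RE.match(text, i)
            if m:
                word = m.group()
                kind = "keyword" if word in KEYWORDS else "ident"
                tokens.append(Token(kind, word, i))
                i = m.end()
                continue
            raise LexError(f"unexpected character {ch!r} at offset {i}")
    return tokens
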