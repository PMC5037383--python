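"""Textual syntax for logic rules.

Rules are written as nested prefix expressions, e.g.

    not(or(near(2,5,3.0), near(3,6,3.0)))

where ``near(i, j, R)`` is the elementary proximity predicate on
particles ``i`` and ``j`` with threshold ``R`` (``inf`` allowed),
``and``/``or`` take two or more operands, ``not`` takes one, and the
bare constants ``0`` / ``1`` are allowed.  :func:`format_logic` is the
exact inverse of :func:`parse_logic`.
"""

from __future__ import annotations

import re

from .logic import And, Const, Expr, Near, Not, Or, pair

__all__ = ["parse_logic", "format_logic", "RuleSyntaxError"]


class RuleSyntaxError(ValueError):
    """Malformed rule text."""


_TOKEN = re.compile(
    r"\s*(?:(?P<name>[A-Za-z_]+)|(?P<num>[-+]?\d+(?:\.\d*)?(?:[eE][-+]?\d+)?)"
    r"|(?P<punct>[(),]))"
)


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.end() == pos:
            if text[pos:].strip():
                raise RuleSyntaxError(
                    f"unexpected character {text[pos]!r} at offset {pos} in rule {text!r}"
                )
            break
        tokens.append(m.group().strip())
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str) -> None:
        self.text = text
        self.tokens = _tokenize(text)
        self.k = 0

    def peek(self) -> str | None:
        return self.tokens[self.k] if self.k < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise RuleSyntaxError(f"unexpected end of rule {self.text!r}")
        self.k += 1
        return tok

    def expect(self, tok: str) -> None:
        got = self.next()
        if got != tok:
            raise RuleSyntaxError(
                f"expected {tok!r} but found {got!r} in rule {self.text!r}"
            )

    def parse(self) -> Expr:
        expr = self.expr()
        if self.peek() is not None:
            raise RuleSyntaxError(
                f"trailing tokens {self.tokens[self.k:]} in rule {self.text!r}"
            )
        return expr

    def expr(self) -> Expr:
        tok = self.next().lower()
        if tok in ("0", "1"):
            return Const(int(tok))
        if tok == "not":
            self.expect("(")
            inner = self.expr()
            self.expect(")")
            return Not(inner)
        if tok in ("and", "or"):
            self.expect("(")
            terms = [self.expr()]
            while self.peek() == ",":
                self.next()
                terms.append(self.expr())
            self.expect(")")
            if len(terms) < 2:
                raise RuleSyntaxError(f"{tok} needs at least two operands")
            return And(tuple(terms)) if tok == "and" else Or(tuple(terms))
        if tok == "near":
            self.expect("(")
            i = self.int_tok()
            self.expect(",")
            j = self.int_tok()
            self.expect(",")
            R = self.num_tok()
            self.expect(")")
            return Near(pair(i, j), R)
        raise RuleSyntaxError(f"unknown rule operator {tok!r} in {self.text!r}")

    def int_tok(self) -> int:
        tok = self.next()
        try:
            return int(tok)
        except ValueError:
            raise RuleSyntaxError(
                f"expected a particle id, found {tok!r} in rule {self.text!r}"
            ) from None

    def num_tok(self) -> float:
        tok = self.next()
        if tok.lower() == "inf":
            return float("inf")
        try:
            return float(tok)
        except ValueError:
            raise RuleSyntaxError(
                f"expected a threshold, found {tok!r} in rule {self.text!r}"
            ) from None


def parse_logic(text: str) -> Expr:
    """Parse a prefix rule expression into a logic tree."""
    return _Parser(text).parse()


def format_logic(expr: Expr) -> str:
    """Serialize a logic tree back to rule text (inverse of parsing)."""
    if isinstance(expr, Const):
        return str(expr.value)
    if isinstance(expr, Near):
        R = "inf" if expr.R == float("inf") else repr(expr.R)
        return f"near({expr.pair.i},{expr.pair.j},{R})"
    if isinstance(expr, Not):
        return f"not({format_logic(expr.term)})"
    if isinstance(expr, And):
        return "and(" + ", ".join(format_logic(t) for t in expr.terms) + ")"
    if isinstance(expr, Or):
        return "or(" + ", ".join(format_logic(t) for t in expr.terms) + ")"
    raise TypeError(f"cannot serialize node {expr!r}")
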