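"""Arithmetic expressions over parameter labels.

User-defined parameters such as the indirect effect ``ab := a*b`` or the
index of moderated mediation ``ind.diff := ind.w1 - ind.w0`` are arithmetic
functions of estimated path coefficients.  The grammar is deliberately small:
``+``, ``-`` (binary and unary), ``*``, parentheses, numeric literals and
identifiers.  Identifiers may contain dots (``a.w0``), which is the common
naming convention for simple effects and their moderated counterparts, so
expressions are parsed here rather than through a general-purpose parser.

Expressions evaluate against a mapping from label to value; values may be
scalars or numpy arrays (the Monte Carlo CI draws evaluate an expression on
20,000 parameter draws at once).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["DefinedParameter", "Expression", "parse_expression", "parse_definition"]

_TOKEN = re.compile(
    r"\s*(?:(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_.]*)"
    r"|(?P<op>[-+*()]))"
)


class ExpressionError(ValueError):
    """Raised for malformed expressions or unresolved labels."""


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ExpressionError(f"unexpected character {text[pos]!r} in {text!r}")
        pos = m.end()
        for kind in ("num", "name", "op"):
            if m.group(kind) is not None:
                tokens.append((kind, m.group(kind)))
                break
    return tokens


# AST nodes: ("num", float) | ("name", str) | ("neg", node) | (op, left, right)


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]], text: str):
        self.tokens = tokens
        self.text = text
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None)

    def take(self):
        tok = self.peek()
        self.i += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.i != len(self.tokens):
            raise ExpressionError(f"trailing input in expression {self.text!r}")
        return node

    def expr(self):
        # additive level
        node = self.term()
        while self.peek() == ("op", "+") or self.peek() == ("op", "-"):
            _, op = self.take()
            node = (op, node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek() == ("op", "*"):
            self.take()
            node = ("*", node, self.factor())
        return node

    def factor(self):
        kind, val = self.take()
        if kind == "num":
            return ("num", float(val))
        if kind == "name":
            return ("name", val)
        if (kind, val) == ("op", "-"):
            return ("neg", self.factor())
        if (kind, val) == ("op", "+"):
            return self.factor()
        if (kind, val) == ("op", "("):
            node = self.expr()
            if self.take() != ("op", ")"):
                raise ExpressionError(f"unbalanced parentheses in {self.text!r}")
            return node
        raise ExpressionError(f"unexpected token in expression {self.text!r}")


def _names(node, out: set[str]) -> None:
    tag = node[0]
    if tag == "name":
        out.add(node[1])
    elif tag == "neg":
        _names(node[1], out)
    elif tag in ("+", "-", "*"):
        _names(node[1], out)
        _names(node[2], out)


def _eval(node, env: Mapping[str, object]):
    tag = node[0]
    if tag == "num":
        return node[1]
    if tag == "name":
        try:
            return env[node[1]]
        except KeyError:
            raise ExpressionError(f"unresolved label {node[1]!r}") from None
    if tag == "neg":
        return -_eval(node[1], env)
    a, b = _eval(node[1], env), _eval(node[2], env)
    if tag == "+":
        return a + b
    if tag == "-":
        return a - b
    return a * b


@dataclass(frozen=True)
class Expression:
    """A parsed arithmetic expression over parameter labels."""

    text: str
    _ast: tuple = field(repr=False)

    @property
    def names(self) -> frozenset[str]:
        out: set[str] = set()
        _names(self._ast, out)
        return frozenset(out)

    def evaluate(self, env: Mapping[str, object]):
        """Evaluate with label values from ``env`` (scalars or arrays)."""
        return _eval(self._ast, env)

    def gradient(self, env: Mapping[str, float], labels: Sequence[str],
                 rel_step: float = 1e-6) -> np.ndarray:
        """Central finite-difference gradient with respect to ``labels``.

        Step size is ``rel_step * max(1, |value|)`` per coordinate.
        """
        base = {k: float(env[k]) for k in env}
        g = np.empty(len(labels))
        for i, lab in enumerate(labels):
            h = rel_step * max(1.0, abs(base.get(lab, 0.0)))
            up = dict(base)
            dn = dict(base)
            up[lab] = base[lab] + h
            dn[lab] = base[lab] - h
            g[i] = (_eval(self._ast, up) - _eval(self._ast, dn)) / (2 * h)
        return g


def parse_expression(text: str) -> Expression:
    ast = _Parser(_tokenize(text), text).parse()
    return Expression(text=text, _ast=ast)


@dataclass(frozen=True)
class DefinedParameter:
    """A named function of model parameters, e.g. ``ab := a*b``.

    Definitions may reference earlier definitions (``ind.diff`` built from
    ``ind.w1`` and ``ind.w0``); resolution order is the declaration order.
    """

    name: str
    expression: Expression

    @classmethod
    def from_string(cls, definition: str) -> "DefinedParameter":
        if ":=" not in definition:
            raise ExpressionError(
                f"definition {definition!r} must use 'name := expression'")
        name, _, rhs = definition.partition(":=")
        name = name.strip()
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.]*", name):
            raise ExpressionError(f"invalid defined-parameter name {name!r}")
        return cls(name=name, expression=parse_expression(rhs.strip()))


def resolve_defined(defined: Sequence[DefinedParameter],
                    env: Mapping[str, object]) -> dict[str, object]:
    """Evaluate a list of definitions in order, allowing chaining.

    ``env`` holds the values of estimated labels; the returned dict holds the
    defined values only.
    """
    scope = dict(env)
    out: dict[str, object] = {}
    for d in defined:
        if d.name in scope:
            raise ExpressionError(f"duplicate defined name {d.name!r}")
        val = d.expression.evaluate(scope)
        scope[d.name] = val
        out[d.name] = val
    return out


def expand_labels(defined: Sequence[DefinedParameter]) -> dict[str, frozenset[str]]:
    """Map each defined name to the set of underlying estimated labels it uses,
    expanding through chained definitions."""
    known: dict[str, frozenset[str]] = {}
    for d in defined:
        base: set[str] = set()
        for nm in d.expression.names:
            base |= known.get(nm, frozenset({nm}))
        known[d.name] = frozenset(base)
    return known
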