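"""Gene-protein-reaction (GPR) Boolean expressions over functional-role strings.

A GPR decides whether a template reaction is included in a genome's core model.
Leaves are RAST-style functional-role strings, written double-quoted because
role names themselves contain parentheses and commas, e.g.::

    "6-phosphofructokinase (EC 2.7.1.11)" or "6-phosphofructokinase class II (EC 2.7.1.11)"
    ("ATP synthase alpha chain (EC 3.6.3.14)" and "ATP synthase beta chain (EC 3.6.3.14)")

``and`` / ``or`` are case-insensitive; ``and`` binds tighter than ``or``.
Role matching is exact string equality after whitespace/case normalization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Union

__all__ = ["GprError", "parse_gpr", "normalize_role", "GprExpr", "Role", "And", "Or"]


class GprError(ValueError):
    """Raised on a malformed GPR expression."""


def normalize_role(role: str) -> str:
    """Collapse whitespace and lowercase — the role-equality convention."""
    return re.sub(r"\s+", " ", role.strip()).lower()


@dataclass(frozen=True)
class Role:
    name: str  # normalized

    def evaluate(self, roles: frozenset[str]) -> bool:
        return self.name in roles

    def leaves(self) -> set[str]:
        return {self.name}

    def unparse(self) -> str:
        return f'"{self.name}"'


@dataclass(frozen=True)
class And:
    terms: tuple["GprExpr", ...]

    def evaluate(self, roles: frozenset[str]) -> bool:
        return all(t.evaluate(roles) for t in self.terms)

    def leaves(self) -> set[str]:
        return set().union(*(t.leaves() for t in self.terms))

    def unparse(self) -> str:
        return "(" + " and ".join(t.unparse() for t in self.terms) + ")"


@dataclass(frozen=True)
class Or:
    terms: tuple["GprExpr", ...]

    def evaluate(self, roles: frozenset[str]) -> bool:
        return any(t.evaluate(roles) for t in self.terms)

    def leaves(self) -> set[str]:
        return set().union(*(t.leaves() for t in self.terms))

    def unparse(self) -> str:
        return "(" + " or ".join(t.unparse() for t in self.terms) + ")"


GprExpr = Union[Role, And, Or]

_TOKENIZER = re.compile(r'\s*(?:("(?:[^"\\]|\\.)*")|(\()|(\))|(\b[Aa][Nn][Dd]\b)|(\b[Oo][Rr]\b))')


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKENIZER.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise GprError(f"unexpected token in GPR at position {pos}: {text[pos:pos + 30]!r}")
        quoted, lpar, rpar, and_, or_ = m.groups()
        if quoted is not None:
            tokens.append(quoted)
        elif lpar:
            tokens.append("(")
        elif rpar:
            tokens.append(")")
        elif and_:
            tokens.append("and")
        elif or_:
            tokens.append("or")
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GprError("unexpected end of GPR expression")
        self.pos += 1
        return tok

    def parse_or(self) -> GprExpr:
        terms = [self.parse_and()]
        while self.peek() == "or":
            self.take()
            terms.append(self.parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and(self) -> GprExpr:
        terms = [self.parse_atom()]
        while self.peek() == "and":
            self.take()
            terms.append(self.parse_atom())
        return terms[0] if len(terms) == 1 else And(tuple(terms))

    def parse_atom(self) -> GprExpr:
        tok = self.take()
        if tok == "(":
            expr = self.parse_or()
            if self.take() != ")":
                raise GprError("missing closing parenthesis in GPR")
            return expr
        if tok.startswith('"'):
            raw = tok[1:-1].replace('\\"', '"')
            return Role(normalize_role(raw))
        raise GprError(f"expected role or '(' in GPR, got {tok!r}")


def parse_gpr(text: str) -> GprExpr:
    """Parse a GPR expression string into an evaluable tree."""
    tokens = _tokenize(text)
    if not tokens:
        raise GprError("empty GPR expression")
    parser = _Parser(tokens)
    expr = parser.parse_or()
    if parser.peek() is not None:
        raise GprError(f"trailing tokens in GPR: {parser.tokens[parser.pos:]}")
    return expr


def evaluate_gpr(expr: GprExpr, roles: Iterable[str]) -> bool:
    """Evaluate a parsed GPR against an iterable of (raw) role strings."""
    normalized = frozenset(normalize_role(r) for r in roles)
    return expr.evaluate(normalized)
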