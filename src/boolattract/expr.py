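"""Boolean expression trees over named variables.

The rule dialect uses ``!`` (NOT), ``&`` (AND), ``|`` (OR), the constants
``0``/``1``, identifiers and parentheses.  Evaluation is vectorised:
variables may be bound to numpy boolean arrays (one entry per state of the
network), in which case the whole expression is evaluated elementwise over
every state at once.  Scalar Python bools work too.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from functools import reduce
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "BoolExpr",
    "Const",
    "Var",
    "Not",
    "And",
    "Or",
    "ExprSyntaxError",
    "parse_expr",
    "expr_from_truth_table",
]


class ExprSyntaxError(ValueError):
    """Raised when a Boolean expression cannot be tokenised or parsed."""


class BoolExpr:
    """Base class for expression nodes (immutable)."""

    __slots__ = ()
    _prec = 4  # atoms bind tightest; Or=1, And=2, Not=3

    def evaluate(self, env: Mapping[str, object]):
        raise NotImplementedError

    def variables(self) -> Iterator[str]:
        """Yield variable names (with repetition) appearing in the expression."""
        return iter(())

    def _child_str(self, child: "BoolExpr") -> str:
        text = str(child)
        return f"({text})" if child._prec < self._prec else text


@dataclass(frozen=True)
class Const(BoolExpr):
    value: bool

    def evaluate(self, env):
        return self.value

    def __str__(self) -> str:
        return "1" if self.value else "0"


@dataclass(frozen=True)
class Var(BoolExpr):
    name: str

    def evaluate(self, env):
        return env[self.name]

    def variables(self):
        yield self.name

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Not(BoolExpr):
    operand: BoolExpr
    _prec = 3

    def evaluate(self, env):
        return np.logical_not(self.operand.evaluate(env))

    def variables(self):
        yield from self.operand.variables()

    def __str__(self) -> str:
        return "!" + self._child_str(self.operand)


@dataclass(frozen=True)
class And(BoolExpr):
    operands: tuple[BoolExpr, ...]
    _prec = 2

    def evaluate(self, env):
        return reduce(np.logical_and, (o.evaluate(env) for o in self.operands))

    def variables(self):
        for o in self.operands:
            yield from o.variables()

    def __str__(self) -> str:
        return " & ".join(self._child_str(o) for o in self.operands)


@dataclass(frozen=True)
class Or(BoolExpr):
    operands: tuple[BoolExpr, ...]
    _prec = 1

    def evaluate(self, env):
        return reduce(np.logical_or, (o.evaluate(env) for o in self.operands))

    def variables(self):
        for o in self.operands:
            yield from o.variables()

    def __str__(self) -> str:
        return " | ".join(self._child_str(o) for o in self.operands)


_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<lpar>\() |
        (?P<rpar>\)) |
        (?P<neg>!)   |
        (?P<conj>&)  |
        (?P<disj>\|) |
        (?P<const>[01])(?![A-Za-z0-9_]) |
        (?P<ident>[A-Za-z_][A-Za-z0-9_.]*)
    )""",
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            rest = text[pos:].strip()
            if not rest:
                break
            raise ExprSyntaxError(f"unexpected character {rest[0]!r} in expression {text.strip()!r}")
        tokens.append((m.lastgroup, m.group(m.lastgroup)))  # type: ignore[arg-type]
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser; precedence NOT > AND > OR."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def advance(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> BoolExpr:
        expr = self.parse_or()
        if self.pos != len(self.tokens):
            kind, value = self.peek()
            raise ExprSyntaxError(f"trailing token {value!r} in expression {self.text.strip()!r}")
        return expr

    def parse_or(self) -> BoolExpr:
        parts = [self.parse_and()]
        while self.peek()[0] == "disj":
            self.advance()
            parts.append(self.parse_and())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def parse_and(self) -> BoolExpr:
        parts = [self.parse_unary()]
        while self.peek()[0] == "conj":
            self.advance()
            parts.append(self.parse_unary())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_unary(self) -> BoolExpr:
        kind, value = self.peek()
        if kind == "neg":
            self.advance()
            return Not(self.parse_unary())
        return self.parse_atom()

    def parse_atom(self) -> BoolExpr:
        kind, value = self.advance()
        if kind == "lpar":
            inner = self.parse_or()
            kind, value = self.advance()
            if kind != "rpar":
                raise ExprSyntaxError(f"missing ')' in expression {self.text.strip()!r}")
            return inner
        if kind == "const":
            return Const(value == "1")
        if kind == "ident":
            return Var(value)
        raise ExprSyntaxError(f"expected an operand in expression {self.text.strip()!r}")


def parse_expr(text: str) -> BoolExpr:
    """Parse a Boolean expression in the ``!``/``&``/``|`` dialect."""
    if not text.strip():
        raise ExprSyntaxError("empty expression")
    return _Parser(text).parse()


def expr_from_truth_table(var_names: Sequence[str], table: Sequence[bool]) -> BoolExpr:
    """Build an expression from an explicit truth table (minterm expansion).

    ``table`` has one entry per assignment of the variables; row ``r`` assigns
    variable ``j`` the bit ``(r >> (k-1-j)) & 1`` (first variable = highest
    bit).  Constant tables collapse to ``Const``; otherwise every variable
    appears syntactically in each minterm.
    """
    k = len(var_names)
    if len(table) != 1 << k:
        raise ValueError(f"truth table must have {1 << k} rows, got {len(table)}")
    rows = [bool(v) for v in table]
    if not any(rows):
        return Const(False)
    if all(rows):
        return Const(True)
    minterms: list[BoolExpr] = []
    for r, on in enumerate(rows):
        if not on:
            continue
        literals: list[BoolExpr] = []
        for j, name in enumerate(var_names):
            bit = (r >> (k - 1 - j)) & 1
            literals.append(Var(name) if bit else Not(Var(name)))
        minterms.append(literals[0] if len(literals) == 1 else And(tuple(literals)))
    return minterms[0] if len(minterms) == 1 else Or(tuple(minterms))
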