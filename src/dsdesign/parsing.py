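"""Tokenizer and recursive-descent parser for the equation dialect.

The dialect is the plain-text form used throughout the toolkit:

* ``X1. = a1*X100^-1 + a1*rho1*X1^2*K1^-2*X100^-1 - b1*X1`` -- an ODE for X1,
* ``0 = 1 + X1^2*K1^-2 + X3*K3^-1 - X100`` -- an algebraic constraint,
* ``*`` multiplication, ``/`` division, ``^`` power, unary ``-`` separates
  negative terms, parentheses group sub-expressions (used by rational-rate-law
  models before recasting).

Exponents are rationals: ``^2``, ``^-1``, ``^0.5`` and ``^(1/2)`` are all
accepted; irrational exponents have no written form and are thereby rejected.

Variable names admit ``$`` and ``_`` so that replicated slice variables such
as ``$X2_0`` (used by co-localization constraints) tokenize as single names.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import List, Optional, Tuple, Union

from .errors import ModelSyntaxError

_TOKEN_RE = re.compile(
    r"""
    (?P<WS>\s+)
  | (?P<NUMBER>\d+\.\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?|\d+(?:[eE][+-]?\d+)?)
  | (?P<NAME>[$]?[A-Za-z_][A-Za-z0-9_$]*)
  | (?P<OP>[-+*/^()=.])
    """,
    re.VERBOSE,
)


@dataclass
class Token:
    kind: str  # NUMBER | NAME | OP | EOF
    value: str
    pos: int


def tokenize(text: str) -> List[Token]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ModelSyntaxError(
                f"unexpected character {text[pos]!r}", text=text, position=pos
            )
        if m.lastgroup != "WS":
            tokens.append(Token(m.lastgroup, m.group(), pos))
        pos = m.end()
    tokens.append(Token("EOF", "", len(text)))
    return tokens


# ---------------------------------------------------------------------------
# AST: an expression is an ordered sum of signed products; each product is an
# ordered list of (base, exponent) factors; a base is a symbol, a number, or a
# parenthesized sub-expression.  Order is load-bearing: term numbering (and
# hence case signatures) follows the textual left-to-right order.
# ---------------------------------------------------------------------------


@dataclass
class Sym:
    name: str


@dataclass
class Num:
    value: Fraction


@dataclass
class Group:
    expr: "SumExpr"


Base = Union[Sym, Num, Group]


@dataclass
class ProductExpr:
    factors: List[Tuple[Base, Fraction]] = field(default_factory=list)


@dataclass
class SumExpr:
    terms: List[Tuple[int, ProductExpr]] = field(default_factory=list)  # (+1/-1, prod)


@dataclass
class ParsedEquation:
    kind: str  # "ode" | "constraint"
    variable: Optional[str]  # lhs variable for ODEs
    rhs: SumExpr
    source: str


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = tokenize(text)
        self.i = 0

    @property
    def tok(self) -> Token:
        return self.tokens[self.i]

    def advance(self) -> Token:
        t = self.tokens[self.i]
        self.i += 1
        return t

    def expect(self, kind: str, value: Optional[str] = None) -> Token:
        t = self.tok
        if t.kind != kind or (value is not None and t.value != value):
            want = value if value is not None else kind
            raise ModelSyntaxError(
                f"expected {want!r}, found {t.value!r}", text=self.text, position=t.pos
            )
        return self.advance()

    # equation := (NAME '.' | '0') '=' sum EOF
    def parse_equation(self) -> ParsedEquation:
        t = self.tok
        if t.kind == "NAME":
            name = self.advance().value
            self.expect("OP", ".")
            kind, variable = "ode", name
        elif t.kind == "NUMBER" and t.value == "0":
            self.advance()
            kind, variable = "constraint", None
        else:
            raise ModelSyntaxError(
                "equation must start with 'NAME.' or '0'",
                text=self.text,
                position=t.pos,
            )
        self.expect("OP", "=")
        rhs = self.parse_sum()
        if self.tok.kind != "EOF":
            raise ModelSyntaxError(
                f"trailing input {self.tok.value!r}",
                text=self.text,
                position=self.tok.pos,
            )
        return ParsedEquation(kind, variable, rhs, self.text)

    def parse_expression(self) -> SumExpr:
        rhs = self.parse_sum()
        if self.tok.kind != "EOF":
            raise ModelSyntaxError(
                f"trailing input {self.tok.value!r}",
                text=self.text,
                position=self.tok.pos,
            )
        return rhs

    # sum := ['+'|'-'] product (('+'|'-') product)*
    def parse_sum(self) -> SumExpr:
        expr = SumExpr()
        sign = 1
        if self.tok.kind == "OP" and self.tok.value in "+-":
            sign = -1 if self.advance().value == "-" else 1
        expr.terms.append((sign, self.parse_product()))
        while self.tok.kind == "OP" and self.tok.value in "+-":
            sign = -1 if self.advance().value == "-" else 1
            expr.terms.append((sign, self.parse_product()))
        return expr

    # product := factor (('*'|'/') factor)*   (juxtaposition is not allowed)
    def parse_product(self) -> ProductExpr:
        prod = ProductExpr()
        prod.factors.append(self.parse_factor())
        while self.tok.kind == "OP" and self.tok.value in "*/":
            op = self.advance().value
            base, exp = self.parse_factor()
            if op == "/":
                exp = -exp
            prod.factors.append((base, exp))
        return prod

    # factor := base ['^' exponent]
    def parse_factor(self) -> Tuple[Base, Fraction]:
        t = self.tok
        if t.kind == "NAME":
            base: Base = Sym(self.advance().value)
        elif t.kind == "NUMBER":
            base = Num(Fraction(self.advance().value))
        elif t.kind == "OP" and t.value == "(":
            self.advance()
            inner = self.parse_sum()
            self.expect("OP", ")")
            base = Group(inner)
        else:
            raise ModelSyntaxError(
                f"expected a variable, number or '(', found {t.value!r}",
                text=self.text,
                position=t.pos,
            )
        exp = Fraction(1)
        if self.tok.kind == "OP" and self.tok.value == "^":
            self.advance()
            exp = self.parse_exponent()
        return base, exp

    # exponent := ['-'] NUMBER | '(' ['-'] NUMBER ['/' NUMBER] ')'
    def parse_exponent(self) -> Fraction:
        neg = False
        if self.tok.kind == "OP" and self.tok.value == "(":
            self.advance()
            if self.tok.kind == "OP" and self.tok.value == "-":
                self.advance()
                neg = True
            num = Fraction(self.expect("NUMBER").value)
            if self.tok.kind == "OP" and self.tok.value == "/":
                self.advance()
                num /= Fraction(self.expect("NUMBER").value)
            self.expect("OP", ")")
        else:
            if self.tok.kind == "OP" and self.tok.value == "-":
                self.advance()
                neg = True
            num = Fraction(self.expect("NUMBER").value)
        return -num if neg else num


def parse_equation(text: str) -> ParsedEquation:
    """Parse one equation string into its AST."""
    return _Parser(text).parse_equation()


def parse_expression(text: str) -> SumExpr:
    """Parse a bare expression (no left-hand side)."""
    return _Parser(text).parse_expression()


_REL_RE = re.compile(r"(<=|>=|<|>|=)")


def split_relation(text: str) -> Tuple[str, str, str]:
    """Split a power-law constraint string ``lhs REL rhs`` into its parts."""
    parts = _REL_RE.split(text)
    if len(parts) != 3:
        raise ModelSyntaxError(
            f"constraint must contain exactly one relation (<, <=, >, >=, =): {text!r}"
        )
    lhs, rel, rhs = (p.strip() for p in parts)
    if not lhs or not rhs:
        raise ModelSyntaxError(f"constraint is missing a side: {text!r}")
    return lhs, rel, rhs


def parse_model_text(text: str):
    """Parse the model text format: one equation per line, ``#`` comments,
    optional header directives ``auxiliary: X100, X200`` and
    ``constraint: rho1 >= 1``.

    Returns ``(equation_strings, auxiliary_names, constraint_strings)``.
    """
    equations: List[str] = []
    auxiliaries: List[str] = []
    constraints: List[str] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        lowered = line.lower()
        if lowered.startswith("auxiliary:") or lowered.startswith("auxiliaries:"):
            names = line.split(":", 1)[1]
            auxiliaries.extend(n.strip() for n in names.split(",") if n.strip())
        elif lowered.startswith("constraint:") or lowered.startswith("constraints:"):
            constraints.append(line.split(":", 1)[1].strip())
        else:
            equations.append(line)
    return equations, auxiliaries, constraints
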