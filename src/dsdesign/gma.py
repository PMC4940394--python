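"""Generalized mass action (GMA) systems.

A GMA system is a set of ODEs plus algebraic constraints in which every term
is a product of power laws with a positive rate constant:

    dX_i/dt = sum_k alpha_ik * prod_j X_j^g_ijk  -  sum_k beta_ik * prod_j X_j^h_ijk
    0       = sum_k alpha_ik * prod_j X_j^g_ijk  -  sum_k beta_ik * prod_j X_j^h_ijk

Dependent variables are the dynamic variables (one ODE each) followed by the
auxiliary variables (one zero-constraint each); every other symbol appearing
in the equations is an independent variable/parameter.  Term order is the
textual left-to-right order of the source equations and is preserved through
all downstream numbering -- case signatures depend on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

from . import parsing
from .errors import (
    ModelStructureError,
    UnsupportedFormError,
    VariableDomainError,
)


def _format_number(x: float) -> str:
    if x == int(x) and abs(x) < 1e16:
        return str(int(x))
    return repr(x)


def _format_exponent(e: Fraction) -> str:
    if e.denominator == 1:
        return str(e.numerator)
    return f"({e.numerator}/{e.denominator})"


@dataclass
class PowerLawTerm:
    """One power-law term: ``coefficient * prod_j name_j^exponent_j``.

    ``factors`` maps every symbol appearing in the term (variables *and*
    named parameters alike) to its rational exponent; symbols absent from the
    map have exponent 0.  The numeric ``coefficient`` collects literal
    numbers and is strictly positive.
    """

    coefficient: float = 1.0
    factors: Dict[str, Fraction] = field(default_factory=dict)

    def exponent(self, name: str) -> Fraction:
        return self.factors.get(name, Fraction(0))

    @property
    def log10_coefficient(self) -> float:
        return math.log10(self.coefficient)

    def evaluate(self, env: Dict[str, float]) -> float:
        value = self.coefficient
        for name, exp in self.factors.items():
            value *= env[name] ** float(exp)
        return value

    def serialize(self) -> str:
        parts = []
        if self.coefficient != 1.0 or not self.factors:
            parts.append(_format_number(self.coefficient))
        for name, exp in self.factors.items():
            if exp == 1:
                parts.append(name)
            else:
                parts.append(f"{name}^{_format_exponent(exp)}")
        return "*".join(parts)

    def multiplied(self, other: "PowerLawTerm") -> "PowerLawTerm":
        factors = dict(self.factors)
        for name, exp in other.factors.items():
            new = factors.get(name, Fraction(0)) + exp
            if new == 0:
                factors.pop(name, None)
            else:
                factors[name] = new
        return PowerLawTerm(self.coefficient * other.coefficient, factors)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize()


def term_from_product(prod: parsing.ProductExpr, source: str = "") -> PowerLawTerm:
    """Collapse a parsed product into a PowerLawTerm.

    Parenthesized sub-expressions are folded when they contain a single
    positive term; multi-term groups are not representable in GMA form and
    raise :class:`UnsupportedFormError` (such models must be recast first).
    """
    coefficient = 1.0
    factors: Dict[str, Fraction] = {}

    def fold(base, exp: Fraction):
        nonlocal coefficient
        if isinstance(base, parsing.Num):
            if base.value <= 0:
                raise UnsupportedFormError(
                    f"non-positive literal {base.value} in a power-law term: {source!r}"
                )
            coefficient *= float(base.value) ** float(exp)
        elif isinstance(base, parsing.Sym):
            new = factors.get(base.name, Fraction(0)) + exp
            if new == 0:
                factors.pop(base.name, None)
            else:
                factors[base.name] = new
        elif isinstance(base, parsing.Group):
            terms = base.expr.terms
            if len(terms) != 1 or terms[0][0] != 1:
                raise UnsupportedFormError(
                    "parenthesized sums are not GMA power laws; "
                    f"recast the model first: {source!r}"
                )
            for b, e in terms[0][1].factors:
                fold(b, e * exp)

    for base, exp in prod.factors:
        fold(base, exp)
    return PowerLawTerm(coefficient, factors)


@dataclass
class GMAEquation:
    kind: str  # "ode" | "constraint"
    variable: Optional[str]
    positive_terms: List[PowerLawTerm]
    negative_terms: List[PowerLawTerm]
    #: textual term sequence as (sign, index-within-sign-list) pairs
    sequence: List[Tuple[int, int]] = field(default_factory=list)
    source: str = ""

    def __post_init__(self):
        if not self.sequence:
            self.sequence = [(1, i) for i in range(len(self.positive_terms))] + [
                (-1, i) for i in range(len(self.negative_terms))
            ]

    @property
    def P(self) -> int:
        return len(self.positive_terms)

    @property
    def Q(self) -> int:
        return len(self.negative_terms)

    def serialize(self) -> str:
        lhs = f"{self.variable}. = " if self.kind == "ode" else "0 = "
        chunks = []
        for k, (sign, idx) in enumerate(self.sequence):
            term = (self.positive_terms if sign > 0 else self.negative_terms)[idx]
            op = ("" if k == 0 else "+ ") if sign > 0 else "- "
            if sign > 0 and k == 0:
                chunks.append(term.serialize())
            else:
                chunks.append(op + term.serialize())
        return lhs + " ".join(chunks)

    def evaluate(self, env: Dict[str, float]) -> Tuple[float, float, float]:
        pos = sum(t.evaluate(env) for t in self.positive_terms)
        neg = sum(t.evaluate(env) for t in self.negative_terms)
        return pos, neg, pos - neg


def equation_from_ast(eq: parsing.ParsedEquation) -> GMAEquation:
    positive: List[PowerLawTerm] = []
    negative: List[PowerLawTerm] = []
    sequence: List[Tuple[int, int]] = []
    for sign, prod in eq.rhs.terms:
        term = term_from_product(prod, eq.source)
        if sign > 0:
            sequence.append((1, len(positive)))
            positive.append(term)
        else:
            sequence.append((-1, len(negative)))
            negative.append(term)
    if not positive or not negative:
        raise ModelStructureError(
            "every GMA equation needs at least one positive and one negative "
            f"term: {eq.source!r}"
        )
    return GMAEquation(eq.kind, eq.variable, positive, negative, sequence, eq.source)


class GMASystem:
    """An ordered GMA system with the canonical variable ordering:
    dynamic variables first, auxiliary variables second, independent last."""

    def __init__(
        self,
        equations: Sequence[GMAEquation],
        auxiliary_variables: Sequence[str],
        extra_independent: Sequence[str] = (),
    ):
        odes = [e for e in equations if e.kind == "ode"]
        constraints = [e for e in equations if e.kind == "constraint"]

        self.dynamic_variables: List[str] = []
        for e in odes:
            if e.variable in self.dynamic_variables:
                raise ModelStructureError(
                    f"variable {e.variable} has more than one ODE"
                )
            self.dynamic_variables.append(e.variable)

        # Pair each declared auxiliary with the unique constraint containing it.
        aux_list = list(auxiliary_variables)
        for a in aux_list:
            if a in self.dynamic_variables:
                raise ModelStructureError(
                    f"auxiliary variable {a} also has an ODE"
                )
        owners: Dict[int, str] = {}
        for a in aux_list:
            hits = [
                i
                for i, c in enumerate(constraints)
                if any(
                    a in t.factors for t in c.positive_terms + c.negative_terms
                )
            ]
            if len(hits) != 1:
                raise ModelStructureError(
                    f"auxiliary variable {a} must appear in exactly one "
                    f"zero-constraint (found {len(hits)})"
                )
            if hits[0] in owners:
                raise ModelStructureError(
                    f"constraint {constraints[hits[0]].source!r} is claimed by "
                    f"both {owners[hits[0]]} and {a}"
                )
            owners[hits[0]] = a
        if len(constraints) != len(aux_list):
            raise ModelStructureError(
                f"{len(constraints)} zero-constraints for {len(aux_list)} "
                "declared auxiliary variables"
            )
        # auxiliary order follows constraint equation order
        self.auxiliary_variables = [owners[i] for i in range(len(constraints))]
        self.equations: List[GMAEquation] = odes + constraints

        dependent = set(self.dynamic_variables) | set(self.auxiliary_variables)
        seen: Dict[str, None] = {}
        for eq in self.equations:
            for sign, idx in eq.sequence:
                term = (eq.positive_terms if sign > 0 else eq.negative_terms)[idx]
                for name in term.factors:
                    if name not in dependent:
                        seen.setdefault(name)
        for name in extra_independent:
            seen.setdefault(name)
        self.independent_variables: List[str] = list(seen)

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_t(self) -> int:
        return len(self.dynamic_variables)

    @property
    def n_c(self) -> int:
        return len(self.auxiliary_variables)

    @property
    def n(self) -> int:
        return self.n_t + self.n_c

    @property
    def m(self) -> int:
        return len(self.independent_variables)

    @property
    def dependent_variables(self) -> List[str]:
        return self.dynamic_variables + self.auxiliary_variables

    @property
    def all_variables(self) -> List[str]:
        return self.dependent_variables + self.independent_variables

    @property
    def signature(self) -> List[Tuple[int, int]]:
        return [(eq.P, eq.Q) for eq in self.equations]

    @property
    def num_cases(self) -> int:
        total = 1
        for P, Q in self.signature:
            total *= P * Q
        return total

    def serialize(self) -> List[str]:
        return [eq.serialize() for eq in self.equations]

    def evaluate(self, point: Dict[str, float]) -> List[Tuple[float, float, float]]:
        """Evaluate every equation at a full positive assignment; returns
        (positive-sum, negative-sum, net) per equation."""
        for name in self.all_variables:
            if name not in point:
                raise VariableDomainError(f"no value assigned to {name}")
            if not point[name] > 0:
                raise VariableDomainError(
                    f"{name} must be strictly positive, got {point[name]}"
                )
        return [eq.evaluate(point) for eq in self.equations]

    def with_extra_independent(self, names: Sequence[str]) -> "GMASystem":
        """A copy of this system with additional independent variables (used
        e.g. for free state-space thresholds)."""
        extra = [n for n in self.independent_variables if True] + [
            n for n in names if n not in self.independent_variables
        ]
        return GMASystem(self.equations, self.auxiliary_variables, extra)

    def __repr__(self) -> str:  # pragma: no cover
        sig = "".join(f"{P}{Q}" for P, Q in self.signature)
        return f"<GMASystem n_t={self.n_t} n_c={self.n_c} m={self.m} signature=({sig})>"


def parse_model(
    equation_strings: Sequence[str],
    auxiliary_names: Sequence[str] = (),
    extra_independent: Sequence[str] = (),
) -> GMASystem:
    """Parse equation strings in the GMA dialect into a :class:`GMASystem`."""
    equations = [
        equation_from_ast(parsing.parse_equation(s)) for s in equation_strings
    ]
    return GMASystem(equations, auxiliary_names, extra_independent)
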