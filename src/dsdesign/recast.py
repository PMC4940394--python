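"""Recasting rational-rate-law models into GMA form.

Biochemical rate laws are typically rational functions (Michaelis-Menten,
Hill, and their regulated variants).  Any such model can be recast exactly
into the GMA differential-algebraic form in five steps: (1) expand numerator
sums by multiplying through common factors; (2) define one auxiliary
variable per distinct multi-term denominator; (3) rearrange each auxiliary
definition into a zero-constraint; (4) substitute the auxiliaries for their
denominators; (5) assemble the differential equations plus constraints into
one system.

Term order is preserved left-to-right through the expansion so that case
numbering downstream is reproducible from the source text.  Auxiliary
variables are auto-named after the equation's left-hand-side variable with
suffix "00" (then "01", "02", ... if taken), e.g. the denominator of the
X1 equation becomes X100.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Tuple

from . import parsing
from .errors import UnsupportedFormError
from .gma import (
    GMAEquation,
    GMASystem,
    PowerLawTerm,
    equation_from_ast,
    term_from_product,
)


@dataclass
class RationalModel:
    """A model whose ODE right-hand sides are sums of terms, each a power law
    or a power law times reciprocals of sums of power laws."""

    equation_strings: List[str]

    def parsed(self) -> List[parsing.ParsedEquation]:
        return [parsing.parse_equation(s) for s in self.equation_strings]


def _expand_product(
    prod: parsing.ProductExpr, source: str
) -> List[Tuple[int, PowerLawTerm, List[Tuple[parsing.SumExpr, Fraction]]]]:
    """Expand one product into a list of (sign, power-law core, denominators).

    Multi-term groups with exponent +1 are multiplied through (step 1),
    preserving order; groups with negative integer exponents are collected
    as denominators for step 2.  Any other multi-term group cannot be
    recast.
    """
    items: List[Tuple[int, PowerLawTerm, List]] = [(1, PowerLawTerm(), [])]
    for base, exp in prod.factors:
        if isinstance(base, parsing.Group):
            terms = base.expr.terms
            if len(terms) == 1:
                sign, inner = terms[0]
                scaled = parsing.ProductExpr(
                    [(b, e * exp) for b, e in inner.factors]
                )
                factor_term = term_from_product(scaled, source)
                if sign < 0:
                    if exp != 1:
                        raise UnsupportedFormError(
                            f"cannot recast a negative group under a power: {source!r}"
                        )
                    items = [(s * sign, t.multiplied(factor_term), d)
                             for s, t, d in items]
                else:
                    items = [(s, t.multiplied(factor_term), d) for s, t, d in items]
                continue
            if exp == 1:
                new_items = []
                for s, t, d in items:
                    for s2, t2, d2 in _expand_sum(base.expr, source):
                        new_items.append((s * s2, t.multiplied(t2), d + d2))
                items = new_items
            elif exp.denominator == 1 and exp < 0:
                items = [(s, t, d + [(base.expr, exp)]) for s, t, d in items]
            else:
                raise UnsupportedFormError(
                    f"multi-term group with exponent {exp} cannot be recast: {source!r}"
                )
        else:
            factor_term = term_from_product(
                parsing.ProductExpr([(base, exp)]), source
            )
            items = [(s, t.multiplied(factor_term), d) for s, t, d in items]
    return items


def _expand_sum(expr: parsing.SumExpr, source: str):
    out = []
    for sign, prod in expr.terms:
        for s, t, d in _expand_product(prod, source):
            out.append((sign * s, t, d))
    return out


def _denominator_terms(expr: parsing.SumExpr, source: str) -> List[PowerLawTerm]:
    terms = []
    for sign, prod in expr.terms:
        if sign < 0:
            raise UnsupportedFormError(
                f"denominator with a negative term cannot be recast: {source!r}"
            )
        term = term_from_product(prod, source)
        terms.append(term)
    return terms


def _denominator_key(terms: List[PowerLawTerm]) -> tuple:
    return tuple(
        (t.coefficient, tuple(sorted((n, e) for n, e in t.factors.items())))
        for t in terms
    )


def recast(model) -> GMASystem:
    """Recast a rational-rate-law model into an exactly equivalent GMA
    system with one auxiliary variable per distinct multi-term denominator.

    ``model`` is a :class:`RationalModel` or a sequence of equation strings.
    Pure GMA input passes through unchanged (no auxiliaries added).
    """
    if not isinstance(model, RationalModel):
        model = RationalModel(list(model))
    parsed = model.parsed()

    used_names = set()
    for eq in parsed:
        if eq.variable:
            used_names.add(eq.variable)

        def collect(expr):
            for _, prod in expr.terms:
                for base, _ in prod.factors:
                    if isinstance(base, parsing.Sym):
                        used_names.add(base.name)
                    elif isinstance(base, parsing.Group):
                        collect(base.expr)

        collect(eq.rhs)

    aux_names: Dict[tuple, str] = {}
    aux_terms: Dict[str, List[PowerLawTerm]] = {}
    aux_order: List[str] = []

    def auxiliary_for(expr: parsing.SumExpr, basename: str, source: str) -> str:
        terms = _denominator_terms(expr, source)
        key = _denominator_key(terms)
        if key in aux_names:
            return aux_names[key]
        suffix = 0
        while f"{basename}{suffix:02d}" in used_names:
            suffix += 1
        name = f"{basename}{suffix:02d}"
        used_names.add(name)
        aux_names[key] = name
        aux_terms[name] = terms
        aux_order.append(name)
        return name

    equations: List[GMAEquation] = []
    for eq in parsed:
        if eq.kind == "constraint":
            equations.append(equation_from_ast(eq))
            continue
        strings_pos: List[PowerLawTerm] = []
        strings_neg: List[PowerLawTerm] = []
        sequence: List[Tuple[int, int]] = []
        for sign, core, denoms in _expand_sum(eq.rhs, eq.source):
            term = core
            for denom_expr, exp in denoms:
                name = auxiliary_for(denom_expr, eq.variable or "X", eq.source)
                term = term.multiplied(PowerLawTerm(1.0, {name: exp}))
            if sign > 0:
                sequence.append((1, len(strings_pos)))
                strings_pos.append(term)
            else:
                sequence.append((-1, len(strings_neg)))
                strings_neg.append(term)
        equations.append(
            GMAEquation(eq.kind, eq.variable, strings_pos, strings_neg, sequence,
                        eq.source)
        )

    for name in aux_order:
        terms = aux_terms[name]
        equations.append(
            GMAEquation(
                "constraint",
                None,
                list(terms),
                [PowerLawTerm(1.0, {name: Fraction(1)})],
            )
        )

    return GMASystem(equations, aux_order, ())
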