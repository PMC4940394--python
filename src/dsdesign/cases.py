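"""Qualitatively distinct phenotypes (cases) of a GMA system.

At any point of the combined state + parameter space each equation has one
dominant positive and one dominant negative term; the per-equation indices
``[p_1 q_1 ... p_n q_n]`` form the *case signature*.  Retaining only the
dominant terms yields a tractable S-system, and the dominance requirement
becomes a system of linear inequalities in the logarithms of all variables
(the *dominance polytope*).  Substituting the S-system's log-linear steady
state into those rows projects them onto the independent variables (the
*boundary conditions*, a polytope in parameter space); a case with a
non-empty boundary polytope is a valid phenotype, and the set of all valid
cases is the phenotypic repertoire.

Case numbers and signatures are in bijection through a mixed-radix rule
with radices ``(P_1, Q_1, ..., P_n, Q_n)``, the last equation's indices
varying fastest and the positive index more significant than the negative
one within an equation; the all-ones signature is case 1.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from . import lp, parsing
from .errors import VariableDomainError
from .gma import GMASystem, parse_model, term_from_product
from .linsys import LinearInequalitySystem, LinearRow
from .ssystems import SSystem

Signature = List[Tuple[int, int]]


# ---------------------------------------------------------------------------
# signature <-> number bijection
# ---------------------------------------------------------------------------

def case_number_from_signature(signature: Signature, radices: Signature) -> int:
    if len(signature) != len(radices):
        raise VariableDomainError(
            f"signature has {len(signature)} index pairs for {len(radices)} equations"
        )
    value = 0
    for (p, q), (P, Q) in zip(signature, radices):
        if not (1 <= p <= P and 1 <= q <= Q):
            raise VariableDomainError(
                f"signature indices ({p},{q}) out of range for term counts ({P},{Q})"
            )
        value = value * P + (p - 1)
        value = value * Q + (q - 1)
    return value + 1


def signature_from_case_number(number: int, radices: Signature) -> Signature:
    total = 1
    for P, Q in radices:
        total *= P * Q
    if not (1 <= number <= total):
        raise VariableDomainError(f"case number {number} out of range 1..{total}")
    value = number - 1
    digits = []
    for P, Q in reversed(radices):
        value, q = divmod(value, Q)
        value, p = divmod(value, P)
        digits.append((p + 1, q + 1))
    return list(reversed(digits))


def signature_string(signature: Signature) -> str:
    flat = [i for pq in signature for i in pq]
    if all(i <= 9 for i in flat):
        return "".join(str(i) for i in flat)
    return "-".join(str(i) for i in flat)


def parse_signature_string(text: str) -> Signature:
    text = text.strip().strip("[]")
    if "-" in text:
        flat = [int(p) for p in text.split("-")]
    else:
        flat = [int(ch) for ch in text]
    if len(flat) % 2:
        raise VariableDomainError(f"signature {text!r} has an odd number of indices")
    return [(flat[i], flat[i + 1]) for i in range(0, len(flat), 2)]


# ---------------------------------------------------------------------------
# power-law constraints
# ---------------------------------------------------------------------------

def constraint_row(text: str) -> LinearRow:
    """Parse ``lhs REL rhs`` (both sides single power laws) into a log-linear
    row.  ``<``/``<=`` rows are negated so every inequality reads ``>= 0``."""
    lhs_text, rel, rhs_text = parsing.split_relation(text)
    sides = []
    for side in (lhs_text, rhs_text):
        expr = parsing.parse_expression(side)
        if len(expr.terms) != 1 or expr.terms[0][0] != 1:
            raise VariableDomainError(
                f"constraint sides must be single power laws: {text!r}"
            )
        sides.append(term_from_product(expr.terms[0][1], side))
    lhs, rhs = sides
    coeffs: Dict[str, Fraction] = dict(lhs.factors)
    for name, exp in rhs.factors.items():
        new = coeffs.get(name, Fraction(0)) - exp
        if new == 0:
            coeffs.pop(name, None)
        else:
            coeffs[name] = new
    const = lhs.log10_coefficient - rhs.log10_coefficient
    if rel in ("<", "<="):
        coeffs = {n: -c for n, c in coeffs.items()}
        const = -const
    relation = "=" if rel == "=" else ">="
    return LinearRow(coeffs, const, relation, label=text)


# ---------------------------------------------------------------------------
# Case
# ---------------------------------------------------------------------------

class Case:
    """One qualitatively distinct phenotype of a design space."""

    def __init__(
        self,
        design_space: "DesignSpace",
        number: int,
        constraints: Sequence[str] = (),
    ):
        self.design_space = design_space
        self.system: GMASystem = design_space.system
        self.number = number
        self.signature: Signature = signature_from_case_number(
            number, self.system.signature
        )
        #: model-level constraints first, then case-specific ones
        self.constraints: List[str] = list(design_space.constraints) + list(constraints)
        self.ssystem: SSystem = design_space._ssystem(number)
        self._boundary: Optional[LinearInequalitySystem] = None
        self._boundary_built = False

    @property
    def signature_string(self) -> str:
        return signature_string(self.signature)

    @property
    def has_solution(self) -> bool:
        return self.ssystem.has_solution

    # -- dominance ---------------------------------------------------------
    def dominance_conditions(self) -> LinearInequalitySystem:
        """Log-linear rows asserting that the signature-selected terms
        dominate every sibling term, over all n+m log-variables."""
        lis = LinearInequalitySystem(self.system.all_variables)
        for i, (eq, (p, q)) in enumerate(zip(self.system.equations, self.signature)):
            for kind, terms, dom_idx in (
                ("pos", eq.positive_terms, p - 1),
                ("neg", eq.negative_terms, q - 1),
            ):
                dom = terms[dom_idx]
                for k, other in enumerate(terms):
                    if k == dom_idx:
                        continue
                    coeffs: Dict[str, Fraction] = dict(dom.factors)
                    for name, exp in other.factors.items():
                        new = coeffs.get(name, Fraction(0)) - exp
                        if new == 0:
                            coeffs.pop(name, None)
                        else:
                            coeffs[name] = new
                    const = dom.log10_coefficient - other.log10_coefficient
                    lis.add_row(
                        coeffs,
                        const,
                        ">=",
                        label=f"eq{i + 1}:{kind}{dom_idx + 1}>={kind}{k + 1}",
                    )
        return lis

    def _substitute_row(self, row: LinearRow) -> LinearRow:
        """Replace dependent-variable coefficients using the steady-state
        solution, leaving a row over the independent variables only."""
        solution = self.ssystem.solve_steady_state()
        dependent = set(self.system.dependent_variables)
        independent = set(self.system.independent_variables)
        coeffs: Dict[str, Fraction] = {}
        const = row.const
        for name, w in row.coeffs.items():
            if name in dependent:
                dep_const, dep_coeffs = solution.affine[name]
                const += float(w) * dep_const
                for ind, c in dep_coeffs.items():
                    new = coeffs.get(ind, Fraction(0)) + w * c
                    if new == 0:
                        coeffs.pop(ind, None)
                    else:
                        coeffs[ind] = new
            elif name in independent:
                new = coeffs.get(name, Fraction(0)) + w
                if new == 0:
                    coeffs.pop(name, None)
                else:
                    coeffs[name] = new
            else:
                raise VariableDomainError(
                    f"constraint references unknown variable {name}"
                )
        return LinearRow(coeffs, const, row.rel, row.label)

    def boundary_conditions(self) -> Optional[LinearInequalitySystem]:
        """The phenotypic polytope: dominance rows with the steady-state
        solution substituted in, over the m log-parameters; ``None`` when the
        S-system is underdetermined."""
        if self._boundary_built:
            return self._boundary
        self._boundary_built = True
        if not self.ssystem.has_solution:
            self._boundary = None
            return None
        lis = LinearInequalitySystem(self.system.independent_variables)
        for row in self.dominance_conditions().rows:
            lis.rows.append(self._substitute_row(row))
        for text in self.constraints:
            lis.rows.append(self._substitute_row(constraint_row(text)))
        self._boundary = lis
        return lis

    # -- validity ----------------------------------------------------------
    def is_valid(
        self,
        p_bounds: Optional[Mapping[str, Union[float, Tuple[float, float]]]] = None,
    ) -> bool:
        """True iff the boundary polytope has an interior point (slack >=
        delta) inside the global box, optionally narrowed by ``p_bounds``
        (scalar values pin a parameter; pairs bound it)."""
        boundary = self.boundary_conditions()
        if boundary is None:
            return False
        bounds, fixed = _split_bounds(p_bounds)
        return lp.feasible(
            boundary,
            delta=self.design_space.delta,
            box=self.design_space.box,
            p_bounds=bounds,
            fixed=fixed,
        )

    def contains_point(self, pvals: Mapping[str, float], tol: float = 1e-9) -> bool:
        boundary = self.boundary_conditions()
        if boundary is None:
            return False
        logpoint = _logpoint(self.system.independent_variables, pvals)
        return boundary.contains(logpoint, tol=tol)

    # -- predictions (implemented in dsdesign.predict) ---------------------
    def valid_parameter_set(self, **kwargs):
        from . import predict

        return predict.valid_parameter_set(self, **kwargs)

    def valid_interior_parameter_set(self, **kwargs):
        from . import predict

        return predict.valid_interior_parameter_set(self, **kwargs)

    def measure_tolerances(self, pvals: Mapping[str, float]):
        from . import predict

        return predict.measure_tolerances(self, pvals)

    def positive_roots(self, pvals: Mapping[str, float]) -> int:
        return self.ssystem.positive_roots(pvals)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Case {self.number} [{self.signature_string}]>"


def _logpoint(names: Sequence[str], pvals: Mapping[str, float]) -> Dict[str, float]:
    logpoint = {}
    for name in names:
        if name not in pvals:
            raise VariableDomainError(f"no value assigned to {name}")
        if not pvals[name] > 0:
            raise VariableDomainError(f"{name} must be strictly positive")
        logpoint[name] = math.log10(pvals[name])
    return logpoint


def _split_bounds(p_bounds):
    """Split a p_bounds mapping into interval bounds and pinned values."""
    if not p_bounds:
        return None, None
    bounds, fixed = {}, {}
    for name, value in p_bounds.items():
        if isinstance(value, (tuple, list)):
            bounds[name] = (float(value[0]), float(value[1]))
        else:
            fixed[name] = float(value)
    return bounds or None, fixed or None


# ---------------------------------------------------------------------------
# DesignSpace
# ---------------------------------------------------------------------------

class DesignSpace:
    """The design space of a GMA system: the facade for enumeration and for
    constructing :class:`Case` objects."""

    def __init__(
        self,
        system: Union[GMASystem, Sequence[str]],
        auxiliary_variables: Sequence[str] = (),
        constraints: Sequence[str] = (),
        extra_independent: Sequence[str] = (),
        delta: float = lp.DEFAULT_DELTA,
        box: Tuple[float, float] = lp.DEFAULT_BOX,
    ):
        if isinstance(system, GMASystem):
            if extra_independent:
                system = system.with_extra_independent(extra_independent)
            self.system = system
        else:
            self.system = parse_model(system, auxiliary_variables, extra_independent)
        self.constraints = list(constraints)
        self.delta = delta
        self.box = box
        self._ssystems: Dict[int, SSystem] = {}
        self._cases: Dict[Tuple[int, Tuple[str, ...]], Case] = {}
        self._valid_cache: Optional[List[int]] = None

    @property
    def num_cases(self) -> int:
        return self.system.num_cases

    def _ssystem(self, number: int) -> SSystem:
        if number not in self._ssystems:
            signature = signature_from_case_number(number, self.system.signature)
            self._ssystems[number] = SSystem.from_case(self.system, signature)
        return self._ssystems[number]

    def case_number_from_signature(self, signature) -> int:
        if isinstance(signature, str):
            signature = parse_signature_string(signature)
        return case_number_from_signature(signature, self.system.signature)

    def signature_from_case_number(self, number: int) -> Signature:
        return signature_from_case_number(number, self.system.signature)

    def __call__(
        self,
        ident,
        by_signature: bool = False,
        constraints: Sequence[str] = (),
    ):
        """Retrieve one Case (or a list of Cases) by number or signature."""
        if isinstance(ident, (list, tuple)):
            return [self(i, by_signature, constraints) for i in ident]
        if by_signature or (isinstance(ident, str) and not ident.isdigit()):
            number = self.case_number_from_signature(ident)
        else:
            number = int(ident)
        key = (number, tuple(constraints))
        if key not in self._cases:
            self._cases[key] = Case(self, number, constraints)
        return self._cases[key]

    def cases(self):
        for number in range(1, self.num_cases + 1):
            yield self(number)

    def valid_cases(
        self,
        p_bounds: Optional[Mapping[str, Union[float, Tuple[float, float]]]] = None,
    ) -> List[int]:
        """Ascending case numbers of all valid phenotypes.

        With ``p_bounds`` holding scalar values for *every* parameter this is
        point membership (the cases coexisting at that parameter set);
        otherwise it is LP validity within the (narrowed) global box.
        """
        if p_bounds and all(
            not isinstance(v, (tuple, list)) for v in p_bounds.values()
        ) and all(n in p_bounds for n in self.system.independent_variables):
            return self.valid_cases_at_point(p_bounds)
        if p_bounds is None and self._valid_cache is not None:
            return list(self._valid_cache)
        result = [case.number for case in self.cases() if case.is_valid(p_bounds)]
        if p_bounds is None:
            self._valid_cache = list(result)
        return result

    def valid_cases_at_point(self, pvals: Mapping[str, float]) -> List[int]:
        """Cases whose phenotypic polytope contains the given parameter
        point (slack >= 0); their count is the number of coexisting fixed
        points of the full system at that point."""
        logpoint = _logpoint(self.system.independent_variables, pvals)
        out = []
        for case in self.cases():
            boundary = case.boundary_conditions()
            if boundary is not None and boundary.contains(logpoint):
                out.append(case.number)
        return out

    def repertoire(self) -> pd.DataFrame:
        """Per-case summary table (case_number, signature, valid, has_solution)."""
        valid = set(self.valid_cases())
        records = []
        for case in self.cases():
            records.append(
                {
                    "case_number": case.number,
                    "signature": case.signature_string,
                    "valid": case.number in valid,
                    "has_solution": case.has_solution,
                }
            )
        return pd.DataFrame.from_records(records)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DesignSpace {self.num_cases} cases over {self.system!r}>"
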