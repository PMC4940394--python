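"""Dominant S-systems: log-linear steady states, gains, and local stability.

An S-system has exactly one positive and one negative power-law term per
equation, so its steady state is linear in logarithmic coordinates:

    G y + a = H y + b

with ``G``/``H`` the kinetic-order matrices of the selected terms and
``a``/``b`` the log rate constants.  Splitting ``y`` into dependent
(dynamic + auxiliary) and independent blocks and solving the dependent block
gives an affine map ``y_dep = D y_I + d`` whose matrix ``D`` *is* the table
of logarithmic gains and parameter sensitivities -- an exact rational
function of kinetic orders, computed here in exact rational arithmetic.

Algebraic constraints (auxiliary variables introduced by recasting) are
eliminated before any stability analysis: the auxiliary block is solved and
substituted back, yielding a purely dynamical S-system whose Jacobian at the
steady state is formed analytically from the power-law derivatives.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import sympy

from .errors import (
    RouthDegenerateError,
    SingularSystemError,
    VariableDomainError,
)
from .gma import GMAEquation, GMASystem, PowerLawTerm

#: eigenvalues with |Re| below this fraction of the spectral radius are
#: treated as borderline (counted as non-positive and flagged)
BORDERLINE_RTOL = 1e-9


@dataclass
class SteadyStateSolution:
    """Affine log-linear steady state ``y_dep = D y_I + d``.

    ``affine`` maps each dependent variable to ``(const, coeffs)`` where
    ``coeffs`` are exact rationals over the independent variables; the gain
    ``L(X_dep, X_ind)`` is ``coeffs[X_ind]``.
    """

    exists: bool
    dependent: List[str]
    independent: List[str]
    affine: Optional[Dict[str, Tuple[float, Dict[str, Fraction]]]] = None

    def log_gain(self, dep: str, ind: str) -> Fraction:
        if not self.exists:
            raise SingularSystemError("S-system has no steady-state solution")
        if dep not in self.affine:
            raise VariableDomainError(f"{dep} is not a dependent variable")
        if ind not in self.independent:
            raise VariableDomainError(f"{ind} is not an independent variable")
        return self.affine[dep][1].get(ind, Fraction(0))

    def gain_matrix(self) -> Dict[str, Dict[str, Fraction]]:
        return {
            dep: {ind: self.log_gain(dep, ind) for ind in self.independent}
            for dep in self.dependent
        }

    def as_power_laws(self) -> Dict[str, PowerLawTerm]:
        """Cartesian form of the solution, e.g. ``X1 = a1*b1^-1``."""
        out = {}
        for dep in self.dependent:
            const, coeffs = self.affine[dep]
            out[dep] = PowerLawTerm(
                10.0 ** const, {n: e for n, e in coeffs.items() if e != 0}
            )
        return out


@dataclass
class StabilityReport:
    eigenvalues: List[complex]
    positive_root_count: int
    margin: float
    borderline: bool


def _rational(fr: Fraction) -> sympy.Rational:
    return sympy.Rational(fr.numerator, fr.denominator)


class SSystem:
    """A dominant S-system: one positive and one negative term per equation."""

    def __init__(
        self,
        equations: List[GMAEquation],
        dynamic_variables: List[str],
        auxiliary_variables: List[str],
        independent_variables: List[str],
    ):
        for eq in equations:
            if eq.P != 1 or eq.Q != 1:
                raise ValueError("an S-system equation has exactly one term per sign")
        self.equations = equations
        self.dynamic_variables = list(dynamic_variables)
        self.auxiliary_variables = list(auxiliary_variables)
        self.independent_variables = list(independent_variables)
        self._solution: Optional[SteadyStateSolution] = None
        self._reduced: Optional["SSystem"] = None

    @classmethod
    def from_case(cls, system: GMASystem, signature: List[Tuple[int, int]]) -> "SSystem":
        equations = []
        for eq, (p, q) in zip(system.equations, signature):
            equations.append(
                GMAEquation(
                    eq.kind,
                    eq.variable,
                    [eq.positive_terms[p - 1]],
                    [eq.negative_terms[q - 1]],
                )
            )
        return cls(
            equations,
            system.dynamic_variables,
            system.auxiliary_variables,
            system.independent_variables,
        )

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

    def serialize(self) -> List[str]:
        return [eq.serialize() for eq in self.equations]

    # -- log-linear algebra ------------------------------------------------
    def _blocks(self):
        """A = G - H split into dependent / independent blocks, plus b - a."""
        dep = self.dependent_variables
        ind = self.independent_variables
        A_dep = sympy.zeros(self.n, self.n)
        A_ind = sympy.zeros(self.n, self.m)
        rhs = np.zeros(self.n)
        for i, eq in enumerate(self.equations):
            pos, neg = eq.positive_terms[0], eq.negative_terms[0]
            for j, name in enumerate(dep):
                A_dep[i, j] = _rational(pos.exponent(name) - neg.exponent(name))
            for j, name in enumerate(ind):
                A_ind[i, j] = _rational(pos.exponent(name) - neg.exponent(name))
            rhs[i] = neg.log10_coefficient - pos.log10_coefficient
        return A_dep, A_ind, rhs

    def solve_steady_state(self) -> SteadyStateSolution:
        """Solve ``(G - H) y = b - a`` for the dependent log-variables,
        symbolically over the independent variables."""
        if self._solution is not None:
            return self._solution
        dep, ind = self.dependent_variables, self.independent_variables
        if self.n == 0:
            self._solution = SteadyStateSolution(True, [], ind, {})
            return self._solution
        A_dep, A_ind, rhs = self._blocks()
        if A_dep.det() == 0:
            self._solution = SteadyStateSolution(False, dep, ind)
            return self._solution
        D = A_dep.LUsolve(-A_ind)  # exact rationals
        d = np.linalg.solve(np.array(A_dep, dtype=float), rhs)
        affine = {}
        for i, name in enumerate(dep):
            coeffs = {
                ind[j]: Fraction(int(D[i, j].p), int(D[i, j].q))
                for j in range(self.m)
                if D[i, j] != 0
            }
            affine[name] = (float(d[i]), coeffs)
        self._solution = SteadyStateSolution(True, dep, ind, affine)
        return self._solution

    @property
    def has_solution(self) -> bool:
        return self.solve_steady_state().exists

    def log_gain(self, dependent: str, independent: str) -> Fraction:
        """Exact logarithmic gain/sensitivity d log X_dep / d log X_ind."""
        return self.solve_steady_state().log_gain(dependent, independent)

    def steady_state(self, pvals: Mapping[str, float]) -> Dict[str, float]:
        """Numeric steady state of the dependent variables at a parameter set."""
        sol = self.solve_steady_state()
        if not sol.exists:
            raise SingularSystemError("S-system has no steady-state solution")
        logp = {}
        for name in self.independent_variables:
            if name not in pvals:
                raise VariableDomainError(f"no value assigned to {name}")
            if not pvals[name] > 0:
                raise VariableDomainError(f"{name} must be strictly positive")
            logp[name] = math.log10(pvals[name])
        out = {}
        for dep in self.dependent_variables:
            const, coeffs = sol.affine[dep]
            out[dep] = 10.0 ** (
                const + sum(float(c) * logp[n] for n, c in coeffs.items())
            )
        return out

    # -- constraint elimination (auxiliary variables) ----------------------
    def remove_algebraic_constraints(self) -> "SSystem":
        """Eliminate the auxiliary variables by solving the algebraic block
        ``A_c y_c = -A_t y_t - A_I y_I + (b - a)_c`` and substituting back,
        yielding a purely dynamical S-system over the dynamic variables."""
        if self.n_c == 0:
            return self
        if self._reduced is not None:
            return self._reduced
        nt, nc = self.n_t, self.n_c
        dyn, aux, ind = (
            self.dynamic_variables,
            self.auxiliary_variables,
            self.independent_variables,
        )
        A_cc = sympy.zeros(nc, nc)
        A_ct = sympy.zeros(nc, nt)
        A_cI = sympy.zeros(nc, self.m)
        rhs = np.zeros(nc)
        for i in range(nc):
            eq = self.equations[nt + i]
            pos, neg = eq.positive_terms[0], eq.negative_terms[0]
            for j, name in enumerate(aux):
                A_cc[i, j] = _rational(pos.exponent(name) - neg.exponent(name))
            for j, name in enumerate(dyn):
                A_ct[i, j] = _rational(pos.exponent(name) - neg.exponent(name))
            for j, name in enumerate(ind):
                A_cI[i, j] = _rational(pos.exponent(name) - neg.exponent(name))
            rhs[i] = neg.log10_coefficient - pos.log10_coefficient
        if A_cc.det() == 0:
            raise SingularSystemError(
                "auxiliary block is singular; constraints cannot be eliminated"
            )
        R = A_cc.LUsolve(A_ct)  # y_c = -R y_t - S y_I + U
        S = A_cc.LUsolve(A_cI)
        U = np.linalg.solve(np.array(A_cc, dtype=float), rhs)

        def substitute(term: PowerLawTerm) -> PowerLawTerm:
            factors: Dict[str, Fraction] = {}
            log_coeff = term.log10_coefficient
            for j, name in enumerate(dyn):
                e = term.exponent(name)
                for i, a in enumerate(aux):
                    ea = term.exponent(a)
                    if ea:
                        e -= ea * Fraction(int(R[i, j].p), int(R[i, j].q))
                if e:
                    factors[name] = e
            for j, name in enumerate(ind):
                e = term.exponent(name)
                for i, a in enumerate(aux):
                    ea = term.exponent(a)
                    if ea:
                        e -= ea * Fraction(int(S[i, j].p), int(S[i, j].q))
                if e:
                    factors[name] = e
            for i, a in enumerate(aux):
                ea = term.exponent(a)
                if ea:
                    log_coeff += float(ea) * U[i]
            return PowerLawTerm(10.0 ** log_coeff, factors)

        equations = []
        for i in range(nt):
            eq = self.equations[i]
            equations.append(
                GMAEquation(
                    "ode",
                    eq.variable,
                    [substitute(eq.positive_terms[0])],
                    [substitute(eq.negative_terms[0])],
                )
            )
        self._reduced = SSystem(equations, dyn, [], ind)
        return self._reduced

    # -- local stability ---------------------------------------------------
    def jacobian(self, pvals: Mapping[str, float]) -> np.ndarray:
        """Analytic Jacobian of the reduced system at its steady state.

        For a power-law term V with kinetic order e_j in X_j, dV/dX_j =
        e_j V / X_j; at steady state both terms equal the flux F_i, so
        J_ij = F_i (g_ij - h_ij) / X_j.
        """
        red = self.remove_algebraic_constraints()
        ss = red.steady_state(pvals)
        env = dict(pvals)
        env.update(ss)
        nt = red.n_t
        J = np.zeros((nt, nt))
        for i, eq in enumerate(red.equations):
            F = eq.positive_terms[0].evaluate(env)
            pos, neg = eq.positive_terms[0], eq.negative_terms[0]
            for j, name in enumerate(red.dynamic_variables):
                diff = float(pos.exponent(name) - neg.exponent(name))
                J[i, j] = F * diff / env[name]
        return J

    def eigenvalues(self, pvals: Mapping[str, float]) -> StabilityReport:
        """Eigenvalues of the reduced S-system Jacobian at the steady state."""
        J = self.jacobian(pvals)
        eig = np.linalg.eigvals(J)
        radius = max(np.max(np.abs(eig)), 1.0e-300)
        threshold = BORDERLINE_RTOL * max(radius, 1.0)
        margin = float(np.min(np.abs(eig.real))) if len(eig) else math.inf
        positive = int(np.sum(eig.real > threshold))
        return StabilityReport(
            eigenvalues=list(eig),
            positive_root_count=positive,
            margin=margin,
            borderline=bool(margin < threshold),
        )

    def positive_roots(self, pvals: Mapping[str, float]) -> int:
        return self.eigenvalues(pvals).positive_root_count

    def routh_positive_roots(self, pvals: Mapping[str, float]) -> int:
        """Count right-half-plane roots of the characteristic polynomial via
        sign changes in the first column of the Routh array.  A zero pivot
        raises :class:`RouthDegenerateError` (fall back to eigenvalues)."""
        J = self.jacobian(pvals)
        coeffs = np.poly(J)  # char. poly of J; roots are the eigenvalues
        n = len(coeffs) - 1
        if n == 0:
            return 0
        scale = np.max(np.abs(coeffs))
        rows = [coeffs[0::2], coeffs[1::2]]
        width = len(rows[0])
        rows[1] = np.concatenate([rows[1], np.zeros(width - len(rows[1]))])
        table = [rows[0], rows[1]]
        for i in range(2, n + 1):
            prev, prev2 = table[i - 1], table[i - 2]
            if abs(prev[0]) < 1e-12 * scale:
                raise RouthDegenerateError("zero pivot in Routh array")
            new = np.zeros(width)
            for j in range(width - 1):
                new[j] = (prev[0] * prev2[j + 1] - prev2[0] * prev[j + 1]) / prev[0]
            table.append(new)
        first = [row[0] for row in table[: n + 1]]
        if any(abs(v) < 1e-12 * scale for v in first):
            raise RouthDegenerateError("zero pivot in Routh array")
        changes = sum(
            1 for x, y in zip(first, first[1:]) if (x > 0) != (y > 0)
        )
        return changes

    # -- reporting ---------------------------------------------------------
    def report(self, pvals: Optional[Mapping[str, float]] = None) -> dict:
        sol = self.solve_steady_state()
        payload = {
            "equations": self.serialize(),
            "has_solution": sol.exists,
        }
        if sol.exists:
            payload["solution"] = {
                dep: term.serialize() for dep, term in sol.as_power_laws().items()
            }
            payload["gain_matrix"] = {
                dep: {ind: float(g) for ind, g in row.items()}
                for dep, row in sol.gain_matrix().items()
            }
        if pvals is not None and sol.exists:
            rep = self.eigenvalues(pvals)
            payload["eigenvalues"] = [
                [z.real, z.imag] for z in rep.eigenvalues
            ]
            payload["positive_root_count"] = rep.positive_root_count
        return payload

    def report_json(self, pvals: Optional[Mapping[str, float]] = None) -> str:
        return json.dumps(self.report(pvals), indent=1)
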