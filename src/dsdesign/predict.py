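"""Parameter-set prediction for phenotypes and phenotype ensembles.

All predictions are linear programs over boundary polytopes in log10
parameter space:

* single-case sets near a vertex (zero or power-law objective) or in the
  interior (max-min slack, then an L1 tie-break for determinism);
* global tolerances by one-dimensional reduction of the boundary rows;
* ensembles -- case *intersections* (stack all members' boundary rows over
  the shared parameters, i.e. coexisting fixed points/multistability) and
  case *co-localizations* (each member receives its own replicated copies
  ``$V_i`` of the slice variables, so the members are simultaneously valid
  within a slice of design space), optionally with additional power-law
  *arrangement* constraints among the replicated variables;
* breadth-first search for maximal stable intersections, pruned by the
  monotone infeasibility of supersets;
* quadrant occupancy analysis of steady-state attractors relative to free
  thresholds.
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from . import lp
from .cases import Case, DesignSpace, _logpoint, _split_bounds, constraint_row
from .errors import NoSolutionError, VariableDomainError
from .linsys import LinearInequalitySystem

ParameterSet = Dict[str, float]

TOLERANCE_FLOOR = 1e-20
TOLERANCE_CEIL = 1e20


# ---------------------------------------------------------------------------
# single-case predictions
# ---------------------------------------------------------------------------

def _case_polytope(case: Case, constraints: Sequence[str]) -> LinearInequalitySystem:
    boundary = case.boundary_conditions()
    if boundary is None:
        raise NoSolutionError(
            f"case {case.number} has no steady-state solution, hence no "
            "phenotypic polytope"
        )
    lis = LinearInequalitySystem(boundary.variables, list(boundary.rows))
    for text in constraints:
        lis.rows.append(case._substitute_row(constraint_row(text)))
    return lis


def _objective_coeffs(case: Case, objective: str) -> Dict[str, float]:
    row = case._substitute_row(constraint_row(f"{objective} > 1"))
    return {n: float(c) for n, c in row.coeffs.items()}


def valid_parameter_set(
    case: Case,
    p_bounds: Optional[Mapping] = None,
    objective: Optional[str] = None,
    constraints: Sequence[str] = (),
) -> ParameterSet:
    """A parameter set realizing the phenotype, near a vertex of its
    feasible region; with a power-law ``objective`` the LP optimum of its
    log-linear form is returned."""
    lis = _case_polytope(case, constraints)
    bounds, fixed = _split_bounds(p_bounds)
    if fixed:
        bounds = dict(bounds or {})
        bounds.update({n: (v, v) for n, v in fixed.items()})
    point = lp.vertex_point(
        lis,
        objective=_objective_coeffs(case, objective) if objective else None,
        delta=case.design_space.delta,
        box=case.design_space.box,
        p_bounds=bounds,
    )
    return {n: 10.0 ** y for n, y in point.items()}


def valid_interior_parameter_set(
    case: Case,
    p_bounds: Optional[Mapping] = None,
    constraints: Sequence[str] = (),
) -> ParameterSet:
    """A parameter set in the interior of the phenotype's feasible region
    (every boundary row satisfied with positive slack)."""
    lis = _case_polytope(case, constraints)
    bounds, fixed = _split_bounds(p_bounds)
    if fixed:
        bounds = dict(bounds or {})
        bounds.update({n: (v, v) for n, v in fixed.items()})
    point = lp.interior_point(
        lis,
        delta=case.design_space.delta,
        box=case.design_space.box,
        p_bounds=bounds,
    )
    return {n: 10.0 ** y for n, y in point.items()}


def measure_tolerances(
    case: Case, pvals: Mapping[str, float]
) -> Dict[str, Tuple[float, float]]:
    """Global tolerances: per parameter, the (fold-decrease, fold-increase)
    from the reference point to the nearest boundary of the enclosing
    phenotypic polytope, all other parameters held fixed.

    Each boundary row reduces to a closed-form bound on the one free
    log-parameter (the spec'd series of 1-D LPs); saturated directions are
    reported as the box limits 1e-20 / 1e20 exactly.
    """
    boundary = case.boundary_conditions()
    if boundary is None:
        raise NoSolutionError(f"case {case.number} has no phenotypic polytope")
    names = case.system.independent_variables
    logpoint = _logpoint(names, pvals)
    if not boundary.contains(logpoint, tol=1e-9):
        raise VariableDomainError(
            "reference parameter set is outside the phenotypic polytope"
        )
    box_lo, box_hi = case.design_space.box
    tolerances: Dict[str, Tuple[float, float]] = {}
    for name in names:
        cur = logpoint[name]
        lo, hi = box_lo, box_hi
        for row in boundary.rows:
            c = float(row.coeffs.get(name, 0))
            if c == 0:
                continue
            rest = row.evaluate(logpoint) - c * cur
            bound = -rest / c
            if row.rel == "=":
                lo, hi = max(lo, bound), min(hi, bound)
            elif c > 0:
                lo = max(lo, bound)
            else:
                hi = min(hi, bound)
        fold_dec = (
            TOLERANCE_FLOOR if lo <= box_lo + 1e-12 else 10.0 ** (lo - cur)
        )
        fold_inc = (
            TOLERANCE_CEIL if hi >= box_hi - 1e-12 else 10.0 ** (hi - cur)
        )
        tolerances[name] = (
            min(max(fold_dec, TOLERANCE_FLOOR), TOLERANCE_CEIL),
            min(max(fold_inc, TOLERANCE_FLOOR), TOLERANCE_CEIL),
        )
    return tolerances


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

class Ensemble:
    """An intersection or co-localization of cases.

    For a co-localization each member case ``i`` receives replicated copies
    of the slice variables named ``$V_i``; power-law constraints among the
    replicated variables express arrangements of the members within the
    slice.
    """

    def __init__(
        self,
        cases: Sequence[Case],
        kind: str = "intersection",
        slice_variables: Sequence[str] = (),
        constraints: Sequence[str] = (),
    ):
        if not cases:
            raise VariableDomainError("an ensemble needs at least one case")
        if kind not in ("intersection", "colocalization"):
            raise VariableDomainError(f"unknown ensemble kind {kind!r}")
        if kind == "intersection" and slice_variables:
            raise VariableDomainError("intersections have no slice variables")
        system = cases[0].system
        for case in cases:
            if case.system is not system:
                raise VariableDomainError("all cases must come from one system")
        for v in slice_variables:
            if v not in system.independent_variables:
                raise VariableDomainError(
                    f"slice variable {v} is not an independent variable"
                )
        self.cases = list(cases)
        self.kind = kind
        self.slice_variables = list(slice_variables)
        self.constraints = list(constraints)
        self.design_space = cases[0].design_space
        self._system: Optional[LinearInequalitySystem] = None
        self._unsolvable = False

    @property
    def case_numbers(self) -> List[int]:
        return [c.number for c in self.cases]

    def replicated_name(self, variable: str, index: int) -> str:
        return f"${variable}_{index}"

    def feasibility_system(self) -> Optional[LinearInequalitySystem]:
        """The stacked log-linear system over the shared parameters plus any
        replicated slice variables; ``None`` if a member lacks a solution."""
        if self._system is not None or self._unsolvable:
            return self._system
        base = self.cases[0].system
        shared = [
            n for n in base.independent_variables if n not in self.slice_variables
        ]
        variables = list(shared)
        for i in range(len(self.cases)):
            for v in self.slice_variables:
                variables.append(self.replicated_name(v, i))
        lis = LinearInequalitySystem(variables)
        for i, case in enumerate(self.cases):
            boundary = case.boundary_conditions()
            if boundary is None:
                self._unsolvable = True
                return None
            mapping = {
                v: self.replicated_name(v, i) for v in self.slice_variables
            }
            for row in boundary.rows:
                lis.rows.append(row.renamed(mapping))
        for text in self.constraints:
            row = constraint_row(text)
            for name in row.coeffs:
                if name not in variables:
                    raise VariableDomainError(
                        f"ensemble constraint references unknown variable {name}"
                    )
            lis.rows.append(row)
        self._system = lis
        return lis

    def is_valid(self, p_bounds: Optional[Mapping] = None) -> bool:
        lis = self.feasibility_system()
        if lis is None:
            return False
        bounds, fixed = _split_bounds(p_bounds)
        return lp.feasible(
            lis,
            delta=self.design_space.delta,
            box=self.design_space.box,
            p_bounds=bounds,
            fixed=fixed,
        )

    def valid_parameter_set(self, **kwargs) -> ParameterSet:
        return self._parameter_set(interior=False, **kwargs)

    def valid_interior_parameter_set(self, **kwargs) -> ParameterSet:
        return self._parameter_set(interior=True, **kwargs)

    def _parameter_set(
        self, interior: bool, p_bounds: Optional[Mapping] = None
    ) -> ParameterSet:
        lis = self.feasibility_system()
        if lis is None:
            raise NoSolutionError("ensemble contains a case without a solution")
        bounds, fixed = _split_bounds(p_bounds)
        if fixed:
            bounds = dict(bounds or {})
            bounds.update({n: (v, v) for n, v in fixed.items()})
        if interior:
            point = lp.interior_point(
                lis,
                delta=self.design_space.delta,
                box=self.design_space.box,
                p_bounds=bounds,
            )
        else:
            point = lp.vertex_point(
                lis,
                delta=self.design_space.delta,
                box=self.design_space.box,
                p_bounds=bounds,
            )
        return {n: 10.0 ** y for n, y in point.items()}

    def member_parameter_sets(self, values: Mapping[str, float]) -> List[ParameterSet]:
        """Expand an ensemble parameter set into one complete set per member
        (replicated slice values substituted back under their own names)."""
        out = []
        for i in range(len(self.cases)):
            pv = {
                n: values[n]
                for n in self.cases[0].system.independent_variables
                if n not in self.slice_variables
            }
            for v in self.slice_variables:
                pv[v] = values[self.replicated_name(v, i)]
            out.append(pv)
        return out

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "cases": self.case_numbers,
            "slice_variables": self.slice_variables,
            "constraints": self.constraints,
        }

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Ensemble {self.kind} {self.case_numbers}>"


def make_intersection(cases: Sequence[Case], constraints: Sequence[str] = ()) -> Ensemble:
    return Ensemble(cases, "intersection", (), constraints)


def make_colocalization(
    cases: Sequence[Case],
    slice_variables: Sequence[str],
    constraints: Sequence[str] = (),
) -> Ensemble:
    return Ensemble(cases, "colocalization", slice_variables, constraints)


# ---------------------------------------------------------------------------
# stable-intersection search
# ---------------------------------------------------------------------------

def intersecting_cases(
    ds: DesignSpace,
    sizes: Iterable[int],
    case_numbers: Sequence[int],
) -> List[Ensemble]:
    """All valid intersections among ``case_numbers`` whose member count
    falls in ``sizes``, found by breadth-first subset growth.

    Adding boundary rows can only shrink a polytope, so a superset of an
    infeasible combination is never tested (monotone-infeasibility pruning);
    the search stops at the first empty level.
    """
    sizes = sorted(set(int(s) for s in sizes))
    if not sizes or sizes[0] < 1:
        raise VariableDomainError("sizes must be positive integers")
    numbers = sorted(set(case_numbers))
    results: List[Ensemble] = []
    level: List[Tuple[int, ...]] = [(n,) for n in numbers]
    if 1 in sizes:
        results.extend(make_intersection([ds(n)]) for n in numbers)
    k = 2
    level_set = set(level)
    while level and k <= sizes[-1]:
        next_level: List[Tuple[int, ...]] = []
        for combo in level:
            for c in numbers:
                if c <= combo[-1]:
                    continue
                cand = combo + (c,)
                if any(
                    cand[:i] + cand[i + 1 :] not in level_set
                    for i in range(len(cand))
                ):
                    continue
                ens = make_intersection([ds(n) for n in cand])
                if ens.is_valid():
                    next_level.append(cand)
                    if k in sizes:
                        results.append(ens)
        level, level_set = next_level, set(next_level)
        k += 1
    return results


def count_attractors_at(
    ds: DesignSpace, pvals: Mapping[str, float]
) -> Tuple[int, int]:
    """(stable, unstable) fixed-point counts at one parameter set: among the
    cases whose polytope contains the point, those with zero eigenvalues of
    positive real part are stable."""
    stable = unstable = 0
    for number in ds.valid_cases_at_point(pvals):
        if ds(number).ssystem.positive_roots(pvals) == 0:
            stable += 1
        else:
            unstable += 1
    return stable, unstable


# ---------------------------------------------------------------------------
# quadrant occupancy of steady-state attractors
# ---------------------------------------------------------------------------

QUADRANTS = ("--", "-+", "+-", "++")


def quadrant_constraints(
    quadrant: str,
    state_variables: Tuple[str, str] = ("X1", "X2"),
    thresholds: Tuple[str, str] = ("Xr1", "Xr2"),
) -> List[str]:
    """Power-law constraints pinning a case's steady state into one of the
    four quadrants defined by the thresholds (e.g. '-+' means X1 < Xr1 and
    X2 > Xr2)."""
    out = []
    for sign, var, thr in zip(quadrant, state_variables, thresholds):
        rel = "<" if sign == "-" else ">"
        out.append(f"{var} {rel} {thr}")
    return out


def quadrant_multisets(size: int = 4) -> List[Tuple[str, ...]]:
    """All multisets of ``size`` quadrant occupancies (35 for size 4)."""
    return list(itertools.combinations_with_replacement(QUADRANTS, size))


def arrangement_feasible(
    ds: DesignSpace,
    member_numbers: Sequence[int],
    quadrants: Sequence[str],
    state_variables: Tuple[str, str] = ("X1", "X2"),
    thresholds: Tuple[str, str] = ("Xr1", "Xr2"),
) -> bool:
    """Feasibility of one assignment of member cases to quadrants (the
    thresholds enter as free independent variables of ``ds``)."""
    members = [
        ds(n, constraints=quadrant_constraints(q, state_variables, thresholds))
        for n, q in zip(member_numbers, quadrants)
    ]
    return make_intersection(members).is_valid()


def satisfiable_quadrant_multisets(
    ds: DesignSpace,
    ensembles: Sequence[Sequence[int]],
    state_variables: Tuple[str, str] = ("X1", "X2"),
    thresholds: Tuple[str, str] = ("Xr1", "Xr2"),
) -> List[Tuple[str, ...]]:
    """The quadrant-occupancy multisets realizable by at least one ensemble
    under some assignment of its member cases to the multiset's quadrants.

    ``ds`` must declare the thresholds as extra independent variables.
    """
    satisfiable = []
    for multiset in quadrant_multisets():
        found = False
        for members in ensembles:
            for assignment in sorted(set(itertools.permutations(multiset))):
                if arrangement_feasible(
                    ds, members, assignment, state_variables, thresholds
                ):
                    found = True
                    break
            if found:
                break
        if found:
            satisfiable.append(multiset)
    return satisfiable
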