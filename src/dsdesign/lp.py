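"""Deterministic linear-programming backend (scipy HiGHS).

All feasibility and prediction questions in the toolkit reduce to LPs over
log10-space polytopes.  Strict dominance inequalities are relaxed to ``>=``
and interior/validity tests require a uniform slack ``delta`` (default 1e-6
log10 units): an LP cannot express strict inequalities and the measure-zero
boundaries are immaterial to the phenotypic repertoire.  The global box is
[-20, 20] in log10 for every quantity, i.e. values in [1e-20, 1e20].

HiGHS with fixed options is deterministic for fixed input, which makes every
prediction reproducible.
"""

from __future__ import annotations

import math
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy.optimize import linprog

from .errors import NoSolutionError
from .linsys import LinearInequalitySystem

DEFAULT_BOX = (-20.0, 20.0)
DEFAULT_DELTA = 1e-6
SLACK_CAP = 1.0  # per-row slack cap (log10 units) for interior points


def _log_bounds(
    lis: LinearInequalitySystem,
    box: Tuple[float, float],
    p_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    fixed: Optional[Mapping[str, float]] = None,
):
    """Per-variable (lo, hi) log10 bounds."""
    bounds = []
    for name in lis.variables:
        lo, hi = box
        if p_bounds and name in p_bounds:
            blo, bhi = p_bounds[name]
            lo, hi = max(lo, math.log10(blo)), min(hi, math.log10(bhi))
        if fixed and name in fixed:
            v = math.log10(fixed[name])
            lo = hi = v
        bounds.append((lo, hi))
    return bounds


def _matrices(lis: LinearInequalitySystem, delta: float):
    """Rows as A_ub x <= b_ub / A_eq x = b_eq for scipy's canonical form."""
    index = {n: j for j, n in enumerate(lis.variables)}
    nv = len(lis.variables)
    A_ub, b_ub, A_eq, b_eq = [], [], [], []
    for row in lis.rows:
        vec = np.zeros(nv)
        for n, c in row.coeffs.items():
            vec[index[n]] = float(c)
        if row.rel == "=":
            A_eq.append(vec)
            b_eq.append(-row.const)
        else:  # coeffs.y + const >= delta  ->  -coeffs.y <= const - delta
            A_ub.append(-vec)
            b_ub.append(row.const - delta)
    return (
        np.array(A_ub) if A_ub else None,
        np.array(b_ub) if b_ub else None,
        np.array(A_eq) if A_eq else None,
        np.array(b_eq) if b_eq else None,
    )


def _solve(c, A_ub, b_ub, A_eq, b_eq, bounds):
    return linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )


def feasible(
    lis: LinearInequalitySystem,
    delta: float = DEFAULT_DELTA,
    box: Tuple[float, float] = DEFAULT_BOX,
    p_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    fixed: Optional[Mapping[str, float]] = None,
) -> bool:
    """True iff the polytope has a point with slack >= delta on every row."""
    bounds = _log_bounds(lis, box, p_bounds, fixed)
    if any(lo > hi for lo, hi in bounds):
        return False
    A_ub, b_ub, A_eq, b_eq = _matrices(lis, delta)
    res = _solve(np.zeros(len(lis.variables)), A_ub, b_ub, A_eq, b_eq, bounds)
    return res.status == 0


def vertex_point(
    lis: LinearInequalitySystem,
    objective: Optional[Mapping[str, float]] = None,
    sense: str = "max",
    delta: float = DEFAULT_DELTA,
    box: Tuple[float, float] = DEFAULT_BOX,
    p_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> Dict[str, float]:
    """A feasible point of the polytope in log10 coordinates.

    With an objective (a log-linear form given as name -> coefficient) the LP
    optimum is returned; otherwise the zero objective yields a basic feasible
    point near a vertex.
    """
    bounds = _log_bounds(lis, box, p_bounds)
    A_ub, b_ub, A_eq, b_eq = _matrices(lis, delta)
    c = np.zeros(len(lis.variables))
    if objective:
        for name, coeff in objective.items():
            if name in lis.variables:
                c[lis.variables.index(name)] = float(coeff)
        if sense == "max":
            c = -c
    res = _solve(c, A_ub, b_ub, A_eq, b_eq, bounds)
    if res.status != 0:
        raise NoSolutionError(
            "polytope is infeasible", certificate=res.message
        )
    return {n: float(v) for n, v in zip(lis.variables, res.x)}


def interior_point(
    lis: LinearInequalitySystem,
    delta: float = DEFAULT_DELTA,
    box: Tuple[float, float] = DEFAULT_BOX,
    p_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    cap: float = SLACK_CAP,
) -> Dict[str, float]:
    """A deterministic interior point: maximise the minimum row slack (capped
    at ``cap`` log10 units so unbounded regions stay well-posed), then break
    LP degeneracy by minimising the L1 norm of the log-coordinates at that
    slack.  For a region with no rows this returns the box centre (all ones).
    """
    bounds = _log_bounds(lis, box, p_bounds)
    if any(lo > hi for lo, hi in bounds):
        raise NoSolutionError("bounds are empty")
    index = {n: j for j, n in enumerate(lis.variables)}
    nv = len(lis.variables)

    # stage 1: max t subject to each ">=" row having slack >= t, 0 <= t <= cap
    A_ub, b_ub, A_eq, b_eq = [], [], [], []
    for row in lis.rows:
        vec = np.zeros(nv + 1)
        for n, c in row.coeffs.items():
            vec[index[n]] = float(c)
        if row.rel == "=":
            A_eq.append(vec)
            b_eq.append(-row.const)
        else:
            vec = -vec
            vec[nv] = 1.0  # -coeffs.y + t <= const
            A_ub.append(vec)
            b_ub.append(row.const)
    c1 = np.zeros(nv + 1)
    c1[nv] = -1.0
    res = _solve(
        c1,
        np.array(A_ub) if A_ub else None,
        np.array(b_ub) if b_ub else None,
        np.array(A_eq) if A_eq else None,
        np.array(b_eq) if b_eq else None,
        bounds + [(delta, cap)],
    )
    if res.status != 0:
        raise NoSolutionError(
            "no interior point with positive slack", certificate=res.message
        )
    t_star = res.x[nv]

    # stage 2: at slack t*, minimise sum_j |y_j| (deterministic tie-break)
    A_ub2, b_ub2, A_eq2, b_eq2 = [], [], [], []
    for row in lis.rows:
        vec = np.zeros(2 * nv)
        for n, c in row.coeffs.items():
            vec[index[n]] = float(c)
        if row.rel == "=":
            A_eq2.append(vec)
            b_eq2.append(-row.const)
        else:
            A_ub2.append(-vec)
            b_ub2.append(row.const - (t_star - 1e-9))
    for j in range(nv):  # u_j >= |y_j|
        for s in (1.0, -1.0):
            vec = np.zeros(2 * nv)
            vec[j] = s
            vec[nv + j] = -1.0
            A_ub2.append(vec)
            b_ub2.append(0.0)
    c2 = np.concatenate([np.zeros(nv), np.ones(nv)])
    span = max(abs(box[0]), abs(box[1]))
    res2 = _solve(
        c2,
        np.array(A_ub2),
        np.array(b_ub2),
        np.array(A_eq2) if A_eq2 else None,
        np.array(b_eq2) if b_eq2 else None,
        bounds + [(0.0, span)] * nv,
    )
    if res2.status != 0:  # numerically thin region: keep the stage-1 point
        return {n: float(v) for n, v in zip(lis.variables, res.x[:nv])}
    return {n: float(v) for n, v in zip(lis.variables, res2.x[:nv])}
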