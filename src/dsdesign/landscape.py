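"""Design-space slices, state-space deconstruction, fixed points, and
simulation of the full GMA dynamics.

Slices classify a 2-D log-uniform grid of parameter values by the set of
phenotypes valid at each point (overlaps mark coexisting fixed points) or by
the total number of eigenvalues with positive real part (0 = monostable,
1 = bistable with its unstable companion, ...).  State-space grids classify
points by the signs of the dominant net rates per ODE (four trajectory
classes in 2-D), locate fixed points case by case with Newton refinement
against the full equations, integrate trajectories with bolus events, and
map basins of attraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .cases import DesignSpace
from .errors import DSError, VariableDomainError
from .gma import GMASystem


# ---------------------------------------------------------------------------
# auxiliary-variable elimination for numeric work
# ---------------------------------------------------------------------------

def solve_auxiliaries(
    system: GMASystem, env: Dict[str, float]
) -> Dict[str, float]:
    """Solve each zero-constraint for its auxiliary variable.

    Works for constraints in which the auxiliary appears in exactly one
    term, alone and with exponent +/-1 (the form produced by recasting);
    constraints may depend on other auxiliaries as long as the dependency
    graph is acyclic (resolved by fixed-point iteration over the list).
    """
    env = dict(env)
    constraints = [
        (aux, eq)
        for aux, eq in zip(
            system.auxiliary_variables, system.equations[system.n_t :]
        )
    ]
    pending = list(constraints)
    for _ in range(len(pending) + 1):
        still = []
        for aux, eq in pending:
            hits = [
                (sign, t)
                for sign, terms in ((1, eq.positive_terms), (-1, eq.negative_terms))
                for t in terms
                if aux in t.factors
            ]
            if len(hits) != 1 or set(hits[0][1].factors) != {aux} or abs(
                hits[0][1].factors[aux]
            ) != 1:
                raise DSError(
                    f"constraint for {aux} is not explicitly solvable"
                )
            sign, aux_term = hits[0]
            try:
                others = 0.0
                for s, terms in ((1, eq.positive_terms), (-1, eq.negative_terms)):
                    for t in terms:
                        if t is aux_term:
                            continue
                        others += s * t.evaluate(env)
            except KeyError:
                still.append((aux, eq))
                continue
            # sign * c * aux^e + others = 0
            e = aux_term.factors[aux]
            value = -others / (sign * aux_term.coefficient)
            if value <= 0:
                raise VariableDomainError(
                    f"auxiliary {aux} solves to a non-positive value"
                )
            env[aux] = value ** (1.0 / float(e))
        pending = still
        if not pending:
            return {a: env[a] for a, _ in constraints}
    raise DSError("auxiliary constraints are cyclically coupled")


def full_rhs(system: GMASystem, pvals: Mapping[str, float]):
    """Return f(state_dict) -> derivative dict for the full GMA ODEs with
    auxiliaries eliminated pointwise."""
    base_env = {
        n: float(pvals[n]) for n in system.independent_variables
    }

    def f(state: Mapping[str, float]) -> Dict[str, float]:
        env = dict(base_env)
        env.update(state)
        env.update(solve_auxiliaries(system, env))
        out = {}
        for eq in system.equations[: system.n_t]:
            pos, neg, net = eq.evaluate(env)
            out[eq.variable] = net
        return out

    return f


# ---------------------------------------------------------------------------
# 2-D slices of design space
# ---------------------------------------------------------------------------

@dataclass
class SliceSpec:
    x_variable: str
    y_variable: str
    x_range: Tuple[float, float]
    y_range: Tuple[float, float]
    resolution: int = 100
    reference: Mapping[str, float] = field(default_factory=dict)

    def axes(self) -> Tuple[np.ndarray, np.ndarray]:
        if not (
            0 < self.x_range[0] < self.x_range[1]
            and 0 < self.y_range[0] < self.y_range[1]
        ):
            raise VariableDomainError("slice ranges must be positive and increasing")
        x = np.logspace(
            math.log10(self.x_range[0]), math.log10(self.x_range[1]), self.resolution
        )
        y = np.logspace(
            math.log10(self.y_range[0]), math.log10(self.y_range[1]), self.resolution
        )
        return x, y


@dataclass
class SliceResult:
    x: np.ndarray
    y: np.ndarray
    #: labels[iy][ix] -- tuple of valid case numbers (or an int count)
    labels: list

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for iy, yv in enumerate(self.y):
            for ix, xv in enumerate(self.x):
                label = self.labels[iy][ix]
                if isinstance(label, tuple):
                    label = "|".join(str(c) for c in label)
                records.append({"x": xv, "y": yv, "label": label})
        return pd.DataFrame.from_records(records)


def _case_row_arrays(ds: DesignSpace, spec: SliceSpec):
    """Precompute, per valid-case boundary row: slack = base + cx*logx + cy*logy."""
    xv, yv = spec.x_variable, spec.y_variable
    names = ds.system.independent_variables
    for name in (xv, yv):
        if name not in names:
            raise VariableDomainError(f"{name} is not an independent variable")
    logref = {}
    for name in names:
        if name in (xv, yv):
            continue
        if name not in spec.reference:
            raise VariableDomainError(f"no reference value for {name}")
        logref[name] = math.log10(spec.reference[name])
    out = []
    for number in ds.valid_cases():
        case = ds(number)
        boundary = case.boundary_conditions()
        base, cx, cy = [], [], []
        for row in boundary.rows:
            b = row.const + sum(
                float(c) * logref[n]
                for n, c in row.coeffs.items()
                if n not in (xv, yv)
            )
            base.append(b)
            cx.append(float(row.coeffs.get(xv, 0)))
            cy.append(float(row.coeffs.get(yv, 0)))
        out.append((number, np.array(base), np.array(cx), np.array(cy)))
    return out


def classify_slice(
    ds: DesignSpace,
    spec: SliceSpec,
    intersections: Optional[Sequence[int]] = None,
) -> SliceResult:
    """Valid case numbers at each grid point of a 2-D log-uniform slice.

    With ``intersections`` given, only points whose number of coexisting
    cases is in the list keep their labels (others get an empty tuple),
    mirroring the overlap-highlighting of design-space plots.
    """
    x, y = spec.axes()
    lx, ly = np.log10(x), np.log10(y)
    rows = _case_row_arrays(ds, spec)
    labels = []
    for yv in ly:
        line = []
        for xv in lx:
            cases = tuple(
                number
                for number, base, cx, cy in rows
                if np.all(base + cx * xv + cy * yv >= -1e-9)
            )
            if intersections is not None and len(cases) not in intersections:
                cases = ()
            line.append(cases)
        labels.append(line)
    return SliceResult(x, y, labels)


def positive_roots_slice(ds: DesignSpace, spec: SliceSpec) -> SliceResult:
    """Total number of eigenvalues with positive real part, summed over the
    cases valid at each grid point (0 = monostable region, 1 = bistable)."""
    x, y = spec.axes()
    lx, ly = np.log10(x), np.log10(y)
    rows = _case_row_arrays(ds, spec)
    roots_cache: Dict[Tuple[int, int, int], int] = {}
    labels = []
    for iy, yv in enumerate(ly):
        line = []
        for ix, xv in enumerate(lx):
            total = 0
            for number, base, cx, cy in rows:
                if np.all(base + cx * xv + cy * yv >= -1e-9):
                    pvals = dict(spec.reference)
                    pvals[spec.x_variable] = 10.0 ** xv
                    pvals[spec.y_variable] = 10.0 ** yv
                    total += ds(number).ssystem.positive_roots(pvals)
            line.append(total)
        labels.append(line)
    return SliceResult(x, y, labels)


# ---------------------------------------------------------------------------
# state-space deconstruction
# ---------------------------------------------------------------------------

#: direction classes in 2-D state space keyed by the sign pair
#: (sign dX1/dt, sign dX2/dt); east/north = increasing
DIRECTION_CLASSES = {
    (1, 1): "NE",
    (-1, 1): "NW",
    (1, -1): "SE",
    (-1, -1): "SW",
}


def trajectory_classes(
    system: GMASystem,
    pvals: Mapping[str, float],
    x_range: Tuple[float, float],
    y_range: Tuple[float, float],
    resolution: int = 60,
    variables: Optional[Tuple[str, str]] = None,
) -> SliceResult:
    """Qualitative trajectory direction at each point of a 2-D state grid,
    from the signs of (dominant positive term - dominant negative term) per
    ODE.  Dominance at a state point is a numeric ranking of term values."""
    if variables is None:
        variables = tuple(system.dynamic_variables[:2])
    xv, yv = variables
    x = np.logspace(math.log10(x_range[0]), math.log10(x_range[1]), resolution)
    y = np.logspace(math.log10(y_range[0]), math.log10(y_range[1]), resolution)
    base_env = {n: float(pvals[n]) for n in system.independent_variables}
    odes = {eq.variable: eq for eq in system.equations[: system.n_t]}
    labels = []
    for yval in y:
        line = []
        for xval in x:
            env = dict(base_env)
            env[xv], env[yv] = xval, yval
            env.update(solve_auxiliaries(system, env))
            signs = []
            for var in (xv, yv):
                eq = odes[var]
                dom_pos = max(t.evaluate(env) for t in eq.positive_terms)
                dom_neg = max(t.evaluate(env) for t in eq.negative_terms)
                signs.append(1 if dom_pos >= dom_neg else -1)
            line.append(DIRECTION_CLASSES[tuple(signs)])
        labels.append(line)
    return SliceResult(x, y, labels)


# ---------------------------------------------------------------------------
# fixed points
# ---------------------------------------------------------------------------

@dataclass
class FixedPoint:
    location: Dict[str, float]
    originating_case: int
    stable: bool
    refined: bool
    residual: float
    quadrant: Optional[str] = None


def _relative_residual(system: GMASystem, env: Dict[str, float]) -> float:
    worst = 0.0
    for eq in system.equations[: system.n_t]:
        pos, neg, net = eq.evaluate(env)
        worst = max(worst, abs(net) / max(pos, neg))
    return worst


def _full_jacobian(f, state: Dict[str, float], names: Sequence[str]) -> np.ndarray:
    n = len(names)
    J = np.zeros((n, n))
    f0 = f(state)
    for j, name in enumerate(names):
        h = 1e-6 * state[name]
        up = dict(state)
        up[name] = state[name] + h
        dn = dict(state)
        dn[name] = state[name] - h
        fu, fd = f(up), f(dn)
        for i, ni in enumerate(names):
            J[i, j] = (fu[ni] - fd[ni]) / (2 * h)
    return J


def _newton_refine(f, state: Dict[str, float], names: Sequence[str],
                   max_iter: int = 50):
    """Damped Newton iteration in log-state coordinates (positivity is
    preserved by construction).  Returns (state, converged)."""
    z = np.array([math.log(state[n]) for n in names])

    def resid(zv):
        st = {n: math.exp(v) for n, v in zip(names, zv)}
        fv = f(st)
        return st, np.array([fv[n] for n in names])

    st, r = resid(z)
    for _ in range(max_iter):
        if np.max(np.abs(r)) == 0:
            break
        Jx = _full_jacobian(f, st, names)
        x = np.array([st[n] for n in names])
        Jz = Jx * x[np.newaxis, :]
        try:
            step = np.linalg.solve(Jz, -r)
        except np.linalg.LinAlgError:
            return st, False
        norm0 = np.linalg.norm(r)
        damping, improved = 1.0, False
        for _ in range(30):
            st2, r2 = resid(z + damping * step)
            if np.linalg.norm(r2) < norm0:
                z, st, r = z + damping * step, st2, r2
                improved = True
                break
            damping /= 2
        if not improved:
            break
        if np.linalg.norm(r) < 1e-13 * max(1.0, np.linalg.norm(x)):
            break
    return st, True


def find_fixed_points(
    ds: DesignSpace,
    pvals: Mapping[str, float],
    refine: bool = True,
    thresholds: Optional[Mapping[str, float]] = None,
) -> List[FixedPoint]:
    """Fixed points of the full system at a parameter set: one candidate per
    valid case (its S-system steady state), optionally Newton-refined
    against the full GMA right-hand sides; near-duplicates (relative
    log-distance < 1e-6) are merged keeping the refined representative, and
    stability is re-evaluated on the full-system Jacobian."""
    system = ds.system
    names = system.dynamic_variables
    f = full_rhs(system, pvals)
    points: List[FixedPoint] = []
    for number in ds.valid_cases_at_point(pvals):
        case = ds(number)
        ss = case.ssystem.steady_state(pvals)
        state = {n: ss[n] for n in names}
        refined = False
        if refine:
            state, refined = _newton_refine(f, state, names)
        env = {n: float(pvals[n]) for n in system.independent_variables}
        env.update(state)
        env.update(solve_auxiliaries(system, env))
        residual = _relative_residual(system, env)
        J = _full_jacobian(f, state, names)
        eig = np.linalg.eigvals(J)
        stable = bool(np.all(eig.real < 0))
        quadrant = None
        if thresholds:
            signs = []
            for n in names[:2]:
                thr = thresholds.get(n)
                if thr is not None:
                    signs.append("+" if state[n] > thr else "-")
            quadrant = "".join(signs) if signs else None
        points.append(
            FixedPoint(state, number, stable, refined, residual, quadrant)
        )
    # merge duplicates, preferring refined representatives
    merged: List[FixedPoint] = []
    for fp in sorted(points, key=lambda p: (not p.refined, p.residual)):
        dup = False
        for kept in merged:
            dist = max(
                abs(math.log10(fp.location[n]) - math.log10(kept.location[n]))
                for n in names
            )
            if dist < 1e-6:
                dup = True
                break
        if not dup:
            merged.append(fp)
    merged.sort(key=lambda p: p.originating_case)
    return merged


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # (len(times), n_t)
    variables: List[str]
    events: List[Tuple[float, str, float]]

    def state_at_end(self) -> Dict[str, float]:
        return dict(zip(self.variables, self.states[-1]))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.variables)
        df.insert(0, "t", self.times)
        return df


def simulate(
    system: GMASystem,
    pvals: Mapping[str, float],
    initial_state: Mapping[str, float],
    t_end: float,
    boluses: Sequence[Tuple[float, str, float]] = (),
    points_per_segment: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the full GMA ODEs (auxiliaries eliminated pointwise) in
    log-state coordinates, applying bolus additions (time, variable, amount)
    as instantaneous jumps.  Log coordinates keep every state strictly
    positive."""
    names = system.dynamic_variables
    for n in names:
        if n not in initial_state or not initial_state[n] > 0:
            raise VariableDomainError(f"initial state for {n} must be positive")
    f = full_rhs(system, pvals)

    def rhs_log(t, z):
        state = {n: math.exp(v) for n, v in zip(names, z)}
        fv = f(state)
        return [fv[n] / state[n] for n in names]

    events = sorted(
        [(float(t), v, float(a)) for t, v, a in boluses], key=lambda e: e[0]
    )
    for t, v, a in events:
        if v not in names:
            raise VariableDomainError(f"bolus variable {v} is not dynamic")
        if not 0 <= t <= t_end:
            raise VariableDomainError("bolus time outside the simulation window")
    breakpoints = [0.0] + [e[0] for e in events] + [float(t_end)]
    state = {n: float(initial_state[n]) for n in names}
    all_t, all_x = [], []
    ei = 0
    for seg in range(len(breakpoints) - 1):
        t0, t1 = breakpoints[seg], breakpoints[seg + 1]
        if t1 > t0:
            z0 = [math.log(state[n]) for n in names]
            t_eval = np.linspace(t0, t1, points_per_segment)
            sol = solve_ivp(
                rhs_log,
                (t0, t1),
                z0,
                method="LSODA",
                t_eval=t_eval,
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise DSError(
                    f"integration failed at t={sol.t[-1] if len(sol.t) else t0}: "
                    f"{sol.message}; last state {state}"
                )
            all_t.append(sol.t)
            all_x.append(np.exp(sol.y.T))
            state = {n: float(np.exp(sol.y[i, -1])) for i, n in enumerate(names)}
        if ei < len(events) and abs(events[ei][0] - t1) < 1e-12:
            _, var, amount = events[ei]
            state[var] += amount
            ei += 1
    return Trajectory(
        np.concatenate(all_t) if all_t else np.array([0.0]),
        np.vstack(all_x) if all_x else np.array([[state[n] for n in names]]),
        list(names),
        events,
    )


# ---------------------------------------------------------------------------
# basins of attraction
# ---------------------------------------------------------------------------

def basins(
    system: GMASystem,
    pvals: Mapping[str, float],
    attractors: Sequence[FixedPoint],
    x_range: Tuple[float, float],
    y_range: Tuple[float, float],
    resolution: int = 60,
    variables: Optional[Tuple[str, str]] = None,
    t_chunk: float = 50.0,
    t_cap: float = 2000.0,
    tol: float = 1e-3,
) -> SliceResult:
    """Label each point of a 2-D state grid by the attractor its trajectory
    converges to (index into ``attractors``), or -1 if unresolved within the
    integration cap.  Convergence means relative log-distance < ``tol``."""
    if variables is None:
        variables = tuple(system.dynamic_variables[:2])
    xv, yv = variables
    names = system.dynamic_variables
    stable = [fp for fp in attractors if fp.stable]
    x = np.logspace(math.log10(x_range[0]), math.log10(x_range[1]), resolution)
    y = np.logspace(math.log10(y_range[0]), math.log10(y_range[1]), resolution)
    f = full_rhs(system, pvals)

    def rhs_log(t, z):
        state = {n: math.exp(v) for n, v in zip(names, z)}
        fv = f(state)
        return [fv[n] / state[n] for n in names]

    def nearest(state):
        for idx, fp in enumerate(stable):
            dist = max(
                abs(math.log10(state[n]) - math.log10(fp.location[n]))
                for n in names
            )
            if dist < tol:
                return idx
        return -1

    labels = []
    for yval in y:
        line = []
        for xval in x:
            state = {n: float(pvals.get(n, 1.0)) for n in names}
            # non-grid dynamic variables start at their median attractor level
            for n in names:
                if n not in (xv, yv) and stable:
                    state[n] = float(
                        np.median([fp.location[n] for fp in stable])
                    )
            state[xv], state[yv] = xval, yval
            label = nearest(state)
            t = 0.0
            while label < 0 and t < t_cap:
                z0 = [math.log(state[n]) for n in names]
                sol = solve_ivp(
                    rhs_log, (0.0, t_chunk), z0, method="LSODA",
                    rtol=1e-7, atol=1e-9,
                )
                if not sol.success:
                    break
                state = {
                    n: float(np.exp(sol.y[i, -1])) for i, n in enumerate(names)
                }
                t += t_chunk
                label = nearest(state)
            line.append(label)
        labels.append(line)
    return SliceResult(x, y, labels)
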