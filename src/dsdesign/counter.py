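"""End-to-end counter demonstration on the memory circuit.

The memory circuit can hold four stable states, one per quadrant of the
(X1, X2) state plane.  Transient boluses of X1 walk the system forward
through three of them, (-,+) -> (+,+) -> (+,-), and boluses of X2 walk it
back -- a stable counter with a positive and a negative input channel.  A
reporter activated by X1 and repressed by X2 reads the count out as three
ordered expression levels.

Everything here is *predicted*, not hard-coded: the quadrastable parameter
set is the interior point of a size-4 stable intersection constrained to
one attractor per quadrant (thresholds at 1), the attractors come from the
fixed-point solver, and the bolus amount is calibrated to cross the
separatrices (the default candidate of 275 concentration units is kept
whenever the predicted instance supports the full cycle with it).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import fixtures
from .cases import DesignSpace
from .errors import DSError
from .landscape import FixedPoint, Trajectory, find_fixed_points, simulate
from .predict import (
    intersecting_cases,
    make_intersection,
    valid_interior_parameter_set,
)

QUADRANT_ORDER = ("--", "-+", "+-", "++")
DEFAULT_BOLUS = 275.0
#: count states in forward order and the channel variables
FORWARD_STATES = ("-+", "++", "+-")


def criteria_cases(ds: DesignSpace) -> List[int]:
    """Memory-circuit phenotypes that are locally stable at an interior
    point and have X1 and X2 uncoupled from the repressor X3."""
    out = []
    for n in ds.valid_cases():
        case = ds(n)
        if case.ssystem.log_gain("X1", "X3") != 0:
            continue
        if case.ssystem.log_gain("X2", "X3") != 0:
            continue
        pv = valid_interior_parameter_set(case)
        if case.ssystem.positive_roots(pv) == 0:
            out.append(n)
    return out


def quadrastable_instance(
    ds: Optional[DesignSpace] = None,
    members: Optional[Sequence[int]] = None,
) -> Tuple[Dict[str, float], Dict[str, FixedPoint], Tuple[int, ...]]:
    """Predict a parameter set with four stable attractors, one per quadrant
    of the (X1, X2) plane with thresholds at 1.

    Returns (pvals, attractors-by-quadrant, member case numbers).
    """
    if ds is None:
        ds = fixtures.MEMORY_CIRCUIT.design_space()
    if members is None:
        crit = criteria_cases(ds)
        quads = intersecting_cases(ds, [4], crit)
        candidates = [tuple(e.case_numbers) for e in quads]
    else:
        candidates = [tuple(members)]
    for cand in candidates:
        for perm in itertools.permutations(QUADRANT_ORDER):
            constrained = [
                ds(
                    n,
                    constraints=[
                        f"X1 {'<' if q[0] == '-' else '>'} 1",
                        f"X2 {'<' if q[1] == '-' else '>'} 1",
                    ],
                )
                for n, q in zip(cand, perm)
            ]
            ens = make_intersection(constrained)
            if not ens.is_valid():
                continue
            pvals = ens.valid_interior_parameter_set()
            points = find_fixed_points(
                ds, pvals, thresholds={"X1": 1.0, "X2": 1.0}
            )
            att = {fp.quadrant: fp for fp in points if fp.stable}
            if set(att) == set(QUADRANT_ORDER):
                return pvals, att, cand
    raise DSError("no quadrastable one-attractor-per-quadrant instance found")


def _quadrant(state: Mapping[str, float]) -> str:
    return ("+" if state["X1"] > 1 else "-") + ("+" if state["X2"] > 1 else "-")


def _step(system, pvals, state, channel, amount, t_settle):
    start = dict(state)
    start[channel] += amount
    traj = simulate(system, pvals, start, t_settle)
    return traj.state_at_end()


def supports_cycle(
    system,
    pvals: Mapping[str, float],
    attractors: Mapping[str, FixedPoint],
    amount: float,
    t_settle: float = 60.0,
) -> bool:
    """True iff ``amount`` drives the full forward cycle
    (-,+) -> (+,+) -> (+,-) via X1 and the reverse via X2."""
    names = system.dynamic_variables

    def restrict(loc):
        state = {n: loc.get(n, 1.0) for n in names}
        return state

    state = restrict(attractors["-+"].location)
    for expected in ("++", "+-"):
        state = _step(system, pvals, state, "X1", amount, t_settle)
        if _quadrant(state) != expected:
            return False
    for expected in ("++", "-+"):
        state = _step(system, pvals, state, "X2", amount, t_settle)
        if _quadrant(state) != expected:
            return False
    return True


def calibrate_bolus(
    system,
    pvals: Mapping[str, float],
    attractors: Mapping[str, FixedPoint],
    candidates: Sequence[float] = (DEFAULT_BOLUS, 100.0, 500.0, 50.0, 1000.0,
                                   30.0, 3000.0, 20.0, 10.0),
) -> float:
    """The first candidate bolus that crosses the separatrix in both
    directions (275 units preferred, the magnitude used in the printed
    simulations)."""
    for amount in candidates:
        if supports_cycle(system, pvals, attractors, amount):
            return amount
    raise DSError("no candidate bolus amount realizes the counter cycle")


@dataclass
class CounterDemo:
    pvals: Dict[str, float]          # memory-circuit parameters
    pvals_full: Dict[str, float]     # plus reporter parameters
    attractors: Dict[str, FixedPoint]
    members: Tuple[int, ...]
    bolus: float
    reporter_levels: Dict[str, float]  # quadrant -> steady X4
    trajectory: Trajectory            # Fig-8-style stimulation schedule


def run_counter_demo(
    ds: Optional[DesignSpace] = None,
    interval: float = 20.0,
    settle: float = 60.0,
) -> CounterDemo:
    """Predict a counter instance and simulate the stimulation schedule:
    two X1 boluses stepping the count up, a pause, then two X2 boluses
    stepping it back down, at regular ``interval`` time units."""
    pvals, attractors, members = quadrastable_instance(ds)
    system = fixtures.counter_system()
    pvals_full = {k: float(v) for k, v in pvals.items()}
    pvals_full.update(fixtures.COUNTER_REPORTER.default_parameters)
    # calibrate on the full system (the reporter does not feed back)
    bolus = calibrate_bolus(system, pvals_full, attractors)

    # steady reporter levels for the three counter states
    levels = {}
    for quadrant in FORWARD_STATES:
        state = {n: attractors[quadrant].location.get(n, 1.0)
                 for n in system.dynamic_variables}
        traj = simulate(system, pvals_full, state, 2 * settle)
        levels[quadrant] = float(traj.state_at_end()["X4"])

    start = {n: attractors["-+"].location.get(n, 1.0)
             for n in system.dynamic_variables}
    start["X4"] = levels["-+"]
    boluses = [
        (1 * interval, "X1", bolus),
        (2 * interval, "X1", bolus),
        (4 * interval, "X2", bolus),
        (5 * interval, "X2", bolus),
    ]
    trajectory = simulate(system, pvals_full, start, 7 * interval, boluses)
    return CounterDemo(
        pvals={k: float(v) for k, v in pvals.items()},
        pvals_full=pvals_full,
        attractors=attractors,
        members=members,
        bolus=bolus,
        reporter_levels=levels,
        trajectory=trajectory,
    )
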