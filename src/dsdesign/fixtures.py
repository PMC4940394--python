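"""Packaged circuit models.

Three gene-circuit models ship with the toolkit:

* ``simple_circuit`` -- a single gene regulator under positive autogenous
  control (dimeric activator, competitive repressor X3, heterodimer loss
  through partner protein X2), in recast GMA form with auxiliary X100.
  Conventions: the heterodimerization rate constant k defaults to 1 and the
  activation capacity rho1 carries the model-level constraint rho1 >= 1
  (a capacity below one would mean "activation" that represses).
* ``memory_circuit`` -- two such activators X1, X2 coupled by irreversible
  heterodimer formation and repressed by a common X3; recast GMA form with
  auxiliaries X100 and X200.  Capacities rho1, rho2 >= 1 as above.
* ``counter_reporter`` -- a reporter gene X4 activated by X1 and repressed
  by X2, turning the memory circuit into a counter whose readout steps
  through distinct expression levels.

Each fixture also carries its rational-rate-law source equations so the
recasting pipeline can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .cases import DesignSpace
from .gma import GMASystem, parse_model
from .parsing import parse_model_text
from .recast import recast


@dataclass
class FixtureModel:
    name: str
    description: str
    text: str  # model text format (equations + directives)
    rational_equations: List[str] = field(default_factory=list)
    default_parameters: Optional[Dict[str, float]] = None

    def parse(self, extra_independent=()) -> GMASystem:
        equations, auxiliaries, _ = parse_model_text(self.text)
        return parse_model(equations, auxiliaries, extra_independent)

    @property
    def constraints(self) -> List[str]:
        _, _, constraints = parse_model_text(self.text)
        return constraints

    def design_space(self, extra_independent=(), **kwargs) -> DesignSpace:
        return DesignSpace(
            self.parse(extra_independent),
            constraints=self.constraints,
            **kwargs,
        )


SIMPLE_CIRCUIT = FixtureModel(
    name="simple_circuit",
    description=(
        "Single-gene positive-autoregulation circuit with competitive "
        "repression and heterodimer loss (recast GMA form)"
    ),
    text="""\
# single positively-autoregulated gene; X2 heterodimer partner, X3 repressor
auxiliary: X100
constraint: rho1 >= 1
X1. = a1*X100^-1 + a1*rho1*X1^2*K1^-2*X100^-1 + a1*X3*K3^-1*X100^-1 - b1*X1 - k*X1*X2
0 = 1 + X1^2*K1^-2 + X3*K3^-1 - X100
""",
    rational_equations=[
        "X1. = a1*(1 + rho1*(X1/K1)^2 + X3/K3)/(1 + (X1/K1)^2 + X3/K3)"
        " - b1*X1 - k*X1*X2",
    ],
    default_parameters={
        "a1": 1.0,
        "b1": 10.0,
        "rho1": 10.0,
        "K1": 1.0,
        "K3": 10.0,
        "k": 1.0,
        "X2": 1.0,
        "X3": 1.0,
    },
)


MEMORY_CIRCUIT = FixtureModel(
    name="memory_circuit",
    description=(
        "Two-activator synthetic memory module: mutual heterodimer loss, "
        "common repressor X3 (recast GMA form)"
    ),
    text="""\
# two positively-autoregulated activators coupled by heterodimer formation
auxiliary: X100, X200
constraint: rho1 >= 1
constraint: rho2 >= 1
X1. = a1*X100^-1 + a1*rho1*X1^2*K1^-2*X100^-1 + a1*X3*K3^-1*X100^-1 - b1*X1 - k*X1*X2
X2. = a2*X200^-1 + a2*rho2*X2^2*K2^-2*X200^-1 + a2*X3*K3^-1*X200^-1 - b2*X2 - k*X1*X2
0 = 1 + X1^2*K1^-2 + X3*K3^-1 - X100
0 = 1 + X2^2*K2^-2 + X3*K3^-1 - X200
""",
    rational_equations=[
        "X1. = a1*(1 + rho1*(X1/K1)^2 + X3/K3)/(1 + (X1/K1)^2 + X3/K3)"
        " - b1*X1 - k*X1*X2",
        "X2. = a2*(1 + rho2*(X2/K2)^2 + X3/K3)/(1 + (X2/K2)^2 + X3/K3)"
        " - b2*X2 - k*X1*X2",
    ],
    default_parameters=None,
)


COUNTER_REPORTER = FixtureModel(
    name="counter_reporter",
    description=(
        "Reporter gene activated by X1 (capacity rho41) and repressed by X2 "
        "(capacity rho42); coupled to the memory circuit it reads out the "
        "counter state"
    ),
    text="""\
auxiliary: X400, X401
X4. = a4*rho41*X1^2*rho42^-1*X2^2*X400^-1*X401^-1 + a4*rho41*X1^2*K2^2*X400^-1*X401^-1 + a4*K1^2*rho42^-1*X2^2*X400^-1*X401^-1 + a4*K1^2*K2^2*X400^-1*X401^-1 - b4*X4
0 = X1^2 + K1^2 - X400
0 = X2^2 + K2^2 - X401
""",
    rational_equations=[
        "X4. = a4*(rho41*X1^2 + K1^2)/(X1^2 + K1^2)"
        "*(rho42^-1*X2^2 + K2^2)/(X2^2 + K2^2) - b4*X4",
    ],
    default_parameters={"a4": 1.0, "b4": 1.0, "rho41": 100.0, "rho42": 100.0},
)


FIXTURES: Dict[str, FixtureModel] = {
    f.name: f for f in (SIMPLE_CIRCUIT, MEMORY_CIRCUIT, COUNTER_REPORTER)
}


def load(name: str) -> FixtureModel:
    try:
        return FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None


def counter_system() -> GMASystem:
    """The full counter: memory circuit plus reporter, recast together from
    the rational equations (auxiliaries X100, X200, X400, X401)."""
    return recast(
        MEMORY_CIRCUIT.rational_equations + COUNTER_REPORTER.rational_equations
    )
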