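"""Linear inequality systems over base-10 logarithms of named quantities.

Every dominance or boundary condition of a dominant S-system phenotype is a
half-space in log space.  A row stores ``sum_j coeff_j * log10(name_j) +
const  REL  0`` with ``REL`` one of ``>=`` or ``=``; strict ``>`` conditions
are represented as ``>=`` and tested for feasibility with a positive interior
slack (see :mod:`dsdesign.lp`).  Coefficients are kept as exact rationals
(kinetic-order differences and log-gain entries are rational by
construction); constants are base-10 logarithms of rate-constant literals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional


@dataclass
class LinearRow:
    coeffs: Dict[str, Fraction]
    const: float
    rel: str = ">="  # ">=" | "="
    label: str = ""

    def evaluate(self, logpoint: Mapping[str, float]) -> float:
        return sum(float(c) * logpoint[n] for n, c in self.coeffs.items()) + self.const

    def renamed(self, mapping: Mapping[str, str]) -> "LinearRow":
        return LinearRow(
            {mapping.get(n, n): c for n, c in self.coeffs.items()},
            self.const,
            self.rel,
            self.label,
        )

    def scaled(self, factor: Fraction) -> "LinearRow":
        return LinearRow(
            {n: c * factor for n, c in self.coeffs.items()},
            self.const * float(factor),
            self.rel,
            self.label,
        )


class LinearInequalitySystem:
    def __init__(self, variables: Iterable[str], rows: Optional[List[LinearRow]] = None):
        self.variables: List[str] = list(variables)
        self.rows: List[LinearRow] = list(rows) if rows else []

    def add_row(self, coeffs: Dict[str, Fraction], const: float, rel: str = ">=",
                label: str = "") -> None:
        for name in coeffs:
            if name not in self.variables:
                raise KeyError(f"row references undeclared variable {name}")
        self.rows.append(LinearRow(dict(coeffs), const, rel, label))

    def extend(self, other: "LinearInequalitySystem") -> None:
        for name in other.variables:
            if name not in self.variables:
                self.variables.append(name)
        self.rows.extend(other.rows)

    def slacks(self, logpoint: Mapping[str, float]) -> List[float]:
        return [row.evaluate(logpoint) for row in self.rows]

    def contains(self, logpoint: Mapping[str, float], tol: float = 1e-9) -> bool:
        for row in self.rows:
            s = row.evaluate(logpoint)
            if row.rel == "=" and abs(s) > tol:
                return False
            if row.rel == ">=" and s < -tol:
                return False
        return True

    def renamed(self, mapping: Mapping[str, str]) -> "LinearInequalitySystem":
        return LinearInequalitySystem(
            [mapping.get(n, n) for n in self.variables],
            [row.renamed(mapping) for row in self.rows],
        )

    def to_json(self) -> str:
        payload = {
            "variables": self.variables,
            "rows": [
                {
                    "coefficients": {n: float(c) for n, c in row.coeffs.items()},
                    "constant": row.const,
                    "relation": row.rel,
                    "label": row.label,
                }
                for row in self.rows
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LinearInequalitySystem":
        payload = json.loads(text)
        sys = cls(payload["variables"])
        for row in payload["rows"]:
            sys.add_row(
                {n: Fraction(v).limit_denominator(10**9)
                 for n, v in row["coefficients"].items()},
                row["constant"],
                row["relation"],
                row.get("label", ""),
            )
        return sys

    def __len__(self) -> int:
        return len(self.rows)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<LinearInequalitySystem {len(self.rows)} rows over "
            f"{len(self.variables)} log-variables>"
        )
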