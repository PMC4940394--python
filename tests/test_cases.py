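"""Case numbering, dominance/boundary conditions, and LP validity."""

import json
import math
from fractions import Fraction

import numpy as np
import pytest

from dsdesign import fixtures
from dsdesign.cases import (
    DesignSpace,
    case_number_from_signature,
    parse_signature_string,
    signature_from_case_number,
    signature_string,
)
from dsdesign.errors import VariableDomainError
from dsdesign.gma import GMAEquation, GMASystem, PowerLawTerm, parse_model
from dsdesign.linsys import LinearInequalitySystem

TABLE1_SIGNATURES = {
    1: "1111", 4: "1211", 7: "2111", 8: "2121", 9: "2131",
    10: "2211", 11: "2221", 12: "2231", 15: "3131", 18: "3231",
}
TABLE3_SIGNATURES = {
    1: "11111111", 10: "11121111", 19: "11211111",
    297: "32213131", 306: "32223131", 315: "32313131",
}


class TestNumbering:
    @pytest.mark.parametrize("number, sig", sorted(TABLE1_SIGNATURES.items()))
    def test_simple_system_pairs(self, simple_ds, number, sig):
        assert simple_ds.case_number_from_signature(sig) == number
        assert signature_string(
            simple_ds.signature_from_case_number(number)
        ) == sig

    @pytest.mark.parametrize("number, sig", sorted(TABLE3_SIGNATURES.items()))
    def test_memory_system_pairs(self, memory_ds, number, sig):
        assert memory_ds.case_number_from_signature(sig) == number

    def test_all_ones_signature_is_case_one(self, simple_ds, memory_ds):
        for ds in (simple_ds, memory_ds):
            n_eq = len(ds.system.signature)
            assert ds.case_number_from_signature([(1, 1)] * n_eq) == 1

    @pytest.mark.parametrize("ds_name", ["simple", "memory"])
    def test_bijection_round_trips_every_case(self, ds_name, simple_ds, memory_ds):
        ds = simple_ds if ds_name == "simple" else memory_ds
        radices = ds.system.signature
        for number in range(1, ds.num_cases + 1):
            sig = signature_from_case_number(number, radices)
            assert case_number_from_signature(sig, radices) == number

    def test_out_of_range_rejected(self, simple_ds):
        with pytest.raises(VariableDomainError):
            simple_ds.case_number_from_signature("4111")
        with pytest.raises(VariableDomainError):
            simple_ds.signature_from_case_number(19)

    def test_signature_string_rendering(self):
        assert signature_string([(2, 1), (3, 1)]) == "2131"
        assert signature_string([(12, 1)]) == "12-1"
        assert parse_signature_string("[2131]") == [(2, 1), (3, 1)]


class TestDominanceConditions:
    def test_case1_row_count(self, simple_ds):
        """(3-1)+(2-1) rows for the ODE plus (3-1)+(1-1) for the constraint."""
        assert len(simple_ds(1).dominance_conditions()) == 5

    def test_case1_activation_row(self, simple_ds):
        """Dividing the basal by the activation term of the X1 equation:
        -log rho1 - 2 log X1 + 2 log K1 >= 0."""
        rows = simple_ds(1).dominance_conditions().rows
        row = rows[0]
        assert row.coeffs == {
            "rho1": Fraction(-1), "X1": Fraction(-2), "K1": Fraction(2)
        }
        assert row.const == 0.0
        assert row.rel == ">="

    def test_single_term_equation_contributes_no_rows(self):
        ds = DesignSpace(["X1. = a - b*X1"])
        assert len(ds(1).dominance_conditions()) == 0

    def test_rows_reference_all_variable_space(self, simple_ds):
        dom = simple_ds(1).dominance_conditions()
        assert dom.variables == simple_ds.system.all_variables


class TestBoundaryConditions:
    def test_case1_substitution(self, simple_ds):
        """Substituting X1 = a1/b1, X100 = 1 into the dominance rows:
        the heterodimer row becomes log b1 - log k - log X2 >= 0 and the
        activation row 2 log b1 + 2 log K1 - log rho1 - 2 log a1 >= 0."""
        boundary = simple_ds(1).boundary_conditions()
        by_label = {row.label: row for row in boundary.rows}
        act = by_label["eq1:pos1>=pos2"]
        assert act.coeffs == {
            "rho1": Fraction(-1), "a1": Fraction(-2),
            "b1": Fraction(2), "K1": Fraction(2),
        }
        het = by_label["eq1:neg1>=neg2"]
        assert het.coeffs == {
            "b1": Fraction(1), "k": Fraction(-1), "X2": Fraction(-1)
        }
        assert set(boundary.variables) == set(
            simple_ds.system.independent_variables
        )

    def test_rows_without_dependents_pass_through(self, simple_ds):
        boundary = simple_ds(1).boundary_conditions()
        by_label = {row.label: row for row in boundary.rows}
        assert by_label["eq1:pos1>=pos3"].coeffs == {
            "X3": Fraction(-1), "K3": Fraction(1)
        }

    def test_underdetermined_case_has_no_boundary(self):
        # the two ODEs share one log-linear row: singular dependent block
        ds = DesignSpace(["X1. = a*X1*X2^-1 - b", "X2. = c*X1*X2^-1 - d"])
        case = ds(1)
        assert not case.has_solution
        assert case.boundary_conditions() is None
        assert not case.is_valid()

    def test_validity_is_independent_of_stability(self, simple_ds):
        """Case 7 is a valid phenotype even though its fixed point is
        unstable: boundary feasibility and stability are orthogonal."""
        case7 = simple_ds(7)
        assert case7.is_valid()
        pv = case7.valid_interior_parameter_set()
        assert case7.ssystem.positive_roots(pv) >= 1


class TestValidity:
    def test_simple_repertoire(self, simple_ds):
        assert simple_ds.valid_cases() == [1, 4, 7, 8, 9, 10, 11, 12, 15, 18]

    def test_single_term_system_is_always_valid(self):
        ds = DesignSpace(["X1. = a - b*X1"])
        assert ds.valid_cases() == [1]

    def test_contradictory_constraints_are_infeasible(self, simple_ds):
        case = simple_ds(1, constraints=["X3 > 10", "X3 < 0.1"])
        assert not case.is_valid()

    def test_validity_invariant_to_equation_rescaling(self, simple_ds):
        """Dominance rows compare terms of one sign within one equation, so
        uniformly rescaling all terms of an equation changes nothing."""
        scale = PowerLawTerm(7.3, {})
        scaled_eqs = []
        for eq in simple_ds.system.equations:
            scaled_eqs.append(
                GMAEquation(
                    eq.kind,
                    eq.variable,
                    [t.multiplied(scale) for t in eq.positive_terms],
                    [t.multiplied(scale) for t in eq.negative_terms],
                )
            )
        scaled = DesignSpace(
            GMASystem(scaled_eqs, simple_ds.system.auxiliary_variables),
            constraints=simple_ds.constraints,
        )
        assert scaled.valid_cases() == simple_ds.valid_cases()

    def test_p_bounds_narrow_the_box(self, simple_ds):
        case9 = simple_ds(9)  # needs the repression term dominant: X3 large
        assert case9.is_valid()
        assert not case9.is_valid(p_bounds={"X3": (1e-3, 1.0), "K3": (1.0, 1e3)})


class TestPointMembership:
    def test_printed_intersection_point(self, simple_ds):
        point = {"K1": 1, "K3": 10, "X2": 1, "X3": 1,
                 "a1": 0.32, "b1": 10, "rho1": 100, "k": 1}
        assert simple_ds.valid_cases_at_point(point) == [1, 7, 8]

    def test_point_deep_inside_single_region(self, simple_ds):
        deep = {"a1": 1, "b1": 10, "rho1": 1, "K1": 100, "K3": 100,
                "X2": 1, "X3": 1, "k": 0.01}
        assert simple_ds.valid_cases_at_point(deep) == [1]

    def test_missing_parameter_is_domain_error(self, simple_ds):
        with pytest.raises(VariableDomainError):
            simple_ds.valid_cases_at_point({"K1": 1.0})

    def test_valid_cases_dispatches_on_full_point(self, simple_ds):
        deep = {"a1": 1, "b1": 10, "rho1": 1, "K1": 100, "K3": 100,
                "X2": 1, "X3": 1, "k": 0.01}
        assert simple_ds.valid_cases(p_bounds=deep) == [1]


class TestPointwisePartition:
    def test_numeric_ranking_matches_dominance_polytope(self, simple_ds):
        """At a generic point of the full (n+m)-space, ranking term values
        numerically selects exactly the one signature whose dominance
        polytope contains the point."""
        system = simple_ds.system
        rng = np.random.default_rng(42)
        for _ in range(25):
            point = {
                n: float(10.0 ** rng.uniform(-3, 3))
                for n in system.all_variables
            }
            signature = []
            for pos, neg, _net in [
                (eq.positive_terms, eq.negative_terms, None)
                for eq in system.equations
            ]:
                p = int(np.argmax([t.evaluate(point) for t in pos])) + 1
                q = int(np.argmax([t.evaluate(point) for t in neg])) + 1
                signature.append((p, q))
            selected = simple_ds.case_number_from_signature(signature)
            logpoint = {n: math.log10(v) for n, v in point.items()}
            containing = [
                c.number
                for c in simple_ds.cases()
                if c.dominance_conditions().contains(logpoint, tol=1e-12)
            ]
            assert containing == [selected]


class TestExports:
    def test_repertoire_dataframe(self, simple_ds):
        df = simple_ds.repertoire()
        assert list(df.columns) == [
            "case_number", "signature", "valid", "has_solution"
        ]
        assert len(df) == 18
        assert df["valid"].sum() == 10

    def test_inequality_system_json_round_trip(self, simple_ds):
        boundary = simple_ds(1).boundary_conditions()
        payload = json.loads(boundary.to_json())
        assert payload["variables"] == boundary.variables
        again = LinearInequalitySystem.from_json(boundary.to_json())
        assert [r.coeffs for r in again.rows] == [r.coeffs for r in boundary.rows]
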