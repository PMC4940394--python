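"""S-system steady states, constraint elimination, gains, and stability."""

import math
from fractions import Fraction

import numpy as np
import pytest

from dsdesign import fixtures
from dsdesign.cases import DesignSpace
from dsdesign.errors import (
    RouthDegenerateError,
    SingularSystemError,
    VariableDomainError,
)
from dsdesign.gma import parse_model
from dsdesign.landscape import solve_auxiliaries
from dsdesign.ssystems import SSystem


class TestSteadyStateSolution:
    def test_case1_solution_in_cartesian_form(self, simple_ds):
        sol = simple_ds(1).ssystem.solve_steady_state()
        text = {k: t.serialize() for k, t in sol.as_power_laws().items()}
        assert text == {"X1": "a1*b1^-1", "X100": "1"}

    def test_case7_solution_exists_and_is_uncoupled(self, simple_ds):
        ssys = simple_ds(7).ssystem
        assert ssys.has_solution
        assert ssys.log_gain("X1", "X2") == 0
        assert ssys.log_gain("X1", "X3") == 0

    def test_singular_dependent_block_reported(self):
        ds = DesignSpace(["X1. = a*X1*X2^-1 - b", "X2. = c*X1*X2^-1 - d"])
        sol = ds(1).ssystem.solve_steady_state()
        assert not sol.exists
        with pytest.raises(SingularSystemError):
            ds(1).ssystem.steady_state({"a": 1, "b": 1, "c": 1, "d": 1})

    def test_solution_satisfies_log_linear_system_identically(self, memory_ds):
        """Substituting the affine solution back into G y + a = H y + b
        leaves exact zeros in every coefficient and constant."""
        for number in (1, 297, 306):
            ssys = memory_ds(number).ssystem
            sol = ssys.solve_steady_state()
            for eq in ssys.equations:
                pos, neg = eq.positive_terms[0], eq.negative_terms[0]
                # residual coefficients per independent variable
                resid = {}
                const = pos.log10_coefficient - neg.log10_coefficient
                for name in ssys.dependent_variables:
                    w = pos.exponent(name) - neg.exponent(name)
                    dep_const, dep_coeffs = sol.affine[name]
                    const += float(w) * dep_const
                    for ind, c in dep_coeffs.items():
                        resid[ind] = resid.get(ind, Fraction(0)) + w * c
                for name in ssys.independent_variables:
                    w = pos.exponent(name) - neg.exponent(name)
                    if w:
                        resid[name] = resid.get(name, Fraction(0)) + w
                assert all(v == 0 for v in resid.values())
                assert abs(const) < 1e-12


class TestLogGains:
    @pytest.mark.parametrize(
        "number, gain_x2, gain_x3",
        [(1, 0, 0), (4, -1, 0), (7, 0, 0), (8, 0, 0), (9, 0, 1),
         (10, 1, 0), (11, -1, 0), (12, 1, 1), (15, 0, 0), (18, -1, 0)],
    )
    def test_simple_system_gain_table(self, simple_ds, number, gain_x2, gain_x3):
        ssys = simple_ds(number).ssystem
        assert ssys.log_gain("X1", "X2") == gain_x2
        assert ssys.log_gain("X1", "X3") == gain_x3

    def test_memory_case_306_half_gains(self, memory_ds):
        """Heterodimer-dominated loss couples X1 and X2 with opposite,
        half-magnitude gains with respect to the repressor."""
        ssys = memory_ds(306).ssystem
        assert ssys.log_gain("X1", "X3") == Fraction(-1, 2)
        assert ssys.log_gain("X2", "X3") == Fraction(1, 2)

    def test_unknown_names_rejected(self, simple_ds):
        ssys = simple_ds(1).ssystem
        with pytest.raises(VariableDomainError):
            ssys.log_gain("X9", "X3")
        with pytest.raises(VariableDomainError):
            ssys.log_gain("X1", "X100")

    def test_gain_matches_numeric_perturbation(self, simple_ds, simple_pvals):
        """Perturbing one parameter by a factor 10^eps moves log10 of each
        dependent variable by gain * eps (the solution is log-linear, so the
        first-order relation is exact)."""
        eps = 1e-6
        for number in (4, 9, 12):
            ssys = simple_ds(number).ssystem
            base = ssys.steady_state(simple_pvals)
            for pname in ("X2", "X3", "b1"):
                gain = float(ssys.log_gain("X1", pname))
                bumped = dict(simple_pvals)
                bumped[pname] *= 10.0 ** eps
                moved = ssys.steady_state(bumped)
                delta = math.log10(moved["X1"]) - math.log10(base["X1"])
                assert delta == pytest.approx(gain * eps, abs=1e-12)


class TestConstraintElimination:
    def test_case1_reduction_matches_printed_form(self, simple_ds):
        reduced = simple_ds(1).ssystem.remove_algebraic_constraints()
        assert reduced.serialize() == ["X1. = a1 - X1*b1"]
        assert reduced.n_c == 0

    def test_reduction_of_constraint_free_system_is_identity(self):
        ds = DesignSpace(["X1. = a - b*X1"])
        ssys = ds(1).ssystem
        assert ssys.remove_algebraic_constraints() is ssys

    def test_memory_reduction_agrees_with_parent_numerically(self, memory_ds):
        """Evaluating the reduced right-hand sides equals the parent
        S-system with auxiliaries solved from their constraints, at random
        positive points, to < 1e-12 relative error."""
        rng = np.random.default_rng(7)
        for number in (1, 306):
            ssys = memory_ds(number).ssystem
            reduced = ssys.remove_algebraic_constraints()
            parent = parse_model(ssys.serialize(), ssys.auxiliary_variables)
            for _ in range(20):
                env = {
                    n: float(10.0 ** rng.uniform(-2, 2))
                    for n in ssys.dynamic_variables + ssys.independent_variables
                }
                env.update(solve_auxiliaries(parent, env))
                for eq_red, eq_par in zip(
                    reduced.equations, parent.equations[: parent.n_t]
                ):
                    net_red = eq_red.evaluate(env)[2]
                    net_par = eq_par.evaluate(env)[2]
                    scale = max(abs(net_par), 1e-30)
                    assert abs(net_red - net_par) / scale < 1e-12

    def test_reduction_preserves_steady_state_and_gains(self, memory_ds):
        ssys = memory_ds(306).ssystem
        reduced = ssys.remove_algebraic_constraints()
        assert reduced.log_gain("X1", "X3") == ssys.log_gain("X1", "X3")
        pv = memory_ds(306).valid_interior_parameter_set()
        full = ssys.steady_state(pv)
        red = reduced.steady_state(pv)
        for name in reduced.dynamic_variables:
            assert red[name] == pytest.approx(full[name], rel=1e-10)


class TestStability:
    def test_case1_stable_at_printed_point(self, simple_ds, simple_pvals):
        report = simple_ds(1).ssystem.eigenvalues(simple_pvals)
        assert report.positive_root_count == 0
        assert not report.borderline

    def test_one_dimensional_closed_form(self):
        """The reduced system a - b X1 has the single eigenvalue -b."""
        ds = DesignSpace(["X1. = a - b*X1"])
        report = ds(1).ssystem.eigenvalues({"a": 2.0, "b": 3.0})
        assert report.eigenvalues == [pytest.approx(-3.0)]
        assert report.positive_root_count == 0

    @pytest.mark.parametrize(
        "number, letter",
        [(1, "S"), (4, "S"), (7, "U"), (8, "S"), (9, "U"), (10, "U"),
         (11, "S"), (12, "U"), (15, "S"), (18, "S")],
    )
    def test_simple_system_stability_column(self, simple_ds, number, letter):
        case = simple_ds(number)
        pv = case.valid_interior_parameter_set()
        roots = case.ssystem.positive_roots(pv)
        assert ("S" if roots == 0 else "U") == letter


class TestRouth:
    def test_linear_system(self):
        ds = DesignSpace(["X1. = a - b*X1"])
        assert ds(1).ssystem.routh_positive_roots({"a": 1.0, "b": 2.0}) == 0

    def test_unstable_case7(self, simple_ds):
        case7 = simple_ds(7)
        pv = case7.valid_interior_parameter_set()
        assert case7.ssystem.routh_positive_roots(pv) >= 1

    def test_routh_agrees_with_eigenvalues_on_random_2x2_systems(self):
        """Cross-method oracle: on random two-variable S-systems the Routh
        first-column sign changes equal the eigenvalue count."""
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 100:
            g = rng.integers(-2, 3, size=(2, 2))
            h = rng.integers(-2, 3, size=(2, 2))
            eqs = [
                f"X1. = a1*X1^{g[0,0]}*X2^{g[0,1]} - b1*X1^{h[0,0]}*X2^{h[0,1]}",
                f"X2. = a2*X1^{g[1,0]}*X2^{g[1,1]} - b2*X1^{h[1,0]}*X2^{h[1,1]}",
            ]
            try:
                ds = DesignSpace(eqs)
            except Exception:
                continue
            ssys = ds(1).ssystem
            if not ssys.has_solution:
                continue
            pv = {
                "a1": float(10.0 ** rng.uniform(-1, 1)),
                "a2": float(10.0 ** rng.uniform(-1, 1)),
                "b1": float(10.0 ** rng.uniform(-1, 1)),
                "b2": float(10.0 ** rng.uniform(-1, 1)),
            }
            report = ssys.eigenvalues(pv)
            if report.borderline or report.margin < 1e-6:
                continue
            try:
                routh = ssys.routh_positive_roots(pv)
            except RouthDegenerateError:
                continue
            assert routh == report.positive_root_count
            checked += 1


class TestReport:
    def test_json_report_fields(self, simple_ds, simple_pvals):
        payload = simple_ds(1).ssystem.report(simple_pvals)
        assert payload["equations"] == ["X1. = a1*X100^-1 - b1*X1", "0 = 1 - X100"]
        assert payload["solution"] == {"X1": "a1*b1^-1", "X100": "1"}
        assert payload["positive_root_count"] == 0
        assert payload["gain_matrix"]["X1"]["X3"] == 0.0
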