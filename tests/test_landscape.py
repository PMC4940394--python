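"""Design-space slices, fixed points, simulation, basins (desk-scale grids)."""

import math

import numpy as np
import pytest

from dsdesign.cases import DesignSpace
from dsdesign.errors import VariableDomainError
from dsdesign.landscape import (
    SliceSpec,
    basins,
    classify_slice,
    find_fixed_points,
    positive_roots_slice,
    simulate,
    solve_auxiliaries,
    trajectory_classes,
)

INTERSECTION_POINT = {"K1": 1.0, "K3": 10.0, "X2": 1.0, "X3": 1.0,
                      "a1": 0.32, "b1": 10.0, "rho1": 100.0, "k": 1.0}


@pytest.fixture(scope="module")
def bistable_slice(simple_ds):
    spec = SliceSpec("X2", "b1", (1e-3, 1e3), (1e-3, 1e3), 21,
                     INTERSECTION_POINT)
    return spec, classify_slice(simple_ds, spec)


class TestSliceClassification:
    def test_mono_and_tristable_regions_coexist(self, bistable_slice):
        """The slice through the 1/7/8 intersection shows single-phenotype
        regions and three-phenotype overlaps (2 stable + 1 unstable)."""
        _, result = bistable_slice
        sizes = {len(label) for row in result.labels for label in row}
        assert 1 in sizes and 3 in sizes

    def test_intersections_filter(self, simple_ds, bistable_slice):
        spec, unfiltered = bistable_slice
        filtered = classify_slice(simple_ds, spec, intersections=[1, 3])
        for row_u, row_f in zip(unfiltered.labels, filtered.labels):
            for lab_u, lab_f in zip(row_u, row_f):
                if len(lab_u) in (1, 3):
                    assert lab_f == lab_u
                else:
                    assert lab_f == ()

    def test_single_region_slice_is_uniform(self, simple_ds):
        deep = {"a1": 1, "b1": 10, "rho1": 1, "K1": 100, "K3": 100,
                "X2": 1, "X3": 1, "k": 0.01}
        spec = SliceSpec("X2", "b1", (0.5, 2.0), (5.0, 20.0), 7, deep)
        result = classify_slice(simple_ds, spec)
        assert {label for row in result.labels for label in row} == {(1,)}

    def test_labels_stable_under_grid_refinement(self, simple_ds):
        coarse = SliceSpec("X2", "b1", (1e-2, 1e2), (1e-2, 1e2), 5,
                           INTERSECTION_POINT)
        fine = SliceSpec("X2", "b1", (1e-2, 1e2), (1e-2, 1e2), 9,
                         INTERSECTION_POINT)
        res_c = classify_slice(simple_ds, coarse)
        res_f = classify_slice(simple_ds, fine)
        # shared coordinates: every other point of the fine grid
        for iy in range(5):
            for ix in range(5):
                assert res_c.labels[iy][ix] == res_f.labels[2 * iy][2 * ix]

    def test_grid_labels_agree_with_numeric_dominance(self, simple_ds):
        """Pointwise oracle: where exactly one case is valid, ranking the
        term values numerically at the case's steady state recovers the
        same signature."""
        spec = SliceSpec("X2", "b1", (1e-2, 1e2), (1e-2, 1e2), 7,
                         INTERSECTION_POINT)
        result = classify_slice(simple_ds, spec)
        system = simple_ds.system
        for iy, yv in enumerate(result.y):
            for ix, xv in enumerate(result.x):
                labels = result.labels[iy][ix]
                if len(labels) != 1:
                    continue
                case = simple_ds(labels[0])
                pvals = dict(INTERSECTION_POINT, X2=xv, b1=yv)
                env = dict(pvals)
                env.update(case.ssystem.steady_state(pvals))
                ranked = []
                for eq in system.equations:
                    p = 1 + int(np.argmax([t.evaluate(env)
                                           for t in eq.positive_terms]))
                    q = 1 + int(np.argmax([t.evaluate(env)
                                           for t in eq.negative_terms]))
                    ranked.append((p, q))
                assert ranked == case.signature

    def test_degenerate_range_rejected(self, simple_ds):
        spec = SliceSpec("X2", "b1", (1.0, 1.0), (1e-3, 1e3), 5,
                         INTERSECTION_POINT)
        with pytest.raises(VariableDomainError):
            classify_slice(simple_ds, spec)


class TestPositiveRootsSlice:
    def test_overlaps_score_one_and_singles_zero(self, simple_ds, bistable_slice):
        spec, classes = bistable_slice
        roots = positive_roots_slice(simple_ds, spec)
        for row_c, row_r in zip(classes.labels, roots.labels):
            for label, count in zip(row_c, row_r):
                if len(label) == 3:
                    assert count == 1
                elif len(label) == 1:
                    assert count == 0

    def test_single_stable_slice_is_all_zero(self, simple_ds):
        deep = {"a1": 1, "b1": 10, "rho1": 1, "K1": 100, "K3": 100,
                "X2": 1, "X3": 1, "k": 0.01}
        spec = SliceSpec("X2", "b1", (0.5, 2.0), (5.0, 20.0), 5, deep)
        roots = positive_roots_slice(simple_ds, spec)
        assert {r for row in roots.labels for r in row} == {0}


class TestAuxiliarySolving:
    def test_constraint_solution_zeroes_the_constraint(self, memory_ds):
        env = {n: 1.7 for n in memory_ds.system.independent_variables}
        env.update({"X1": 0.3, "X2": 2.5})
        aux = solve_auxiliaries(memory_ds.system, env)
        env.update(aux)
        for pos, neg, net in memory_ds.system.evaluate(env)[memory_ds.system.n_t:]:
            assert abs(net) < 1e-12 * max(pos, neg)


class TestFixedPoints:
    def test_monostable_point_recovers_dilution_balance(self, simple_ds):
        deep = {"a1": 1, "b1": 10, "rho1": 1, "K1": 100, "K3": 100,
                "X2": 1, "X3": 1, "k": 0.01}
        points = find_fixed_points(simple_ds, deep)
        assert len(points) == 1
        fp = points[0]
        assert fp.stable and fp.refined
        # basal/dilution balance: X1 ~ a1/b1, slightly shifted by the
        # neglected terms that refinement restores
        assert fp.location["X1"] == pytest.approx(deep["a1"] / deep["b1"],
                                                  rel=0.05)
        assert fp.residual < 1e-9

    def test_quadrastable_point_has_four_stable_attractors(
        self, memory_ds, quadrastable_instance_point
    ):
        pvals, attractors, members = quadrastable_instance_point
        points = find_fixed_points(memory_ds, pvals,
                                   thresholds={"X1": 1.0, "X2": 1.0})
        stable = [fp for fp in points if fp.stable]
        assert len(stable) == 4
        assert {fp.quadrant for fp in stable} == {"--", "-+", "+-", "++"}
        assert all(fp.residual < 1e-9 for fp in points if fp.refined)
        # companion unstable fixed points accompany the attractors
        assert len(points) > 4


class TestTrajectoryClasses:
    def test_four_direction_classes_around_attractors(
        self, memory_ds, quadrastable_instance_point
    ):
        pvals, attractors, _ = quadrastable_instance_point
        result = trajectory_classes(memory_ds.system, pvals,
                                    (1e-3, 1e3), (1e-3, 1e3), 24)
        seen = {label for row in result.labels for label in row}
        assert seen == {"NE", "NW", "SE", "SW"}

    def test_classes_match_full_rhs_signs_away_from_boundaries(
        self, memory_ds, quadrastable_instance_point
    ):
        """The dominant-term sign equals the sign of the full right-hand
        side except in thin strips where non-dominant terms flip it."""
        pvals, _, _ = quadrastable_instance_point
        system = memory_ds.system
        result = trajectory_classes(system, pvals, (1e-2, 1e2), (1e-2, 1e2), 12)
        agree = disagree = 0
        for iy, yv in enumerate(result.y):
            for ix, xv in enumerate(result.x):
                env = {n: float(pvals[n]) for n in system.independent_variables}
                env.update({"X1": xv, "X2": yv})
                env.update(solve_auxiliaries(system, env))
                nets = [eq.evaluate(env)[2]
                        for eq in system.equations[: system.n_t]]
                full = ("E" if nets[0] > 0 else "W", "N" if nets[1] > 0 else "S")
                label = result.labels[iy][ix]
                if label[0] == full[1] and label[1] == full[0]:
                    agree += 1
                else:
                    disagree += 1
        assert agree > 3 * disagree


class TestSimulation:
    def test_zero_bolus_stays_at_attractor(
        self, memory_ds, quadrastable_instance_point
    ):
        pvals, attractors, _ = quadrastable_instance_point
        start = dict(attractors["-+"].location)
        traj = simulate(memory_ds.system, pvals, start, 50.0)
        end = traj.state_at_end()
        for name, value in start.items():
            assert abs(math.log10(end[name]) - math.log10(value)) < 1e-2
        assert np.all(traj.states > 0)

    def test_perturbation_relaxes_back(self, memory_ds, quadrastable_instance_point):
        """A 1% displacement from every attractor decays back (local
        stability confirmed by integration)."""
        pvals, attractors, _ = quadrastable_instance_point
        for fp in attractors.values():
            start = {n: v * 1.01 for n, v in fp.location.items()}
            traj = simulate(memory_ds.system, pvals, start, 100.0)
            end = traj.state_at_end()
            dist = max(
                abs(math.log10(end[n]) - math.log10(fp.location[n]))
                for n in fp.location
            )
            assert dist < 1e-3

    def test_bolus_event_is_applied(self, memory_ds, quadrastable_instance_point):
        pvals, attractors, _ = quadrastable_instance_point
        start = dict(attractors["--"].location)
        traj = simulate(memory_ds.system, pvals, start, 2.0,
                        boluses=[(1.0, "X1", 50.0)])
        i = np.searchsorted(traj.times, 1.0 + 1e-6)
        x1 = traj.states[i, traj.variables.index("X1")]
        assert x1 > 10.0

    def test_invalid_initial_state_rejected(self, memory_ds,
                                            quadrastable_instance_point):
        pvals, _, _ = quadrastable_instance_point
        with pytest.raises(VariableDomainError):
            simulate(memory_ds.system, pvals, {"X1": 1.0, "X2": -1.0}, 1.0)


class TestBasins:
    def test_bistable_pair_partitions_coarse_grid(
        self, memory_ds, quadrastable_instance_point
    ):
        pvals, attractors, _ = quadrastable_instance_point
        stable = sorted(attractors.values(), key=lambda f: f.quadrant)
        result = basins(memory_ds.system, pvals, stable,
                        (1e-2, 1e2), (1e-2, 1e2), resolution=7,
                        t_cap=400.0)
        seen = {label for row in result.labels for label in row}
        assert len(seen - {-1}) >= 2  # multiple basins visible
        assert sum(1 for row in result.labels for l in row if l == -1) <= 5

    def test_grid_point_at_attractor_labels_itself(
        self, memory_ds, quadrastable_instance_point
    ):
        pvals, attractors, _ = quadrastable_instance_point
        stable = sorted(attractors.values(), key=lambda f: f.quadrant)
        fp = stable[0]
        x1, x2 = fp.location["X1"], fp.location["X2"]
        result = basins(memory_ds.system, pvals, stable,
                        (x1, x1 * 1.001), (x2, x2 * 1.001), resolution=2)
        assert result.labels[0][0] == 0
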