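"""Static optimization: moment arms, solver-vs-oracle, reactions, normalization."""

import copy

import numpy as np
import pytest

from spineforge.anatomy import ligament_force
from spineforge.muscle_opt import (
    InfeasibleProblemError,
    OptimizationProblem,
    build_problem,
    joint_reactions,
    ligament_utilization,
    moment_arm,
    normalize_to_standing,
    solve,
)
from spineforge.statics import LoadCase, Posture, flexion_posture
from spineforge.synthetic_spine import make_toy_problem


class TestMomentArm:
    def test_vertical_fascicle_posterior_of_joint(self):
        # line of action +Y, passing 50 mm posterior (x = -50) of the joint
        a = moment_arm(np.array([-50.0, 0, 0.0]), np.array([-50.0, 100.0, 0.0]), np.zeros(3))
        assert abs(a[2]) == pytest.approx(0.05)
        assert a[0] == pytest.approx(0.0)

    def test_through_joint_origin_is_zero(self):
        a = moment_arm(np.array([0.0, -50.0, 0.0]), np.array([0.0, 50.0, 0.0]), np.zeros(3))
        assert np.allclose(a, 0.0)

    def test_mirrored_fascicle_negates_frontal_component(self):
        o, i = np.array([0.0, 0.0, 40.0]), np.array([10.0, 100.0, 60.0])
        m = np.array([1.0, 1.0, -1.0])
        a = moment_arm(o, i, np.zeros(3))
        am = moment_arm(o * m, i * m, np.zeros(3))
        assert am[0] == pytest.approx(-a[0])
        assert am[2] == pytest.approx(a[2])

    def test_zero_length_fascicle_rejected(self):
        with pytest.raises(ValueError):
            moment_arm(np.zeros(3), np.zeros(3), np.ones(3))


def _grid_oracle(problem, step=1.0, fmax=2000.0):
    """Brute-force oracle for single-constraint problems with <=3 muscles.

    All but the last force are gridded; the last is solved exactly from the
    moment constraint so every candidate is strictly feasible.
    """
    A, b = problem.moment_arms, problem.target_moments
    assert A.shape[0] == 1
    r, target = A[0], b[0]
    ub = problem.force_bounds
    if A.shape[1] == 1:
        f = np.array([target / r[0]])
        return float(np.sum((f / problem.pcsa) ** 3)), f
    grids = [np.arange(0.0, min(u, fmax) + step, step) for u in ub[:-1]]
    mesh = np.meshgrid(*grids, indexing="ij")
    Fpart = np.stack([m.ravel() for m in mesh], axis=1)
    f_last = (target - Fpart @ r[:-1]) / r[-1]
    feas = (f_last >= 0.0) & (f_last <= ub[-1])
    F = np.column_stack([Fpart[feas], f_last[feas]])
    costs = np.sum((F / problem.pcsa) ** 3, axis=1)
    k = int(np.argmin(costs))
    return float(costs[k]), F[k]


class TestSolveToys:
    @pytest.mark.parametrize("name", ["single_muscle", "antagonist_pair", "two_agonists"])
    def test_matches_attached_closed_form(self, name):
        prob = make_toy_problem(name)
        sol = solve(prob)
        assert np.allclose(sol.forces_n, prob.expected.forces, atol=1.0)
        assert np.abs(sol.residuals_nm).max() <= 0.1

    @pytest.mark.parametrize("name", ["antagonist_pair", "two_agonists"])
    def test_matches_grid_oracle_cost(self, name):
        prob = make_toy_problem(name)
        sol = solve(prob)
        oracle = _grid_oracle(prob)
        assert oracle is not None
        # optimal cost within 0.1% of the dense grid search
        assert sol.cost == pytest.approx(oracle[0], rel=1e-3)

    def test_bounds_respected_exactly(self):
        prob = make_toy_problem("single_muscle")
        sol = solve(prob)
        assert np.all(sol.forces_n >= 0.0)
        assert np.all(sol.forces_n <= prob.force_bounds + 1e-9)

    def test_multistart_agrees_with_single_start(self):
        prob = make_toy_problem("two_agonists")
        a = solve(prob, n_starts=1)
        b = solve(prob, n_starts=10)
        assert a.cost == pytest.approx(b.cost, rel=1e-6)

    def test_raising_sigma_max_keeps_feasible_solution(self):
        lo = make_toy_problem("two_agonists")
        lo.sigma_max_mpa = 0.6
        hi = make_toy_problem("two_agonists")
        hi.sigma_max_mpa = 1.0
        assert np.allclose(solve(lo).forces_n, solve(hi).forces_n, atol=0.5)

    def test_infeasible_problem_names_worst_constraint(self):
        prob = OptimizationProblem(
            moment_arms=np.array([[0.05]]),
            pcsa=np.array([1.0]),
            target_moments=np.array([100.0]),  # needs 2000 N, bound is 100 N
            sigma_max_mpa=1.0,
            constraint_names=["L5/S1:Mz"],
        )
        with pytest.raises(InfeasibleProblemError, match="L5/S1"):
            solve(prob)


class TestFullModel:
    def test_moment_balance_residual_under_tolerance(self, lordotic_model):
        post = flexion_posture(lordotic_model, 20.0)
        sol = solve(build_problem(lordotic_model, post))
        assert np.abs(sol.residuals_nm).max() <= 0.1

    def test_symmetric_model_zero_lateral_shear(self, straight_model):
        post = flexion_posture(straight_model, 10.0)
        sol = solve(build_problem(straight_model, post))
        reac = joint_reactions(straight_model, post, sol.forces_n)
        for j, r in reac.items():
            assert abs(r["lateral_shear_n"]) < 5.0, j

    def test_bare_vertical_stack_compression_equals_weight(self, bare_straight_model):
        model = bare_straight_model
        reac = joint_reactions(model, Posture(), np.zeros(0))
        g = model.gravity_m_s2
        above = model.bodies
        w_t12 = (above["thorax"].mass_kg + above["arm_left"].mass_kg + above["arm_right"].mass_kg) * g
        assert reac["T12/L1"]["compression_n"] == pytest.approx(w_t12, rel=1e-2)
        w_l5 = sum(
            b.mass_kg for n, b in above.items() if n != "ground"
        ) * g
        assert reac["L5/S1"]["compression_n"] == pytest.approx(w_l5, rel=1e-2)
        assert abs(reac["L5/S1"]["ap_shear_n"]) < 0.02 * w_l5

    def test_compressive_muscle_pair_adds_only_compression(self, bare_straight_model):
        """Adding muscle force along the joint axis raises compression and
        leaves the shear components unchanged."""
        from spineforge.anatomy import MuscleFascicle, PointRef

        model = copy.deepcopy(bare_straight_model)
        base = joint_reactions(model, Posture(), np.zeros(0))
        j = model.joint("L5/S1")
        axis = j.orientation[:, 1]
        for sz in (+40.0, -40.0):
            off = np.array([0.0, 0.0, sz])
            model.muscles.append(
                MuscleFascicle(
                    "IS", "left" if sz > 0 else "right",
                    PointRef("thorax", "o", j.origin + off + 300.0 * axis),
                    PointRef("ground", "i", j.origin + off - 30.0 * axis),
                    pcsa_cm2=5.0,
                )
            )
        loaded = joint_reactions(model, Posture(), np.array([100.0, 100.0]))
        r0, r1 = base["L5/S1"], loaded["L5/S1"]
        assert r1["compression_n"] == pytest.approx(r0["compression_n"] + 200.0, rel=1e-6)
        assert r1["ap_shear_n"] == pytest.approx(r0["ap_shear_n"], abs=1e-6)
        assert r1["lateral_shear_n"] == pytest.approx(r0["lateral_shear_n"], abs=1e-6)


class TestNormalization:
    def test_standing_over_standing_is_one(self):
        res = {"standing": {"L4/L5": {"compression_n": 500.0}}}
        out = normalize_to_standing(res)
        assert out["standing"]["L4/L5"] == 1.0

    def test_doubling_masses_leaves_normalized_unchanged(self, bare_straight_model):
        model = bare_straight_model
        double = copy.deepcopy(model)
        for b in double.bodies.values():
            b.mass_kg *= 2.0
        post = flexion_posture(model, 10.0)
        res = {
            "standing": joint_reactions(model, Posture(), np.zeros(0)),
            "flexed": joint_reactions(model, post, np.zeros(0)),
        }
        res2 = {
            "standing": joint_reactions(double, Posture(), np.zeros(0)),
            "flexed": joint_reactions(double, post, np.zeros(0)),
        }
        n1 = normalize_to_standing(res)
        n2 = normalize_to_standing(res2)
        for j in n1["flexed"]:
            assert n1["flexed"][j] == pytest.approx(n2["flexed"][j], rel=1e-9)

    def test_missing_standing_case_rejected(self):
        with pytest.raises(KeyError):
            normalize_to_standing({"flexed": {}})

    def test_flexed_compression_at_least_standing(self, straight_model):
        results = {}
        for name, flex in (("standing", 0.0), ("flexion_20", 20.0)):
            post = flexion_posture(straight_model, flex)
            sol = solve(build_problem(straight_model, post))
            results[name] = joint_reactions(straight_model, post, sol.forces_n)
        norm = normalize_to_standing(results)
        assert norm["flexion_20"]["L4/L5"] >= 1.0


class TestLigamentUtilization:
    def test_definition_boundaries(self, lordotic_model):
        lig = lordotic_model.ligaments[0]
        assert ligament_force(lig, lig.l_B) / lig.F_B == pytest.approx(1.0, rel=1e-9)
        assert ligament_force(lig, lig.l_0) == 0.0

    def test_posterior_ligaments_monotone_in_flexion(self, lordotic_model):
        series = []
        for f in (0.0, 10.0, 20.0, 30.0):
            util = ligament_utilization(lordotic_model, flexion_posture(lordotic_model, f))
            series.append(util["ISL@L4/L5"])
        assert np.all(np.diff(series) >= 0)
        assert series[-1] > series[0]
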