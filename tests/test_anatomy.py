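"""Ligament law, disc law, muscle table resolution and model assembly."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spineforge.anatomy import (
    DiscElement,
    LigamentElement,
    PointRef,
    SpineModel,
    build_muscles,
    default_generic_points,
    default_muscle_table,
    derive_ligament_params,
    disc_moment,
    ligament_force,
    load_param_json,
    MuscleAssemblyError,
)


def _lig(**kw) -> LigamentElement:
    base = dict(
        name="ISL",
        joint="L4/L5",
        attach_inferior=PointRef("L5", "a", np.zeros(3)),
        attach_superior=PointRef("L4", "b", np.array([0.0, 10.0, 0.0])),
        n=1,
        l_neut=10.0,
        eps_pre=0.05,
        eps_A=0.1,
        eps_B=0.3,
        F_A=100.0,
        F_B=400.0,
    )
    base.update(kw)
    return LigamentElement(**base)


class TestLigamentLaw:
    def test_derived_parameter_chain_hand_computed(self):
        lig = _lig()
        assert lig.l_0 == pytest.approx(9.5)
        assert lig.l_A == pytest.approx(10.45)
        assert lig.K_lin == pytest.approx(157.89, abs=0.01)
        assert lig.eps_lin == pytest.approx(0.06667, abs=1e-4)
        assert lig.exp_nll == pytest.approx(1.5, abs=1e-9)
        assert lig.K_nl == pytest.approx(108.0, abs=0.1)
        assert ligament_force(lig, 10.0) == pytest.approx(38.2, abs=0.1)

    def test_slack_below_rest_length(self):
        lig = _lig()
        assert ligament_force(lig, lig.l_0) == 0.0
        assert ligament_force(lig, 0.5 * lig.l_0) == 0.0

    def test_both_branches_agree_at_transition(self):
        lig = _lig()
        assert ligament_force(lig, lig.l_A) == pytest.approx(lig.F_A, rel=1e-9)

    def test_parallel_components_share_the_whole_ligament_force(self):
        # F_A/F_B are whole-ligament forces, so splitting the ligament into
        # n parallel components must leave the whole-ligament curve unchanged
        one = _lig(n=1)
        two = _lig(n=2)
        for l in (9.8, 10.2, two.l_A, 11.5, 13.0):
            assert ligament_force(two, l) == pytest.approx(ligament_force(one, l), rel=1e-9)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            ligament_force(_lig(), -1.0)

    @given(
        l_neut=st.floats(5.0, 60.0),
        eps_pre=st.floats(-0.08, 0.08),
        eps_a=st.floats(0.03, 0.2),
        deps=st.floats(0.05, 0.4),
        f_a=st.floats(10.0, 200.0),
        df=st.floats(10.0, 400.0),
        n=st.integers(1, 4),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_c0_c1_continuity_and_monotonicity(self, l_neut, eps_pre, eps_a, deps, f_a, df, n):
        """The toe branch meets the linear branch with matching value and slope,
        and the force never decreases with length, for any valid parameter set."""
        lig = _lig(
            l_neut=l_neut, eps_pre=eps_pre, eps_A=eps_a, eps_B=eps_a + deps,
            F_A=f_a, F_B=f_a + df, n=n,
        )
        x = lig.l_A - lig.l_0
        # C0 at l_A: toe branch evaluated at l_A meets the linear branch value
        toe_at_a = lig.n * lig.K_nl * x**lig.exp_nll
        assert toe_at_a == pytest.approx(lig.F_A, rel=1e-9)
        # C1 at l_A: toe-branch derivative equals the linear stiffness
        toe_slope = lig.n * lig.exp_nll * lig.K_nl * x ** (lig.exp_nll - 1.0)
        assert toe_slope == pytest.approx(n * lig.K_lin, rel=1e-9)
        # monotone non-decreasing over the whole range
        ls = np.linspace(0.0, 1.5 * lig.l_B, 200)
        fs = [ligament_force(lig, l) for l in ls]
        assert np.all(np.diff(fs) >= -1e-9)

    def test_invalid_breakpoints_rejected(self):
        with pytest.raises(ValueError):
            _lig(eps_A=0.3, eps_B=0.3)
        with pytest.raises(ValueError):
            _lig(F_A=400.0, F_B=400.0)


class TestPreStrain:
    def test_zero_pre_strain_unloaded_at_neutral(self):
        lig = derive_ligament_params(
            "ALL", "L4/L5",
            PointRef("L5", "a", np.zeros(3)), PointRef("L4", "b", np.array([0.0, 12.0, 0.0])),
            n=1, eps_pre=0.0, eps_A=0.1, eps_B=0.3, F_A=100.0, F_B=300.0,
        )
        assert lig.l_0 == pytest.approx(12.0)
        assert ligament_force(lig, lig.l_neut) == 0.0

    def test_positive_pre_strain_loaded_at_neutral(self):
        lig = _lig(eps_pre=0.05)
        assert ligament_force(lig, lig.l_neut) > 0.0

    def test_negative_pre_strain_slack_at_neutral(self):
        lig = _lig(eps_pre=-0.05)
        assert ligament_force(lig, lig.l_neut) == 0.0


class TestDisc:
    DISC = DiscElement("L4/L5", [2.0, 1.0, 2.0], [1.5, 4.0, 1.0])

    def test_zero_inside_neutral_zone(self):
        assert np.allclose(disc_moment(self.DISC, [1.0, 0.5, -1.5]), 0.0)

    def test_restoring_beyond_neutral_zone(self):
        m = disc_moment(self.DISC, [0.0, 0.0, 5.0])
        assert m[2] == pytest.approx(-3.0)  # k=1, NZ=2, theta=5 -> 3 N*m restoring

    def test_odd_function(self):
        th = np.array([3.0, -2.5, 6.0])
        assert np.allclose(disc_moment(self.DISC, th), -disc_moment(self.DISC, -th))


class TestDefaultParameters:
    def test_five_ligament_systems_with_published_pre_strains(self):
        params = load_param_json("ligaments")["ligaments"]
        assert set(params) == {"ALL", "PLL", "LF", "ISL", "SSL"}
        assert params["LF"]["eps_pre"] == pytest.approx(0.05)
        assert params["SSL"]["eps_pre"] < 0.0


class TestMuscles:
    def test_default_table_has_9_groups_103_actuators(self, straight_geometry):
        geoms, _tr = straight_geometry
        muscles = build_muscles(geoms, default_generic_points(geoms))
        assert len(muscles) == 103
        assert len({m.group for m in muscles}) == 9

    def test_merge_sums_pcsa(self, straight_geometry):
        geoms, _tr = straight_geometry
        table = [
            {"group": "MF", "side": "left", "origin": "L1:spinous_inferior",
             "insertion": "L3:transverse_left_superior", "pcsa_cm2": 0.6},
            {"group": "MF", "side": "left", "origin": "L1:spinous_inferior",
             "insertion": "L3:transverse_left_superior", "pcsa_cm2": 0.4},
        ]
        muscles = build_muscles(geoms, default_generic_points(geoms), table)
        assert len(muscles) == 1
        assert muscles[0].pcsa_cm2 == pytest.approx(1.0)

    def test_unresolvable_landmark_listed_in_error(self, straight_geometry):
        geoms, _tr = straight_geometry
        table = [
            {"group": "MF", "side": "left", "origin": "L1:no_such_point",
             "insertion": "L3:transverse_left_superior", "pcsa_cm2": 1.0}
        ]
        with pytest.raises(MuscleAssemblyError, match="no_such_point"):
            build_muscles(geoms, default_generic_points(geoms), table)

    def test_thoracic_multifidus_and_interspinales_unit_pcsa(self):
        entries = default_muscle_table()
        is_entries = [e for e in entries if e["group"] == "IS"]
        mft = [e for e in entries if e["group"] == "MF" and e["origin"].startswith("T")]
        assert is_entries and all(e["pcsa_cm2"] == 1.0 for e in is_entries)
        assert mft and all(e["pcsa_cm2"] == 1.0 for e in mft)


class TestAssembly:
    def test_total_mass_is_sum_of_parts(self, straight_model):
        s = sum(b.mass_kg for n, b in straight_model.bodies.items() if n != "ground")
        assert straight_model.total_mass_kg == pytest.approx(s)

    def test_symmetric_fixture_com_on_midplane(self, straight_model):
        mid_z = straight_model.bodies["L3"].com_mm[2]
        assert abs(straight_model.com()[2] - mid_z) < 2.0

    def test_joint_chain_ordered_caudal_to_cranial(self, straight_model):
        ys = [j.origin[1] for j in straight_model.joints]
        assert np.all(np.diff(ys) > 0)

    def test_serialization_round_trip(self, straight_model):
        d = json.loads(json.dumps(straight_model.to_dict()))
        m2 = SpineModel.from_dict(d)
        assert m2.joint_names == straight_model.joint_names
        assert m2.total_mass_kg == pytest.approx(straight_model.total_mass_kg)
        assert len(m2.ligaments) == len(straight_model.ligaments)
        l1, l2 = straight_model.ligaments[3], m2.ligaments[3]
        assert l2.K_nl == pytest.approx(l1.K_nl)
        assert np.allclose(m2.joints[0].orientation, straight_model.joints[0].orientation)
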