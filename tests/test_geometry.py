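"""Landmark extraction, realignment, joint frames and alignment metrics."""

import numpy as np
import pytest

from spineforge.geometry import (
    MissingLandmarkError,
    RigidTransform,
    extract_all,
    extract_landmarks,
    joint_center,
    joint_orientation,
    measure_alignment,
    realign_craniocaudal,
)
from spineforge.synthetic_spine import SpineParams, generate_spine_volume
from spineforge.volume import LabeledVolume


class TestRealign:
    def test_already_vertical_gives_identity_rotation(self):
        tr = realign_craniocaudal({"T1": np.array([0.0, 400.0, 0.0]), "L5": np.zeros(3)})
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-12)

    def test_tilted_line_maps_onto_vertical_axis(self):
        tr = realign_craniocaudal({"T1": np.array([50.0, 400.0, 0.0]), "L5": np.zeros(3)})
        t1 = tr.apply(np.array([50.0, 400.0, 0.0]))
        l5 = tr.apply(np.zeros(3))
        assert np.allclose(l5, 0.0, atol=1e-9)
        assert t1[0] == pytest.approx(0.0, abs=1e-9)
        assert t1[2] == pytest.approx(0.0, abs=1e-9)
        assert t1[1] > 0
        # rigid: lengths preserved
        assert np.linalg.norm(t1 - l5) == pytest.approx(np.linalg.norm([50.0, 400.0, 0.0]))

    def test_idempotent_on_aligned_input(self):
        tr = realign_craniocaudal({"T1": np.array([50.0, 400.0, 0.0]), "L5": np.zeros(3)})
        t1a = tr.apply(np.array([50.0, 400.0, 0.0]))
        tr2 = realign_craniocaudal({"T1": t1a, "L5": tr.apply(np.zeros(3))})
        assert np.allclose(tr2.rotation, np.eye(3), atol=1e-9)

    def test_missing_boundary_vertebra_raises(self):
        with pytest.raises(ValueError, match="T1"):
            realign_craniocaudal({"L5": np.zeros(3)})


class TestLandmarks:
    def test_left_right_mirror_within_one_voxel(self, straight_geometry, straight_params):
        geoms, _tr = straight_geometry
        vs = straight_params.voxel_size
        g = geoms["L3"]
        mid_z = g.centroid[2]
        left = g.landmarks["transverse_left_lateral"]
        right = g.landmarks["transverse_right_lateral"]
        assert abs((left[2] - mid_z) + (right[2] - mid_z)) <= vs
        assert abs(left[0] - right[0]) <= vs
        assert abs(left[1] - right[1]) <= vs

    def test_body_lateral_points_at_cylinder_radius(self, straight_geometry, straight_params):
        geoms, _tr = straight_geometry
        g = geoms["L3"]
        r = straight_params.vertebra_width / 2.0
        for name in ("body_left_lateral", "body_right_lateral"):
            d = abs(g.landmarks[name][2] - g.centroid[2])
            assert d == pytest.approx(r, abs=1.5 * straight_params.voxel_size)

    def test_spinous_posterior_is_extreme_point(self, straight_volumes):
        inst, sub = straight_volumes
        g = extract_landmarks(inst, sub, "L2")
        spin = inst.world_coords(
            (inst.voxels == inst.label_map["L2"]) & (sub.voxels == sub.label_map["spinous_process"])
        )
        assert g.landmarks["spinous_posterior"][0] == pytest.approx(spin[:, 0].min())

    def test_missing_subregion_error_names_it(self, straight_volumes):
        inst, sub = straight_volumes
        cropped = LabeledVolume(
            np.where(sub.voxels == sub.label_map["spinous_process"], 0, sub.voxels),
            sub.affine,
            sub.label_map,
        )
        with pytest.raises(MissingLandmarkError, match="spinous_process"):
            extract_landmarks(inst, cropped, "L2")

    def test_landmarks_inside_dilated_instance_box(self, straight_geometry, straight_volumes, straight_params):
        geoms, tr = straight_geometry
        inst, _sub = straight_volumes
        vs = straight_params.voxel_size
        for lev in ("T6", "L1", "L4"):
            pts = tr.apply(inst.world_coords(inst.voxels == inst.label_map[lev]))
            lo, hi = pts.min(axis=0) - vs, pts.max(axis=0) + vs
            for name, p in geoms[lev].landmarks.items():
                assert np.all(p >= lo - 1e-9) and np.all(p <= hi + 1e-9), (lev, name)

    def test_sagittal_mirror_reflects_landmarks(self):
        params = SpineParams(cobb_deg=12.0, seed=5)
        inst, sub = generate_spine_volume(params)
        # anatomical mirror: flip the lateral axis (world z' = -z) and swap
        # the left/right subregion codes so labels keep their meaning
        flip = lambda v: v[:, :, ::-1].copy()
        nz = inst.voxels.shape[2]
        aff = inst.affine.copy()
        aff[2, 3] = -(aff[2, 3] + aff[2, 2] * (nz - 1))
        sub_f = flip(sub.voxels)
        lc, rc = sub.label_map["transverse_left"], sub.label_map["transverse_right"]
        swapped = sub_f.copy()
        swapped[sub_f == lc] = rc
        swapped[sub_f == rc] = lc
        m_inst = LabeledVolume(flip(inst.voxels), aff, inst.label_map)
        m_sub = LabeledVolume(swapped, aff, sub.label_map)
        g = extract_all(inst, sub)[0]["T6"]
        gm = extract_all(m_inst, m_sub)[0]["T6"]
        for a, b in (
            ("transverse_left_lateral", "transverse_right_lateral"),
            ("spinous_posterior", "spinous_posterior"),
            ("body_left_lateral", "body_right_lateral"),
        ):
            assert np.allclose(
                g.landmarks[a] * [1, 1, -1], gm.landmarks[b], atol=2.1 * params.voxel_size
            ), (a, b)


class TestJointFrames:
    def test_joint_center_is_endplate_midpoint(self, straight_geometry):
        geoms, _tr = straight_geometry
        c = joint_center(geoms["L5"], geoms["L4"])
        expect = 0.5 * (
            geoms["L5"].endplate_superior_center + geoms["L4"].endplate_inferior_center
        )
        assert np.allclose(c, expect)

    def test_non_adjacent_levels_rejected(self, straight_geometry):
        geoms, _tr = straight_geometry
        with pytest.raises(ValueError):
            joint_center(geoms["L5"], geoms["L3"])

    def test_collinear_vertical_centroids_give_identity(self):
        cents = [np.array([0.0, y, 0.0]) for y in (300.0, 200.0, 100.0, 0.0)]
        R = joint_orientation(cents, np.array([0.0, 150.0, 0.0]))
        assert np.allclose(R, np.eye(3), atol=1e-9)

    def test_planar_sagittal_curve_keeps_world_lateral_axis(self):
        s = np.linspace(0, 1, 8)
        cents = [np.array([30.0 * np.sin(2 * t), 400.0 * (1 - t), 0.0]) for t in s]
        R = joint_orientation(cents, cents[3])
        assert np.allclose(R[:, 2], [0.0, 0.0, 1.0], atol=1e-9)
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_repeated_centroids_rejected(self):
        cents = [np.zeros(3), np.zeros(3), np.array([0, 1, 0.0]), np.array([0, 2, 0.0])]
        with pytest.raises(ValueError):
            joint_orientation(cents, np.zeros(3))

    def test_joint_centers_strictly_ordered_superiorly(self, lordotic_geometry):
        geoms, _tr = lordotic_geometry
        order = ["SACRUM", "L5", "L4", "L3", "L2", "L1"]
        ys = [
            joint_center(geoms[lo], geoms[hi])[1]
            for lo, hi in zip(order[:-1], order[1:])
        ]
        assert np.all(np.diff(ys) > 0)


class TestAlignment:
    def test_straight_fixture_measures_zero(self, straight_geometry):
        geoms, _tr = straight_geometry
        rep = measure_alignment(geoms)
        assert abs(rep.lumbar_lordosis_deg) < 1.0
        assert abs(rep.thoracic_kyphosis_deg) < 1.0
        assert abs(rep.cobb_deg) < 1.0

    def test_lordotic_fixture_round_trip(self, lordotic_geometry):
        geoms, _tr = lordotic_geometry
        rep = measure_alignment(geoms)
        assert rep.lumbar_lordosis_deg == pytest.approx(29.0, abs=3.0)
        assert rep.thoracic_kyphosis_deg == pytest.approx(31.0, abs=3.0)

    def test_scoliotic_fixture_round_trip(self):
        inst, sub = generate_spine_volume(SpineParams(cobb_deg=18.0, seed=2))
        geoms, _tr = extract_all(inst, sub)
        rep = measure_alignment(geoms)
        assert rep.cobb_deg == pytest.approx(18.0, abs=3.0)

    def test_missing_boundary_vertebra_raises(self, straight_geometry):
        geoms, _tr = straight_geometry
        partial = {k: v for k, v in geoms.items() if k != "T12"}
        with pytest.raises(ValueError, match="T12"):
            measure_alignment(partial)


def test_resolution_convergence_of_landmarks():
    """Halving the voxel size moves each landmark by less than the coarse voxel."""
    coarse = SpineParams(lumbar_lordosis_deg=15.0, voxel_size=3.0, seed=1)
    fine = SpineParams(lumbar_lordosis_deg=15.0, voxel_size=1.5, seed=1)
    gc = extract_all(*generate_spine_volume(coarse))[0]["L3"]
    gf = extract_all(*generate_spine_volume(fine))[0]["L3"]
    for name in ("body_left_lateral", "spinous_posterior", "transverse_right_lateral"):
        d = np.linalg.norm(gc.landmarks[name] - gf.landmarks[name])
        assert d <= coarse.voxel_size * 1.5, name
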