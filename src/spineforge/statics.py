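"""Postures, load cases and inverse statics on the assembled model.

Poses are chains of joint rotations: each actuated joint rotates every
body superior to it about the joint's own (already posed) origin and
frame.  Trunk flexion splits into 40% sacral rotation and 60% lumbar
flexion, the lumbar share distributed 25.5 / 23.1 / 20.4 / 18.5 / 12.5 %
over L1/L2 ... L5/S1 — the fixed lumbopelvic rhythm used for all flexion
angles.  The sacral share is applied as a base rotation at the
lumbosacral joint (the pelvis is the mechanical ground here).

Net joint moments are what the joint actuators must supply to hold a
posture: moments of gravity and external loads on the superstructure
about the joint, net of the passive ligament and disc contributions,
expressed in the joint frame.  Sign convention: +Z moments are extension
(sagittal), +X lateral bending (frontal); flexion postures therefore use
negative sagittal rotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .anatomy import SpineModel, disc_moment, ligament_force, superstructure
from .geometry import RigidTransform

__all__ = [
    "Posture",
    "LoadCase",
    "ExternalLoad",
    "LUMBAR_FLEXION_SPLIT",
    "SACRAL_FRACTION",
    "flexion_posture",
    "neutral_posture",
    "compose_postures",
    "apply_load_case",
    "pose_model",
    "net_joint_moments",
]

#: lumbopelvic rhythm: sacral share of trunk flexion, lumbar share split
SACRAL_FRACTION = 0.40
LUMBAR_FLEXION_SPLIT: dict[str, float] = {
    "L1/L2": 0.255,
    "L2/L3": 0.231,
    "L3/L4": 0.204,
    "L4/L5": 0.185,
    "L5/S1": 0.125,
}


@dataclass
class Posture:
    """Joint rotations in degrees about the joint axes (X frontal, Y axial, Z sagittal)."""

    joint_rotations_deg: dict[str, np.ndarray] = field(default_factory=dict)
    sacral_tilt_deg: float = 0.0

    def rotation(self, joint: str) -> np.ndarray:
        return np.asarray(self.joint_rotations_deg.get(joint, np.zeros(3)), float)


@dataclass
class LoadCase:
    """A static loading task.

    ``hand_mass_kg`` acts as a point load rigidly attached to the thorax at
    ``load_offset_mm`` anterior of the named reference point ('chest' on
    the thorax or 'sacrum_ref' on the ground body); ``arms_elevated``
    repositions the arm dummy centres of mass to shoulder height at a
    configurable anterior offset.
    """

    name: str
    trunk_flexion_deg: float = 0.0
    hand_mass_kg: float = 0.0
    load_offset_mm: float = 0.0
    reference: str = "chest"
    arms_elevated: bool = False
    arm_elevation_offset_mm: tuple[float, float] = (150.0, 250.0)  # anterior, superior

    def __post_init__(self) -> None:
        if self.hand_mass_kg < 0:
            raise ValueError("hand mass must be non-negative")


@dataclass
class ExternalLoad:
    body: str
    position_mm: np.ndarray  # neutral position; follows the body's pose
    force_n: np.ndarray  # world frame


def flexion_posture(model: SpineModel, trunk_flexion_deg: float) -> Posture:
    """Distribute trunk flexion over the sacrum and the lumbar joints.

    Sacral rotation takes 40% of the trunk angle, lumbar flexion the
    remaining 60% with the fixed per-level split.  Flexion is a negative
    rotation about +Z.  Angles outside the validated 0-45 degree range
    only raise a warning.
    """
    if not 0.0 <= trunk_flexion_deg <= 45.0:
        warnings.warn(
            f"trunk flexion {trunk_flexion_deg} deg outside the validated 0-45 deg range",
            stacklevel=2,
        )
    lumbar_total = (1.0 - SACRAL_FRACTION) * trunk_flexion_deg
    rots = {
        joint: np.array([0.0, 0.0, -frac * lumbar_total])
        for joint, frac in LUMBAR_FLEXION_SPLIT.items()
    }
    return Posture(joint_rotations_deg=rots, sacral_tilt_deg=-SACRAL_FRACTION * trunk_flexion_deg)


def compose_postures(a: Posture, b: Posture) -> Posture:
    """Sum of two postures (joint rotations add; sacral tilts add).

    Used to superpose the optimized upright-standing compensation with a
    task posture such as distributed flexion.
    """
    joints = set(a.joint_rotations_deg) | set(b.joint_rotations_deg)
    return Posture(
        joint_rotations_deg={j: a.rotation(j) + b.rotation(j) for j in joints},
        sacral_tilt_deg=a.sacral_tilt_deg + b.sacral_tilt_deg,
    )


def apply_load_case(model: SpineModel, case: LoadCase) -> tuple[list[ExternalLoad], dict[str, np.ndarray]]:
    """External loads and centre-of-mass overrides realizing a load case."""
    loads: list[ExternalLoad] = []
    com_overrides: dict[str, np.ndarray] = {}
    if case.hand_mass_kg > 0:
        if case.reference == "chest":
            ref_body, ref = "thorax", model.point("thorax", "chest")
        elif case.reference in ("sacrum", "sacrum_ref"):
            ref_body, ref = "thorax", model.point("ground", "sacrum_ref")
            # the load is carried in the hands, hence rides on the thorax,
            # even when its lever arm is specified from the sacrum
        else:
            raise KeyError(f"unknown load reference {case.reference!r}")
        pos = ref + np.array([case.load_offset_mm, 0.0, 0.0])
        f = np.array([0.0, -case.hand_mass_kg * model.gravity_m_s2, 0.0])
        loads.append(ExternalLoad(body=ref_body, position_mm=pos, force_n=f))
    if case.arms_elevated:
        da, ds = case.arm_elevation_offset_mm
        for sd in ("left", "right"):
            shoulder = model.point("thorax", f"shoulder_{sd}")
            com_overrides[f"arm_{sd}"] = shoulder + np.array([da, ds, 0.0])
    return loads, com_overrides


# ------------------------------------------------------------------------- posing


def pose_model(model: SpineModel, posture: Posture) -> dict[str, RigidTransform]:
    """Rigid transform per body realizing the posture by chain kinematics.

    Joint rotations are applied caudal to cranial about each joint's
    current origin and frame; the sacral tilt acts as a base rotation at
    the lumbosacral joint affecting the whole superstructure.
    """
    poses = {name: RigidTransform.identity() for name in model.bodies}
    acc = RigidTransform.identity()

    def joint_rotation(origin: np.ndarray, axes: np.ndarray, angles_deg: np.ndarray) -> RigidTransform:
        rx, ry, rz = np.deg2rad(angles_deg)

        def about(axis: np.ndarray, a: float) -> np.ndarray:
            axis = axis / np.linalg.norm(axis)
            K = np.array(
                [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
            )
            return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)

        R = about(axes[:, 0], rx) @ about(axes[:, 1], ry) @ about(axes[:, 2], rz)
        return RigidTransform(R, origin - R @ origin)

    base = model.joint("L5/S1")
    if abs(posture.sacral_tilt_deg) > 0:
        acc = joint_rotation(
            base.origin, base.orientation, np.array([0.0, 0.0, posture.sacral_tilt_deg])
        )

    for jf in model.joints:  # ordered caudal -> cranial
        origin = acc.apply(jf.origin)
        axes = acc.rotation @ jf.orientation
        acc = joint_rotation(origin, axes, posture.rotation(jf.name)).compose(acc)
        sup_body = superstructure(jf.name)[0]
        poses[sup_body] = acc
    poses["arm_left"] = poses["thorax"]
    poses["arm_right"] = poses["thorax"]
    return poses


def _posed_elements(
    model: SpineModel,
    posture: Posture,
    case: LoadCase | None,
):
    """Posed COMs, joint frames, ligament endpoint positions and external loads."""
    loads: list[ExternalLoad] = []
    com_overrides: dict[str, np.ndarray] = {}
    if case is not None:
        loads, com_overrides = apply_load_case(model, case)
    poses = pose_model(model, posture)
    coms = {}
    for name, b in model.bodies.items():
        com0 = com_overrides.get(name, b.com_mm)
        coms[name] = poses[name].apply(com0)
    jframes = {}
    for jf in model.joints:
        # a joint moves with its inferior body
        sup = superstructure(jf.name)[0]
        inf_pose = poses[{"L5": "ground", "L4": "L5", "L3": "L4", "L2": "L3", "L1": "L2", "thorax": "L1"}[sup]]
        jframes[jf.name] = (inf_pose.apply(jf.origin), inf_pose.rotation @ jf.orientation)
    lig_pts = [
        (
            poses[l.attach_inferior.body].apply(l.attach_inferior.position),
            poses[l.attach_superior.body].apply(l.attach_superior.position),
        )
        for l in model.ligaments
    ]
    posed_loads = [
        ExternalLoad(ld.body, poses[ld.body].apply(ld.position_mm), ld.force_n) for ld in loads
    ]
    return poses, coms, jframes, lig_pts, posed_loads


def net_joint_moments(
    model: SpineModel,
    posture: Posture,
    case: LoadCase | None = None,
) -> dict[str, np.ndarray]:
    """Required actuator moment per joint (N*m, joint frame).

    For each joint, gravity on every superstructure body and every external
    load contributes ``(r - r_joint) x F``; ligaments crossing the joint
    pull the superstructure toward their inferior attachment; discs add
    their restoring moment.  The returned moment is what the actuators
    (muscles) must produce for equilibrium: minus the sum of all of the
    above.
    """
    _poses, coms, jframes, lig_pts, loads = _posed_elements(model, posture, case)
    g = np.array([0.0, -model.gravity_m_s2, 0.0])
    out: dict[str, np.ndarray] = {}
    for jf in model.joints:
        oj, Rj = jframes[jf.name]
        M = np.zeros(3)
        sup = superstructure(jf.name)
        for bname in sup:
            b = model.bodies[bname]
            if b.mass_kg <= 0:
                continue
            # moments in N*m: positions in mm -> 1e-3 m
            M += np.cross((coms[bname] - oj) * 1e-3, b.mass_kg * g)
        for ld in loads:
            if ld.body in sup:
                M += np.cross((ld.position_mm - oj) * 1e-3, ld.force_n)
        for lig, (p_inf, p_sup) in zip(model.ligaments, lig_pts):
            if lig.attach_superior.body not in sup or lig.attach_inferior.body in sup:
                continue
            d = p_inf - p_sup
            l = np.linalg.norm(d)
            f = ligament_force(lig, l)
            if f > 0:
                M += np.cross((p_sup - oj) * 1e-3, f * d / l)
        disc = model.discs.get(jf.name)
        if disc is not None:
            M += Rj @ disc_moment(disc, posture.rotation(jf.name))
        out[jf.name] = -(Rj.T @ M)
    return out


def neutral_posture(
    model: SpineModel,
    bounds_deg: float = 10.0,
    tol: float = 1e-10,
) -> Posture:
    """Upright-standing compensation: sagittal angles minimizing joint moments.

    Minimizes the sum of squared required sagittal moments over the six
    actuated joints (the energy-efficient stance), starting from zero
    angles with +-``bounds_deg`` bounds per joint.  Deterministic: fixed
    initialization and solver settings.
    """
    names = model.joint_names

    def posture_of(x: np.ndarray) -> Posture:
        return Posture({n: np.array([0.0, 0.0, xi]) for n, xi in zip(names, x)})

    def objective(x: np.ndarray) -> float:
        mom = net_joint_moments(model, posture_of(x))
        return float(sum(mom[n][2] ** 2 for n in names))

    res = minimize(
        objective,
        x0=np.zeros(len(names)),
        method="Powell",
        bounds=[(-bounds_deg, bounds_deg)] * len(names),
        options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 2000},
    )
    if not res.success and res.fun > tol:
        warnings.warn(f"neutral-posture optimization stopped early (residual {res.fun:.3g})")
    p = posture_of(res.x)
    p.objective = float(res.fun)  # type: ignore[attr-defined]
    return p
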