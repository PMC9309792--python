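"""Model assembly: bodies, joints, ligaments, discs and muscle fascicles.

The static model is a kinematic chain ground (sacrum/pelvis) -> L5 -> ... ->
L1 -> thorax, where the thorax fuses the thoracic spine, ribcage and
head-neck into one rigid body and two arm dummies ride on it.  Six actuated
spherical joints (L5/S1 up to T12/L1) articulate the chain.  Passive
elements are the five spinal ligament systems (anterior/posterior
longitudinal, flaval, interspinous, supraspinous) with a nonlinear
toe-region force-length law, and rotational disc elements with a neutral
zone.  The muscle apparatus is nine groups discretized into 103
point-to-point actuators bound to named vertebral landmarks or generic-body
points.

Ligament law (elongation ``l`` in mm, per parallel component)::

    F(l) = 0                            l <= l_0        (slack)
         = K_nl * (l - l_0)**exp_nll    l_0 < l <= l_A  (toe)
         = F_A_n + K_lin * (l - l_A)    l > l_A         (linear)

with the slack length ``l_0 = (1 - eps_pre) * l_neut`` set by the measured
neutral length and pre-strain, the breakpoints given as strains relative to
``l_0`` (which guarantees uniform preload within one ligamentous structure),
and ``exp_nll = eps_A / eps_lin``, ``K_nl = F_A_n / (eps_A * l_0)**exp_nll``
chosen so the toe branch meets the linear branch at ``l_A`` with matching
value and slope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .geometry import JointFrame, VertebraGeometry, joint_center, joint_orientation
from .mass_model import TissueSegment

__all__ = [
    "PointRef",
    "LigamentElement",
    "DiscElement",
    "MuscleFascicle",
    "Body",
    "SpineModel",
    "JOINTS",
    "LIGAMENT_NAMES",
    "MUSCLE_GROUPS",
    "load_param_json",
    "ligament_force",
    "derive_ligament_params",
    "build_ligaments",
    "disc_moment",
    "build_discs",
    "default_muscle_table",
    "default_generic_points",
    "build_muscles",
    "assemble_model",
]

#: Actuated joints, ordered caudal to cranial.  Loads are commonly reported
#: at T12/L1 and L4/L5, so the thoracolumbar junction is articulated too.
JOINTS: tuple[str, ...] = ("L5/S1", "L4/L5", "L3/L4", "L2/L3", "L1/L2", "T12/L1")

LIGAMENT_NAMES = ("ALL", "PLL", "LF", "ISL", "SSL")
MUSCLE_GROUPS = ("RA", "IO", "EO", "PM", "QL", "MF", "LL", "IL", "IS")

#: chain order, ground first; arms are children of the thorax
BODY_CHAIN: tuple[str, ...] = ("ground", "L5", "L4", "L3", "L2", "L1", "thorax")

_JOINT_SUPERIOR_BODY = {
    "L5/S1": "L5",
    "L4/L5": "L4",
    "L3/L4": "L3",
    "L2/L3": "L2",
    "L1/L2": "L1",
    "T12/L1": "thorax",
}


def body_of_level(level: str) -> str:
    """Rigid body owning a vertebral level (thoracic levels fuse into the thorax)."""
    if level.startswith("T"):
        return "thorax"
    if level.startswith("L"):
        return level
    return "ground"  # sacrum / pelvis


def superstructure(joint: str) -> tuple[str, ...]:
    """Bodies superior to a joint (the part whose equilibrium the joint carries)."""
    chain = BODY_CHAIN[BODY_CHAIN.index(_JOINT_SUPERIOR_BODY[joint]) :]
    return chain + ("arm_left", "arm_right") if "thorax" in chain else chain


def load_param_json(name_or_path: str | Path) -> dict:
    """Load a parameter JSON, either a shipped default (by bare name) or a path."""
    p = Path(name_or_path)
    if p.exists():
        return json.loads(p.read_text())
    ref = resources.files("spineforge.data") / f"{name_or_path}.json"
    return json.loads(ref.read_text())


# ------------------------------------------------------------------------- elements


@dataclass
class PointRef:
    """A named point rigidly attached to a body, with its neutral position (mm)."""

    body: str
    name: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float)


@dataclass
class LigamentElement:
    """One ligament segment spanning one intervertebral joint.

    Raw parameters are the pre-strain, breakpoint strains/forces and the
    neutral length measured in the assembled model; all derived stiffnesses
    are computed on construction.
    """

    name: str
    joint: str
    attach_inferior: PointRef
    attach_superior: PointRef
    n: int
    l_neut: float
    eps_pre: float
    eps_A: float
    eps_B: float
    F_A: float
    F_B: float
    # derived (filled in __post_init__)
    l_0: float = 0.0
    l_A: float = 0.0
    l_B: float = 0.0
    F_A_n: float = 0.0
    F_B_n: float = 0.0
    K_lin: float = 0.0
    eps_lin: float = 0.0
    exp_nll: float = 0.0
    K_nl: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_A >= self.eps_B:
            raise ValueError(f"{self.name}@{self.joint}: eps_A must be < eps_B")
        if self.F_A >= self.F_B:
            raise ValueError(f"{self.name}@{self.joint}: F_A must be < F_B")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.l_neut <= 0:
            raise ValueError("l_neut must be positive")
        self.l_0 = (1.0 - self.eps_pre) * self.l_neut
        self.F_A_n = self.F_A / self.n
        self.F_B_n = self.F_B / self.n
        self.l_A = (1.0 + self.eps_A) * self.l_0
        self.l_B = (1.0 + self.eps_B) * self.l_0
        self.K_lin = (self.F_B_n - self.F_A_n) / (self.l_B - self.l_A)
        self.eps_lin = self.F_A_n / (self.K_lin * self.l_0)
        self.exp_nll = self.eps_A / self.eps_lin
        self.K_nl = self.F_A_n / (self.eps_A * self.l_0) ** self.exp_nll


def ligament_force(lig: LigamentElement, l: float) -> float:
    """Whole-ligament elastic force (N) at length ``l`` (mm).

    Piecewise: slack below ``l_0``, power-law toe up to ``l_A``, linear
    beyond; the per-component law is scaled by the ``n`` parallel
    components.  Non-negative and monotone non-decreasing in ``l``.
    """
    if l < 0:
        raise ValueError("ligament length must be non-negative")
    if l <= lig.l_0:
        per = 0.0
    elif l <= lig.l_A:
        per = lig.K_nl * (l - lig.l_0) ** lig.exp_nll
    else:
        per = lig.F_A_n + lig.K_lin * (l - lig.l_A)
    return lig.n * per


def derive_ligament_params(
    name: str,
    joint: str,
    attach_inferior: PointRef,
    attach_superior: PointRef,
    n: int,
    eps_pre: float,
    eps_A: float,
    eps_B: float,
    F_A: float,
    F_B: float,
) -> LigamentElement:
    """Build a ligament element, measuring ``l_neut`` from the neutral model.

    The neutral length is the attachment distance in the assembled neutral
    posture; expressing the breakpoints as strains relative to the slack
    length then yields uniform preloads within one ligamentous structure.
    """
    l_neut = float(np.linalg.norm(attach_superior.position - attach_inferior.position))
    return LigamentElement(
        name=name,
        joint=joint,
        attach_inferior=attach_inferior,
        attach_superior=attach_superior,
        n=n,
        l_neut=l_neut,
        eps_pre=eps_pre,
        eps_A=eps_A,
        eps_B=eps_B,
        F_A=F_A,
        F_B=F_B,
    )


@dataclass
class DiscElement:
    """Rotational intervertebral disc element with a neutral zone.

    Inside the neutral zone the disc produces no moment; beyond it the
    moment grows linearly with the excess rotation and opposes it.  The
    viscous part of the viscoelastic element vanishes at static
    equilibrium, so only this elastic law enters the statics.
    """

    joint: str
    neutral_zone_deg: np.ndarray
    stiffness_nm_per_deg: np.ndarray

    def __post_init__(self) -> None:
        self.neutral_zone_deg = np.asarray(self.neutral_zone_deg, float)
        self.stiffness_nm_per_deg = np.asarray(self.stiffness_nm_per_deg, float)
        if np.any(self.neutral_zone_deg < 0) or np.any(self.stiffness_nm_per_deg < 0):
            raise ValueError("neutral zone and stiffness must be non-negative")


def disc_moment(disc: DiscElement, rotation_deg: np.ndarray) -> np.ndarray:
    """Restoring disc moment (N*m, joint frame) for a rotation in degrees.

    Odd in the rotation: zero inside the neutral zone, then
    ``-sign(theta) * k * (|theta| - NZ)`` per axis.
    """
    th = np.asarray(rotation_deg, float)
    excess = np.maximum(np.abs(th) - disc.neutral_zone_deg, 0.0)
    return -np.sign(th) * disc.stiffness_nm_per_deg * excess


@dataclass
class MuscleFascicle:
    group: str
    side: str  # left / right / midline
    origin: PointRef
    insertion: PointRef
    pcsa_cm2: float

    def __post_init__(self) -> None:
        if self.pcsa_cm2 <= 0:
            raise ValueError("pcsa must be positive")
        if np.allclose(self.origin.position, self.insertion.position):
            raise ValueError("origin and insertion coincide")


@dataclass
class Body:
    name: str
    mass_kg: float
    com_mm: np.ndarray
    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.com_mm = np.asarray(self.com_mm, float)


# ------------------------------------------------------------------------ model


@dataclass
class SpineModel:
    """Assembled static model: a serializable bag of bodies, joints and elements."""

    bodies: dict[str, Body]
    joints: list[JointFrame]
    ligaments: list[LigamentElement]
    discs: dict[str, DiscElement]
    muscles: list[MuscleFascicle]
    provenance: dict = field(default_factory=dict)
    gravity_m_s2: float = 9.81

    @property
    def joint_names(self) -> list[str]:
        return [j.name for j in self.joints]

    def joint(self, name: str) -> JointFrame:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(name)

    @property
    def total_mass_kg(self) -> float:
        return sum(b.mass_kg for b in self.bodies.values() if b.name != "ground")

    def com(self) -> np.ndarray:
        m = 0.0
        acc = np.zeros(3)
        for b in self.bodies.values():
            if b.name == "ground":
                continue
            m += b.mass_kg
            acc += b.mass_kg * b.com_mm
        return acc / m

    def point(self, body: str, name: str) -> np.ndarray:
        return self.bodies[body].points[name]

    # -------------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        def pref(p: PointRef) -> dict:
            return {"body": p.body, "name": p.name, "position": p.position.tolist()}

        return {
            "gravity_m_s2": self.gravity_m_s2,
            "provenance": self.provenance,
            "bodies": {
                k: {
                    "name": b.name,
                    "mass_kg": b.mass_kg,
                    "com_mm": b.com_mm.tolist(),
                    "points": {n: p.tolist() for n, p in b.points.items()},
                }
                for k, b in self.bodies.items()
            },
            "joints": [
                {"name": j.name, "origin": j.origin.tolist(), "orientation": j.orientation.tolist()}
                for j in self.joints
            ],
            "ligaments": [
                {
                    "name": l.name,
                    "joint": l.joint,
                    "attach_inferior": pref(l.attach_inferior),
                    "attach_superior": pref(l.attach_superior),
                    "n": l.n,
                    "l_neut": l.l_neut,
                    "eps_pre": l.eps_pre,
                    "eps_A": l.eps_A,
                    "eps_B": l.eps_B,
                    "F_A": l.F_A,
                    "F_B": l.F_B,
                }
                for l in self.ligaments
            ],
            "discs": {
                k: {
                    "neutral_zone_deg": d.neutral_zone_deg.tolist(),
                    "stiffness_nm_per_deg": d.stiffness_nm_per_deg.tolist(),
                }
                for k, d in self.discs.items()
            },
            "muscles": [
                {
                    "group": m.group,
                    "side": m.side,
                    "origin": pref(m.origin),
                    "insertion": pref(m.insertion),
                    "pcsa_cm2": m.pcsa_cm2,
                }
                for m in self.muscles
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpineModel":
        def unpref(p: dict) -> PointRef:
            return PointRef(p["body"], p["name"], np.asarray(p["position"], float))

        return cls(
            bodies={
                k: Body(
                    name=b["name"],
                    mass_kg=b["mass_kg"],
                    com_mm=np.asarray(b["com_mm"], float),
                    points={n: np.asarray(p, float) for n, p in b["points"].items()},
                )
                for k, b in d["bodies"].items()
            },
            joints=[
                JointFrame(j["name"], np.asarray(j["origin"], float), np.asarray(j["orientation"], float))
                for j in d["joints"]
            ],
            ligaments=[
                LigamentElement(
                    name=l["name"],
                    joint=l["joint"],
                    attach_inferior=unpref(l["attach_inferior"]),
                    attach_superior=unpref(l["attach_superior"]),
                    n=l["n"],
                    l_neut=l["l_neut"],
                    eps_pre=l["eps_pre"],
                    eps_A=l["eps_A"],
                    eps_B=l["eps_B"],
                    F_A=l["F_A"],
                    F_B=l["F_B"],
                )
                for l in d["ligaments"]
            ],
            discs={
                k: DiscElement(k, np.asarray(v["neutral_zone_deg"], float), np.asarray(v["stiffness_nm_per_deg"], float))
                for k, v in d["discs"].items()
            },
            muscles=[
                MuscleFascicle(
                    group=m["group"],
                    side=m["side"],
                    origin=unpref(m["origin"]),
                    insertion=unpref(m["insertion"]),
                    pcsa_cm2=m["pcsa_cm2"],
                )
                for m in d["muscles"]
            ],
            provenance=d.get("provenance", {}),
            gravity_m_s2=d.get("gravity_m_s2", 9.81),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SpineModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# -------------------------------------------------------------------- construction


def _joint_pair(joint: str) -> tuple[str, str]:
    """(superior level, inferior level) of a joint name like 'L4/L5'."""
    sup, inf = joint.split("/")
    if inf == "S1":
        inf = "SACRUM"
    return sup, inf


def build_ligaments(
    geometries: dict[str, VertebraGeometry],
    params: dict | None = None,
) -> list[LigamentElement]:
    """Instantiate every ligament system at every actuated joint.

    Attachment landmarks come from the parameter table; at the lumbosacral
    joint posterior-element landmarks fall back to the sacral body rim
    (the synthetic sacrum carries no posterior elements).
    """
    if params is None:
        params = load_param_json("ligaments")
    ligs: list[LigamentElement] = []
    for joint in JOINTS:
        sup_lev, inf_lev = _joint_pair(joint)
        gs, gi = geometries[sup_lev], geometries[inf_lev]
        for name, p in params["ligaments"].items():
            inf_lm = p["attachment_inferior"]
            if inf_lm not in gi.landmarks:
                inf_lm = p["sacrum_attachment"]
            sup_lm = p["attachment_superior"]
            if sup_lm not in gs.landmarks:
                sup_lm = p["sacrum_attachment"]
            a_inf = PointRef(body_of_level(inf_lev), f"{inf_lev}:{inf_lm}", gi.landmarks[inf_lm])
            a_sup = PointRef(body_of_level(sup_lev), f"{sup_lev}:{sup_lm}", gs.landmarks[sup_lm])
            ligs.append(
                derive_ligament_params(
                    name,
                    joint,
                    a_inf,
                    a_sup,
                    n=int(p["n"]),
                    eps_pre=float(p["eps_pre"]),
                    eps_A=float(p["eps_A"]),
                    eps_B=float(p["eps_B"]),
                    F_A=float(p["F_A"]),
                    F_B=float(p["F_B"]),
                )
            )
    return ligs


def build_discs(params: dict | None = None) -> dict[str, DiscElement]:
    if params is None:
        params = load_param_json("discs")
    return {
        j: DiscElement(j, np.asarray(v["neutral_zone_deg"], float), np.asarray(v["stiffness_nm_per_deg"], float))
        for j, v in params["discs"].items()
    }


# ------------------------------------------------------------------ muscle tables


def default_generic_points(
    geometries: dict[str, VertebraGeometry], scale: float = 1.0
) -> dict[str, tuple[str, np.ndarray]]:
    """Named attachment points on the generic bodies (pelvis, ribcage, shoulders).

    Offsets are generic adult dimensions (mm) scaled with stature and
    anchored to the extracted sacrum and thoracic vertebra positions, so a
    patient-specific spine drags the generic frame along with it.
    """
    sac = geometries["SACRUM"].centroid

    def t(level: str) -> np.ndarray:
        return geometries[level].centroid

    pts: dict[str, tuple[str, np.ndarray]] = {}

    def pelvis(name: str, off: np.ndarray) -> None:
        pts[name] = ("ground", sac + scale * off)

    def thorax(name: str, anchor: np.ndarray, off: np.ndarray) -> None:
        pts[name] = ("thorax", anchor + scale * off)

    for sd, sz in (("left", 1.0), ("right", -1.0)):
        pelvis(f"iliac_crest_{sd}", np.array([-20.0, 20.0, sz * 110.0]))
        pelvis(f"iliac_crest_post_{sd}", np.array([-60.0, 0.0, sz * 45.0]))
        pelvis(f"psis_{sd}", np.array([-70.0, -10.0, sz * 40.0]))
        pelvis(f"mf_ilium_{sd}", np.array([-65.0, -25.0, sz * 55.0]))
        pelvis(f"pubis_{sd}", np.array([80.0, -60.0, sz * 30.0]))
        pelvis(f"femur_{sd}", np.array([20.0, -120.0, sz * 90.0]))
        thorax(f"sternum_{sd}", t("T8"), np.array([120.0, 0.0, sz * 40.0]))
        thorax(f"rib_lateral_{sd}", t("T8"), np.array([30.0, 0.0, sz * 130.0]))
        thorax(f"rib_lower_{sd}", t("T11"), np.array([60.0, -10.0, sz * 100.0]))
        thorax(f"rib12_post_{sd}", t("T12"), np.array([-40.0, 10.0, sz * 80.0]))
        thorax(f"rib_post_{sd}", t("T10"), np.array([-50.0, 0.0, sz * 60.0]))
        thorax(f"rib_angle_{sd}", t("T10"), np.array([-55.0, 0.0, sz * 85.0]))
        thorax(f"shoulder_{sd}", t("T2"), np.array([0.0, 0.0, sz * 180.0]))
    thorax("chest", t("T8"), np.array([120.0, 0.0, 0.0]))
    pelvis("sacrum_ref", np.zeros(3))
    return pts


def default_muscle_table() -> list[dict]:
    """Nine muscle groups discretized into 103 point-to-point actuators.

    Globally acting groups (rectus abdominis, internal/external obliques)
    and the ribcage-attached fascicles of longissimus, iliocostalis and
    quadratus lumborum are one actuator per side; the locally acting lumbar
    fascicles are enumerated per level.  Which fascicles merge into which
    actuator is a reconstruction: the table is built to the published group
    and actuator counts, with per-fascicle cross-sections in the range of
    validated lumbar-spine muscle architectures (thoracic multifidus and
    the interspinales carry the deliberately generous 1 cm^2 default).
    """
    entries: list[dict] = []

    def add(group: str, side: str, origin: str, insertion: str, pcsa: float) -> None:
        entries.append(
            {"group": group, "side": side, "origin": origin, "insertion": insertion, "pcsa_cm2": pcsa}
        )

    lumbar = ["L1", "L2", "L3", "L4", "L5"]
    for sd in ("left", "right"):
        lat = sd  # landmark suffix
        # global abdominal sheets: one actuator per side each
        add("RA", sd, f"PELVIS:pubis_{sd}", f"THORAX:sternum_{sd}", 5.7)
        add("EO", sd, f"PELVIS:iliac_crest_{sd}", f"THORAX:rib_lateral_{sd}", 14.7)
        add("IO", sd, f"PELVIS:iliac_crest_{sd}", f"THORAX:rib_lower_{sd}", 11.5)
        # psoas major: per-level body and transverse-process fascicles + T12
        body_pt = "body_left_lateral" if sd == "left" else "body_right_lateral"
        for lev in lumbar:
            add("PM", sd, f"{lev}:{body_pt}", f"PELVIS:femur_{sd}", 1.6)
            add("PM", sd, f"{lev}:transverse_{lat}_inferior", f"PELVIS:femur_{sd}", 1.6)
        add("PM", sd, f"T12:{body_pt}", f"PELVIS:femur_{sd}", 1.6)
        # quadratus lumborum: four lumbar fascicles + one ribcage actuator
        for lev in lumbar[:4]:
            add("QL", sd, f"{lev}:transverse_{lat}_lateral", f"PELVIS:iliac_crest_{sd}", 0.7)
        add("QL", sd, f"THORAX:rib12_post_{sd}", f"PELVIS:iliac_crest_{sd}", 2.5)
        # longissimus pars lumborum + thoracis
        for lev in lumbar:
            add("LL", sd, f"{lev}:transverse_{lat}_posterior", f"PELVIS:iliac_crest_post_{sd}", 1.5)
        add("LL", sd, f"THORAX:rib_post_{sd}", f"PELVIS:iliac_crest_post_{sd}", 12.0)
        # iliocostalis lumborum + thoracis
        for lev in lumbar[:4]:
            add("IL", sd, f"{lev}:transverse_{lat}_superior", f"PELVIS:iliac_crest_post_{sd}", 1.0)
        add("IL", sd, f"THORAX:rib_angle_{sd}", f"PELVIS:iliac_crest_post_{sd}", 9.0)
        # multifidus, lumbar part: short two-level fascicle, long fascicle and
        # an iliac fascicle per level (single iliac fascicle at L5)
        targets = ["L3", "L4", "L5", "SACRUM", f"PELVIS:psis_{sd}", f"PELVIS:iliac_crest_post_{sd}"]
        for i, lev in enumerate(lumbar):
            if lev != "L5":
                for tgt in (targets[i], targets[i + 1]):
                    ins = (
                        tgt
                        if ":" in tgt
                        else (
                            f"{tgt}:body_rim_post_sup"
                            if tgt == "SACRUM"
                            else f"{tgt}:transverse_{lat}_superior"
                        )
                    )
                    add("MF", sd, f"{lev}:spinous_inferior", ins, 1.2)
            add("MF", sd, f"{lev}:spinous_inferior", f"PELVIS:mf_ilium_{sd}", 1.3)
        # thoracic multifidus fascicles insert on the upper lumbar spine so
        # the thoracolumbar junction has dedicated differential extensors
        for tlev, llev in (
            ("T7", "L1"), ("T8", "L1"), ("T9", "L1"),
            ("T10", "L2"), ("T11", "L2"), ("T12", "L2"),
        ):
            add("MF", sd, f"{tlev}:spinous_inferior", f"{llev}:transverse_{lat}_superior", 1.0)
    # interspinales: midline, between adjacent spinous processes
    for i, lev in enumerate(lumbar):
        below = lumbar[i + 1] if i + 1 < len(lumbar) else "SACRUM"
        ins = f"{below}:spinous_superior" if below != "SACRUM" else "SACRUM:body_rim_post_sup"
        add("IS", "midline", f"{lev}:spinous_inferior", ins, 1.0)
    return entries


class MuscleAssemblyError(ValueError):
    pass


def build_muscles(
    geometries: dict[str, VertebraGeometry],
    generic_points: dict[str, tuple[str, np.ndarray]],
    table: list[dict] | None = None,
) -> list[MuscleFascicle]:
    """Resolve a fascicle table into bound actuators.

    Endpoint references are ``LEVEL:landmark`` (vertebral landmarks from the
    geometry module) or ``PELVIS:point`` / ``THORAX:point`` (generic-body
    points).  Fascicles of one group sharing both endpoint references are
    merged into a single actuator with summed cross-sectional area.
    Unresolvable references raise an assembly error listing them.
    """
    if table is None:
        table = default_muscle_table()

    def resolve(ref: str) -> PointRef:
        prefix, name = ref.split(":", 1)
        if prefix in ("PELVIS", "THORAX"):
            if name not in generic_points:
                raise MuscleAssemblyError(f"unresolvable generic point {ref!r}")
            body, pos = generic_points[name]
            return PointRef(body, ref, pos)
        if prefix not in geometries or name not in geometries[prefix].landmarks:
            raise MuscleAssemblyError(f"unresolvable landmark {ref!r}")
        return PointRef(body_of_level(prefix), ref, geometries[prefix].landmarks[name])

    merged: dict[tuple[str, str, str, str], dict] = {}
    missing: list[str] = []
    for e in table:
        key = (e["group"], e["side"], e["origin"], e["insertion"])
        if key in merged:
            merged[key]["pcsa_cm2"] += float(e["pcsa_cm2"])
        else:
            merged[key] = dict(e)
    fascicles: list[MuscleFascicle] = []
    for e in merged.values():
        try:
            o = resolve(e["origin"])
            i = resolve(e["insertion"])
        except MuscleAssemblyError as err:
            missing.append(str(err))
            continue
        fascicles.append(
            MuscleFascicle(
                group=e["group"], side=e["side"], origin=o, insertion=i, pcsa_cm2=float(e["pcsa_cm2"])
            )
        )
    if missing:
        raise MuscleAssemblyError("; ".join(missing))
    return fascicles


# ---------------------------------------------------------------------- assembly


def assemble_model(
    geometries: dict[str, VertebraGeometry],
    segments: list[TissueSegment],
    generic_masses: dict[str, float],
    bone_masses: dict[str, float],
    *,
    ligament_params: dict | None = None,
    disc_params: dict | None = None,
    muscle_table: list[dict] | None = None,
    provenance: dict | None = None,
) -> SpineModel:
    """Assemble the full static model from extracted and configured parts.

    Per-level soft-tissue segments are rigidly fixed to their vertebra at
    the calculated centres of mass; thoracic levels, the head-neck mass and
    the ribcage fuse into one thorax body; arm dummies hang from the
    shoulders.  Ligaments measure their neutral lengths from the assembled
    geometry.
    """
    seg_by_level = {s.level: s for s in segments}
    scale = float(generic_masses.get("scale", 1.0))
    gp = default_generic_points(geometries, scale)

    def level_mass_com(lev: str) -> tuple[float, np.ndarray]:
        m = bone_masses.get(lev, 0.0)
        acc = m * geometries[lev].centroid
        if lev in seg_by_level:
            s = seg_by_level[lev]
            m += s.mass_kg
            acc = acc + s.mass_kg * s.com_mm
        return m, acc / m if m > 0 else geometries[lev].centroid

    bodies: dict[str, Body] = {}
    # lumbar bodies
    for lev in ("L1", "L2", "L3", "L4", "L5"):
        m, com = level_mass_com(lev)
        bodies[lev] = Body(lev, m, com)
    # thorax fuses T1-T12 plus head-neck
    m_tot, acc = 0.0, np.zeros(3)
    for i in range(1, 13):
        m, com = level_mass_com(f"T{i}")
        m_tot += m
        acc += m * com
    head = float(generic_masses.get("head_neck", 0.0))
    if head > 0:
        head_com = geometries["T1"].centroid + scale * np.array([20.0, 180.0, 0.0])
        m_tot += head
        acc += head * head_com
    bodies["thorax"] = Body("thorax", m_tot, acc / m_tot)
    # arm dummies ride on the thorax; neutral pose: hanging at the sides
    for sd, sz in (("left", 1.0), ("right", -1.0)):
        am = float(generic_masses.get(f"arm_{sd}", 0.0))
        shoulder = gp[f"shoulder_{sd}"][1]
        bodies[f"arm_{sd}"] = Body(f"arm_{sd}", am, shoulder + scale * np.array([30.0, -250.0, 0.0]))
    bodies["ground"] = Body("ground", 0.0, geometries["SACRUM"].centroid)

    # attach generic points to their bodies for later reference
    for name, (body, pos) in gp.items():
        bodies[body].points[name] = pos

    # joints: centre = endplate midpoints, orientation = centroid-spline tangent
    order = [f"T{i}" for i in range(1, 13)] + ["L1", "L2", "L3", "L4", "L5", "SACRUM"]
    cents = [geometries[lev].centroid for lev in order if lev in geometries]
    joints: list[JointFrame] = []
    for jname in JOINTS:
        sup_lev, inf_lev = _joint_pair(jname)
        origin = joint_center(geometries[inf_lev], geometries[sup_lev])
        R = joint_orientation(cents, geometries[inf_lev].endplate_superior_center)
        joints.append(JointFrame(jname, origin, R))

    ligaments = build_ligaments(geometries, ligament_params)
    discs = build_discs(disc_params)
    muscles = build_muscles(geometries, gp, muscle_table)

    prov = dict(provenance or {})
    prov.setdefault("generic_masses", {k: v for k, v in generic_masses.items()})
    return SpineModel(
        bodies=bodies,
        joints=joints,
        ligaments=ligaments,
        discs=discs,
        muscles=muscles,
        provenance=prov,
    )
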