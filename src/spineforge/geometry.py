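"""Vertebral geometry: realignment, landmarks, joint frames, alignment metrics.

Works on multi-label instance masks plus subregion masks.  All coordinates
are world millimetres (voxel indices mapped through the NIfTI affine),
optionally after a rigid craniocaudal realignment that maps the T1-L5
centroid line onto the vertical axis — the supine-to-upright posture
correction applied before any landmark is measured.

Landmark extraction follows the extreme-value scheme: per subregion the
most posterior / superior / inferior / lateral surface points are taken
from minimal and maximal coordinate values; vertebral-body rim points come
from a rectangle fitted to the sagittal midplane cross-section whose
corner and edge-centre points are projected onto the body surface by
shortest distance; arch attachment points from the minimal distance
between the arch's anterior border and posterior body points in the
sagittal plane and two laterally shifted planes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar

from .synthetic_spine import LEVELS, SUBREGION_LABELS
from .volume import LabeledVolume

__all__ = [
    "RigidTransform",
    "VertebraGeometry",
    "JointFrame",
    "AlignmentReport",
    "MissingLandmarkError",
    "realign_craniocaudal",
    "extract_landmarks",
    "extract_all",
    "joint_center",
    "joint_orientation",
    "measure_alignment",
]

WORLD_ANTERIOR = np.array([1.0, 0.0, 0.0])
WORLD_SUPERIOR = np.array([0.0, 1.0, 0.0])
WORLD_LEFT = np.array([0.0, 0.0, 1.0])


class MissingLandmarkError(ValueError):
    """A required subregion is empty for the requested vertebra."""


@dataclass
class RigidTransform:
    """p' = R @ p + t (millimetres)."""

    rotation: np.ndarray
    translation: np.ndarray

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class VertebraGeometry:
    """Centroid, endplate centres and named landmarks of one vertebra (mm).

    ``axis`` is the measured local superior axis (mean of the two fitted
    endplate normals); when absent it falls back to the endplate-centre
    difference.
    """

    level: str
    centroid: np.ndarray
    endplate_superior_center: np.ndarray
    endplate_inferior_center: np.ndarray
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)
    axis: np.ndarray | None = None

    @property
    def superior_axis(self) -> np.ndarray:
        if self.axis is not None:
            return self.axis / np.linalg.norm(self.axis)
        d = self.endplate_superior_center - self.endplate_inferior_center
        return d / np.linalg.norm(d)

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "centroid": self.centroid.tolist(),
            "endplate_superior_center": self.endplate_superior_center.tolist(),
            "endplate_inferior_center": self.endplate_inferior_center.tolist(),
            "landmarks": {k: v.tolist() for k, v in self.landmarks.items()},
            "axis": None if self.axis is None else self.axis.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VertebraGeometry":
        return cls(
            level=d["level"],
            centroid=np.asarray(d["centroid"], float),
            endplate_superior_center=np.asarray(d["endplate_superior_center"], float),
            endplate_inferior_center=np.asarray(d["endplate_inferior_center"], float),
            landmarks={k: np.asarray(v, float) for k, v in d["landmarks"].items()},
            axis=None if d.get("axis") is None else np.asarray(d["axis"], float),
        )


@dataclass
class JointFrame:
    """Intervertebral joint origin and orientation.

    Orientation columns are the joint's anterior, superior and lateral
    (subject-left) axes; the matrix is a proper rotation.
    """

    name: str
    origin: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.orientation, float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
            raise ValueError("orientation must be a proper rotation matrix")
        self.orientation = R


@dataclass
class AlignmentReport:
    lumbar_lordosis_deg: float
    thoracic_kyphosis_deg: float
    cobb_deg: float

    def to_dict(self) -> dict:
        return {
            "lumbar_lordosis_deg": self.lumbar_lordosis_deg,
            "thoracic_kyphosis_deg": self.thoracic_kyphosis_deg,
            "cobb_deg": self.cobb_deg,
        }


# ----------------------------------------------------------------------- realignment


def realign_craniocaudal(centroids: dict[str, np.ndarray]) -> RigidTransform:
    """Rigid transform mapping the T1-L5 centroid line onto world vertical.

    The L5 centroid maps to the origin and T1 to a point on the +Y axis,
    removing the supine tilt of the scanned posture.
    """
    if "T1" not in centroids or "L5" not in centroids:
        raise ValueError("realignment needs both T1 and L5 centroids")
    t1 = np.asarray(centroids["T1"], float)
    l5 = np.asarray(centroids["L5"], float)
    u = t1 - l5
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        raise ValueError("T1 and L5 centroids coincide")
    u = u / nu
    v = WORLD_SUPERIOR
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, v))
    if s < 1e-12:
        R = np.eye(3) if c > 0 else _rotation_about(WORLD_ANTERIOR, np.pi)
    else:
        axis = axis / s
        R = _rotation_about(axis, np.arctan2(s, c))
    return RigidTransform(R, -R @ l5)


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


# ------------------------------------------------------------------------- landmarks


def _coords(volume: LabeledVolume, mask: np.ndarray, transform: RigidTransform) -> np.ndarray:
    return transform.apply(volume.world_coords(mask))


def _extreme(points: np.ndarray, axis: np.ndarray, direction: float, tol: float) -> np.ndarray:
    """Extreme point along ±axis; ties broken toward the point cloud centroid."""
    proj = points @ axis * direction
    cand = points[proj >= proj.max() - tol]
    if len(cand) == 1:
        return cand[0]
    center = points.mean(axis=0)
    return cand[np.argmin(np.linalg.norm(cand - center, axis=1))]


def _endplate_face(
    points: np.ndarray, axis_hint: np.ndarray, sign: float, vs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Centre and outward normal of one endplate of a vertebral body.

    The endplate is a near-planar cap of the body voxel cloud.  Starting
    from ``axis_hint`` (e.g. the centroid-chain tangent), a thin slab at the
    extreme of the projection is cut and the cap's plane normal re-estimated
    as the slab's minimum-variance principal axis — well conditioned because
    the cap is tens of millimetres wide but only a voxel or two thick.
    Three refinement passes suffice for sub-degree normals on clean masks.
    """
    ax = axis_hint / np.linalg.norm(axis_hint)
    center = points.mean(axis=0)
    for it in range(3):
        proj = points @ ax * sign
        thick = 2.0 * vs if it == 0 else 1.5 * vs
        slab = points[proj >= proj.max() - thick]
        center = slab.mean(axis=0)
        cov = np.cov((slab - center).T)
        _w, v = np.linalg.eigh(cov)
        n = v[:, 0]
        if n @ ax < 0:
            n = -n
        ax = n
    return center, sign * ax


def _surface(mask: np.ndarray) -> np.ndarray:
    """6-connected surface voxels of a boolean mask."""
    from scipy.ndimage import binary_erosion

    return mask & ~binary_erosion(mask)


def extract_landmarks(
    instance: LabeledVolume,
    subregion: LabeledVolume,
    level: str,
    transform: RigidTransform | None = None,
    axis_hint: np.ndarray | None = None,
) -> VertebraGeometry:
    """Extreme-value landmarks and endplate centres for one vertebra.

    ``transform`` is the craniocaudal realignment; landmark math happens in
    the realigned world frame.  ``axis_hint`` seeds the endplate-normal fit
    (the centroid-chain tangent when extracting a full spine; world
    superior otherwise).  Raises :class:`MissingLandmarkError` naming the
    subregion when a required subregion is empty (the sacrum only needs a
    body).
    """
    if transform is None:
        transform = RigidTransform.identity()
    lab = instance.label_id(level)
    inst_mask = instance.voxels == lab
    if not inst_mask.any():
        raise MissingLandmarkError(f"vertebra {level} absent from instance mask")
    vs = float(np.cbrt(instance.voxel_volume_mm3))
    sub = subregion.voxels

    def region(name: str) -> np.ndarray:
        return inst_mask & (sub == SUBREGION_LABELS[name])

    body_mask = region("body_cortex") | region("body_trabecular")
    if not body_mask.any():
        raise MissingLandmarkError(f"vertebral body empty for {level}")
    body = _coords(instance, body_mask, transform)
    centroid = body.mean(axis=0)
    hint = WORLD_SUPERIOR if axis_hint is None else np.asarray(axis_hint, float)

    ep_sup, n_sup = _endplate_face(body, hint, +1.0, vs)
    ep_inf, n_inf = _endplate_face(body, hint, -1.0, vs)
    axis = n_sup - n_inf  # n_inf points inferior; their difference averages both fits
    axis = axis / np.linalg.norm(axis)

    landmarks: dict[str, np.ndarray] = {}

    # most-lateral body points from the horizontal midplane slab
    proj = (body - centroid) @ axis
    mid = body[np.abs(proj) <= vs]
    landmarks["body_left_lateral"] = _extreme(mid, WORLD_LEFT, +1.0, 0.5 * vs)
    landmarks["body_right_lateral"] = _extreme(mid, WORLD_LEFT, -1.0, 0.5 * vs)

    # sagittal-midplane rectangle fit -> rim points projected to the surface
    surf = _coords(instance, _surface(body_mask), transform)
    sag = body[np.abs(body[:, 2] - centroid[2]) <= vs]
    x_lo, x_hi = sag[:, 0].min(), sag[:, 0].max()
    y_lo, y_hi = sag[:, 1].min(), sag[:, 1].max()
    x_mid, y_mid = 0.5 * (x_lo + x_hi), 0.5 * (y_lo + y_hi)
    rect = {
        "body_rim_ant_sup": (x_hi, y_hi),
        "body_rim_ant_inf": (x_hi, y_lo),
        "body_rim_post_sup": (x_lo, y_hi),
        "body_rim_post_inf": (x_lo, y_lo),
        "body_rim_ant_center": (x_hi, y_mid),
        "body_rim_post_center": (x_lo, y_mid),
        "body_rim_sup_center": (x_mid, y_hi),
        "body_rim_inf_center": (x_mid, y_lo),
    }
    for name, (rx, ry) in rect.items():
        target = np.array([rx, ry, centroid[2]])
        landmarks[name] = surf[np.argmin(np.linalg.norm(surf - target, axis=1))]

    geom = VertebraGeometry(
        level=level,
        centroid=centroid,
        endplate_superior_center=ep_sup,
        endplate_inferior_center=ep_inf,
        landmarks=landmarks,
        axis=axis,
    )
    if level == "SACRUM":
        return geom

    # posterior-element subregions: coordinate extremes
    for name, req in (
        ("spinous_process", True),
        ("transverse_left", True),
        ("transverse_right", True),
        ("arch", True),
    ):
        m = region(name)
        if not m.any():
            if req:
                raise MissingLandmarkError(f"subregion {name!r} empty for {level}")
            continue
        pts = _coords(instance, m, transform)
        short = {
            "spinous_process": "spinous",
            "transverse_left": "transverse_left",
            "transverse_right": "transverse_right",
            "arch": "arch",
        }[name]
        landmarks[f"{short}_posterior"] = _extreme(pts, WORLD_ANTERIOR, -1.0, 0.5 * vs)
        landmarks[f"{short}_superior"] = _extreme(pts, WORLD_SUPERIOR, +1.0, 0.5 * vs)
        landmarks[f"{short}_inferior"] = _extreme(pts, WORLD_SUPERIOR, -1.0, 0.5 * vs)
        if name == "transverse_left":
            landmarks["transverse_left_lateral"] = _extreme(pts, WORLD_LEFT, +1.0, 0.5 * vs)
        if name == "transverse_right":
            landmarks["transverse_right_lateral"] = _extreme(pts, WORLD_LEFT, -1.0, 0.5 * vs)

    # arch attachment points: minimal distance between the arch's anterior
    # border and posterior body points, in three sagittal slabs
    arch_pts = _coords(instance, region("arch"), transform)
    post_body = surf[surf[:, 0] <= centroid[0]]
    for tag, shift in (("center", 0.0), ("left", 12.0), ("right", -12.0)):
        z0 = centroid[2] + shift
        a_sl = arch_pts[np.abs(arch_pts[:, 2] - z0) <= 1.5 * vs]
        b_sl = post_body[np.abs(post_body[:, 2] - z0) <= 1.5 * vs]
        if len(a_sl) == 0 or len(b_sl) == 0:
            continue
        # anterior border of the arch slab
        front = a_sl[a_sl[:, 0] >= a_sl[:, 0].max() - 1.5 * vs]
        d = np.linalg.norm(front[:, None, :] - b_sl[None, :, :], axis=2)
        i, _j = np.unravel_index(np.argmin(d), d.shape)
        landmarks[f"arch_attach_{tag}"] = front[i]

    return geom


def extract_all(
    instance: LabeledVolume,
    subregion: LabeledVolume,
    realign: bool = True,
) -> tuple[dict[str, VertebraGeometry], RigidTransform]:
    """Landmarks for every level present, after computing the realignment."""
    present = [lev for lev in LEVELS if np.any(instance.voxels == instance.label_map.get(lev, -1))]
    body_codes = (SUBREGION_LABELS["body_cortex"], SUBREGION_LABELS["body_trabecular"])
    body_sub = np.isin(subregion.voxels, body_codes)
    cents = {}
    for lev in present:
        m = instance.voxels == instance.label_map[lev]
        mb = m & body_sub
        # body centroids: free of the posterior-element bias of whole-instance
        # centroids, which matters for the axis hints below
        cents[lev] = instance.world_coords(mb if mb.any() else m).mean(axis=0)
    transform = realign_craniocaudal(cents) if realign else RigidTransform.identity()
    aligned = {lev: transform.apply(c) for lev, c in cents.items()}
    geoms = {}
    for lev in present:
        i = present.index(lev)
        cranial = aligned[present[max(i - 1, 0)]]
        caudal = aligned[present[min(i + 1, len(present) - 1)]]
        hint = cranial - caudal
        if np.linalg.norm(hint) < 1e-9:
            hint = WORLD_SUPERIOR
        geoms[lev] = extract_landmarks(instance, subregion, lev, transform, axis_hint=hint)
    return geoms, transform


# ---------------------------------------------------------------------- joint frames


def joint_center(inferior: VertebraGeometry, superior: VertebraGeometry) -> np.ndarray:
    """Midpoint of the facing endplate centres of an adjacent vertebra pair."""
    levels = list(LEVELS)
    ii, si = levels.index(inferior.level), levels.index(superior.level)
    if ii - si != 1:
        raise ValueError(
            f"{superior.level} and {inferior.level} are not adjacent (superior first in the spine)"
        )
    return 0.5 * (inferior.endplate_superior_center + superior.endplate_inferior_center)


def joint_orientation(
    centroids: list[np.ndarray],
    at_point: np.ndarray,
) -> np.ndarray:
    """Joint rotation from the centroid-spline tangent at ``at_point``.

    A natural cubic spline through the (cranial-to-caudal ordered) centroids,
    parameterized by cumulative chord length, supplies the superior axis as
    its tangent at the parameter closest to ``at_point`` (in use, the
    superior endplate centre of the inferior vertebra).  The anterior axis is
    the tangent's in-sagittal-plane normal and lateral completes the
    right-handed frame; columns are (anterior, superior, lateral).
    """
    pts = np.asarray(centroids, float)
    if len(pts) < 4:
        raise ValueError("need at least four centroids for a cubic spline")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg < 1e-9):
        raise ValueError("repeated centroids make the spline degenerate")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    spline = CubicSpline(s, pts, bc_type="natural")

    dense = np.linspace(s[0], s[-1], 512)
    d2 = np.linalg.norm(spline(dense) - at_point, axis=1)
    s0 = dense[np.argmin(d2)]
    res = minimize_scalar(
        lambda t: float(np.sum((spline(t) - at_point) ** 2)),
        bounds=(max(s[0], s0 - seg.mean()), min(s[-1], s0 + seg.mean())),
        method="bounded",
    )
    t0 = float(res.x)

    tangent = spline(t0, 1)
    sup = tangent / np.linalg.norm(tangent)
    if sup @ WORLD_SUPERIOR < 0:
        sup = -sup
    ant = WORLD_ANTERIOR - (WORLD_ANTERIOR @ sup) * sup
    na = np.linalg.norm(ant)
    if na < 1e-9:
        ant = np.cross(WORLD_LEFT, sup)
        na = np.linalg.norm(ant)
    ant = ant / na
    lat = np.cross(ant, sup)
    return np.column_stack([ant, sup, lat])


# ------------------------------------------------------------------------- alignment


def _sagittal_tilt_deg(geom: VertebraGeometry) -> float:
    a = geom.superior_axis
    return float(np.degrees(np.arctan2(a[0], a[1])))


def _frontal_tilt_deg(geom: VertebraGeometry) -> float:
    a = geom.superior_axis
    return float(np.degrees(np.arctan2(a[2], a[1])))


def measure_alignment(geometries: dict[str, VertebraGeometry]) -> AlignmentReport:
    """Spinal alignment from endplate orientations of the boundary vertebrae.

    Lumbar lordosis is the sagittal angle between L1 and the sacral
    endplate, thoracic kyphosis between T1 and T12, and the Cobb angle the
    frontal-plane angle across the thoracic spine.  Angles are reported as
    magnitudes in degrees.
    """
    for need in ("T1", "T12", "L1", "SACRUM"):
        if need not in geometries:
            raise ValueError(f"alignment needs vertebra {need}")
    lordosis = abs(_sagittal_tilt_deg(geometries["L1"]) - _sagittal_tilt_deg(geometries["SACRUM"]))
    kyphosis = abs(_sagittal_tilt_deg(geometries["T1"]) - _sagittal_tilt_deg(geometries["T12"]))
    cobb = abs(_frontal_tilt_deg(geometries["T1"]) - _frontal_tilt_deg(geometries["T12"]))
    return AlignmentReport(lordosis, kyphosis, cobb)
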