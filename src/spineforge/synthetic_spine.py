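"""Synthetic labeled spine volumes and analytic toy statics problems.

Real inputs to the modelling pipeline are multi-label vertebra instance
masks, per-vertebra subregion masks and a calibrated CT intensity volume.
This module fabricates all three from a parametric spine so every
downstream stage (landmark extraction, tissue classification, model
assembly, optimization) can be exercised with known ground truth.

Each vertebra is the union of an elliptic-cylinder body (split into a
cortical shell and trabecular core), a posterior arch with a canal
opening, a spinous process and two transverse processes — the simplest
shape family that exposes every subregion the landmark extractor needs.
Sagittal curvature (lumbar lordosis, thoracic kyphosis) and frontal
curvature (Cobb) are imposed by rotating and translating successive
vertebrae along circular arcs, so the requested angles are analytically
recoverable from the endplate orientations of the boundary vertebrae.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import LabeledVolume

__all__ = [
    "SpineParams",
    "LEVELS",
    "INSTANCE_LABELS",
    "SUBREGION_LABELS",
    "TISSUE_INTENSITY",
    "SizingError",
    "generate_spine_volume",
    "generate_tissue_volume",
    "ground_truth",
    "uniform_slab_volume",
    "make_toy_problem",
]

# Craniocaudal level order, cranial first.
LEVELS: tuple[str, ...] = tuple(f"T{i}" for i in range(1, 13)) + tuple(
    f"L{i}" for i in range(1, 6)
) + ("SACRUM",)

INSTANCE_LABELS: dict[str, int] = {name: i + 1 for i, name in enumerate(LEVELS)}

SUBREGION_LABELS: dict[str, int] = {
    "body_cortex": 1,
    "body_trabecular": 2,
    "arch": 3,
    "spinous_process": 4,
    "transverse_left": 5,
    "transverse_right": 6,
}

# Representative intensities (HU) placed well inside the classifier's
# default windows: lung [-1000,-500), fat [-200,-20), soft [-20,150).
#: air sits at the scanner floor, below the lung window's lower edge
TISSUE_INTENSITY = {"air": -1024.0, "lung": -750.0, "fat": -100.0, "soft": 40.0, "bone": 400.0}


class SizingError(ValueError):
    """Requested voxel grid cannot contain the generated spine."""


@dataclass
class SpineParams:
    """Geometric and material parameters of the synthetic spine.

    Curvature angles follow the clinical conventions: ``lumbar_lordosis_deg``
    is the sagittal angle between the L1 and sacral endplates,
    ``thoracic_kyphosis_deg`` between T1 and T12, ``cobb_deg`` the frontal
    arc over the thoracic spine.
    """

    n_thoracic: int = 12
    n_lumbar: int = 5
    vertebra_height: float = 24.0  # mm, craniocaudal body height
    vertebra_width: float = 44.0  # mm, lateral body width
    disc_height: float = 8.0  # mm
    lumbar_lordosis_deg: float = 0.0
    thoracic_kyphosis_deg: float = 0.0
    cobb_deg: float = 0.0
    torso_fat_fraction: float = 0.3
    voxel_size: float = 2.0  # mm isotropic
    seed: int = 0
    noise_sd: float = 0.0  # HU; optional intensity jitter, off by default
    grid_shape: tuple[int, int, int] | None = None  # autosized when None

    def __post_init__(self) -> None:
        if self.n_thoracic != 12 or self.n_lumbar != 5:
            raise ValueError("generator supports the full T1-L5 spine only")
        for name in ("vertebra_height", "vertebra_width", "disc_height", "voxel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("lumbar_lordosis_deg", "thoracic_kyphosis_deg", "cobb_deg"):
            if not -90.0 <= getattr(self, name) <= 90.0:
                raise ValueError(f"{name} must lie in [-90, 90] degrees")
        if not 0.0 <= self.torso_fat_fraction <= 1.0:
            raise ValueError("torso_fat_fraction must lie in [0, 1]")


# --------------------------------------------------------------------------- placement


def _rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, 0.0 + s, c]])


def _level_angles(params: SpineParams) -> dict[str, tuple[float, float]]:
    """Per-level (sagittal tilt, frontal tilt) in degrees.

    The sagittal tilt varies linearly from +lordosis/2 at the sacrum to
    -lordosis/2 at L1 (anterior lean positive, i.e. the superior axis tips
    toward +X for positive tilt), is constant over the L1/T12 transition,
    and then changes by +kyphosis from T12 up to T1.  The frontal tilt
    ramps by the Cobb angle across the thoracic levels.
    """
    ll, kk, cc = params.lumbar_lordosis_deg, params.thoracic_kyphosis_deg, params.cobb_deg
    angles: dict[str, tuple[float, float]] = {}
    lumbar_chain = ["SACRUM", "L5", "L4", "L3", "L2", "L1"]
    for i, lev in enumerate(lumbar_chain):
        angles[lev] = (ll / 2.0 - ll * i / (len(lumbar_chain) - 1), 0.0)
    base = angles["L1"][0]
    thor_chain = [f"T{i}" for i in range(12, 0, -1)]  # T12 .. T1
    for i, lev in enumerate(thor_chain):
        sag = base + kk * i / (len(thor_chain) - 1)
        fro = -cc / 2.0 + cc * i / (len(thor_chain) - 1)
        angles[lev] = (sag, fro)
    return angles


def _level_frames(params: SpineParams) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-level (centroid, rotation) with the sacrum centroid at the origin."""
    angles = _level_angles(params)
    rots = {lev: _rot_z(-sag) @ _rot_x(fro) for lev, (sag, fro) in angles.items()}
    # note: anterior lean (superior axis toward +X) is a negative rotation
    # about +Z in a right-handed x-anterior/y-superior/z-left frame.
    frames: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    order = ["SACRUM", "L5", "L4", "L3", "L2", "L1"] + [f"T{i}" for i in range(12, 0, -1)]
    pos = np.zeros(3)
    prev = None
    sac_h = 1.5 * params.vertebra_height
    for lev in order:
        if prev is not None:
            step_len = 0.5 * (sac_h if prev == "SACRUM" else params.vertebra_height) + \
                params.disc_height + 0.5 * params.vertebra_height
            d = 0.5 * (rots[prev] + rots[lev]) @ np.array([0.0, step_len, 0.0])
            pos = pos + d
        frames[lev] = (pos.copy(), rots[lev])
        prev = lev
    return frames


def ground_truth(params: SpineParams) -> dict:
    """Analytic placement used by the generator: centroids, tilts, frames.

    Exposed so tests and sidecar files can compare extracted geometry with
    the generator's own placement formula.
    """
    angles = _level_angles(params)
    frames = _level_frames(params)
    return {
        "levels": list(LEVELS),
        "centroids": {lev: frames[lev][0].tolist() for lev in LEVELS},
        "sagittal_tilt_deg": {lev: angles[lev][0] for lev in LEVELS},
        "frontal_tilt_deg": {lev: angles[lev][1] for lev in LEVELS},
    }


# ------------------------------------------------------------------------ rasterizing


def _vertebra_masks(local: np.ndarray, params: SpineParams, sacrum: bool) -> dict[str, np.ndarray]:
    """Subregion membership tests in a vertebra's local frame.

    ``local`` is (N, 3) local coordinates (x anterior, y superior, z left).
    """
    w = params.vertebra_width
    b = w / 2.0  # lateral semi-axis
    a = 0.75 * b  # anterior-posterior semi-axis
    h = (1.5 if sacrum else 1.0) * params.vertebra_height
    shell = 3.0  # mm cortical shell
    arch_d = 12.0
    sp_len = 20.0
    tp_len = 14.0

    x, y, z = local[:, 0], local[:, 1], local[:, 2]
    in_h = np.abs(y) <= h / 2.0
    r2 = (x / a) ** 2 + (z / b) ** 2
    body = (r2 <= 1.0) & in_h
    inner = ((x / max(a - shell, 1.0)) ** 2 + (z / max(b - shell, 1.0)) ** 2 <= 1.0) & (
        np.abs(y) <= h / 2.0 - shell
    )
    out: dict[str, np.ndarray] = {
        "body_trabecular": body & inner,
        "body_cortex": body & ~inner,
    }
    if sacrum:
        # the sacrum is a plain body block (ground side); no posterior elements
        out["arch"] = np.zeros_like(body)
        out["spinous_process"] = np.zeros_like(body)
        out["transverse_left"] = np.zeros_like(body)
        out["transverse_right"] = np.zeros_like(body)
        return out

    arch_x = (x <= -a * 0.85) & (x >= -a - arch_d)
    # canal hole sits forward in the arch so a posterior lamina band survives
    # on the midline (where the flaval attachment is probed)
    canal = (x + a + 4.0) ** 2 + z**2 <= 5.0**2
    out["arch"] = arch_x & (np.abs(z) <= 0.55 * b) & (np.abs(y) <= 0.35 * h) & ~canal & ~body
    out["spinous_process"] = (
        (x <= -a - arch_d)
        & (x >= -a - arch_d - sp_len)
        & (np.abs(z) <= 5.0)
        & (np.abs(y) <= 0.35 * h)
    )
    tp_x = (x <= -a * 0.85) & (x >= -a - arch_d)
    tp_y = np.abs(y) <= 5.0
    out["transverse_left"] = tp_x & tp_y & (z >= 0.55 * b) & (z <= 0.55 * b + tp_len)
    out["transverse_right"] = tp_x & tp_y & (z <= -0.55 * b) & (z >= -0.55 * b - tp_len)
    return out


def _grid(params: SpineParams) -> tuple[tuple[int, int, int], np.ndarray]:
    """Voxel grid shape and affine covering spine plus torso compartments."""
    frames = _level_frames(params)
    cents = np.array([frames[lev][0] for lev in LEVELS])
    # torso extents relative to the spine: anterior chest wall, lateral ribs
    lo = cents.min(axis=0) + np.array([-90.0, -params.vertebra_height * 1.2, -150.0])
    hi = cents.max(axis=0) + np.array([180.0, params.vertebra_height * 1.2, 150.0])
    vs = params.voxel_size
    shape_needed = tuple(int(np.ceil((hi[i] - lo[i]) / vs)) + 1 for i in range(3))
    if params.grid_shape is not None:
        if any(params.grid_shape[i] < shape_needed[i] for i in range(3)):
            raise SizingError(
                f"grid {params.grid_shape} too small; spine needs at least {shape_needed}"
            )
        shape = tuple(int(s) for s in params.grid_shape)
    else:
        shape = shape_needed
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = lo
    return shape, affine  # type: ignore[return-value]


def generate_spine_volume(params: SpineParams) -> tuple[LabeledVolume, LabeledVolume]:
    """Rasterize the parametric spine into instance and subregion label volumes.

    Returns ``(instance_labels, subregion_labels)`` on a shared grid.  The
    instance volume codes T1..L5 and the sacrum (1..18); the subregion
    volume codes cortex/trabecular body, arch, spinous and transverse
    processes.  Deterministic for fixed parameters.
    """
    frames = _level_frames(params)
    shape, affine = _grid(params)
    inst = np.zeros(shape, dtype=np.int16)
    sub = np.zeros(shape, dtype=np.int16)
    inv = np.linalg.inv(affine)

    for lev in LEVELS:
        c, rot = frames[lev]
        sacrum = lev == "SACRUM"
        reach = params.vertebra_width / 2.0 + 50.0
        lo_i = np.floor((inv[:3, :3] @ (c - reach) + inv[:3, 3])).astype(int)
        hi_i = np.ceil((inv[:3, :3] @ (c + reach) + inv[:3, 3])).astype(int)
        lo_i = np.clip(lo_i, 0, np.array(shape) - 1)
        hi_i = np.clip(hi_i, 0, np.array(shape) - 1)
        ii, jj, kk = np.meshgrid(
            *[np.arange(lo_i[d], hi_i[d] + 1) for d in range(3)], indexing="ij"
        )
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        world = idx @ affine[:3, :3].T + affine[:3, 3]
        local = (world - c) @ rot  # rot columns are local axes => p_local = R^T p
        masks = _vertebra_masks(local, params, sacrum)
        lab = INSTANCE_LABELS[lev]
        for name, m in masks.items():
            if not m.any():
                continue
            sel = idx[m]
            free = inst[sel[:, 0], sel[:, 1], sel[:, 2]] == 0
            sel = sel[free]
            inst[sel[:, 0], sel[:, 1], sel[:, 2]] = lab
            sub[sel[:, 0], sel[:, 1], sel[:, 2]] = SUBREGION_LABELS[name]
    instance = LabeledVolume(inst, affine, dict(INSTANCE_LABELS))
    subregion = LabeledVolume(sub, affine, dict(SUBREGION_LABELS))
    return instance, subregion


def generate_tissue_volume(params: SpineParams, instance_labels: LabeledVolume) -> LabeledVolume:
    """Pseudo-CT intensity volume with lung, fat and soft-tissue compartments.

    The torso is an elliptic cylinder around the spine; an outer shell whose
    cross-sectional area fraction equals ``torso_fat_fraction`` carries fat
    intensities, two ellipsoids in the thoracic range carry lung
    intensities, the remainder is soft tissue.  Bone voxels (from the
    instance mask) get a bone intensity outside every tissue window.
    """
    shape = instance_labels.voxels.shape
    affine = instance_labels.affine
    frames = _level_frames(params)
    cents = np.array([frames[lev][0] for lev in LEVELS])

    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij", sparse=True)
    x = affine[0, 0] * ii + affine[0, 3]
    y = affine[1, 1] * jj + affine[1, 3]
    z = affine[2, 2] * kk + affine[2, 3]

    cx = float(cents[:, 0].mean()) + 50.0  # torso centre sits anterior of the spine
    cz = float(cents[:, 2].mean())
    ax_, az_ = 120.0, 140.0
    rn2 = ((x - cx) / ax_) ** 2 + ((z - cz) / az_) ** 2
    ylo = cents[:, 1].min() - params.vertebra_height
    yhi = cents[:, 1].max() + params.vertebra_height
    torso = (rn2 <= 1.0) & (y >= ylo) & (y <= yhi)

    vol = np.full(shape, TISSUE_INTENSITY["air"], dtype=np.float32)
    vol[torso] = TISSUE_INTENSITY["soft"]

    if params.torso_fat_fraction > 0:
        s0 = np.sqrt(1.0 - params.torso_fat_fraction)
        vol[torso & (rn2 > s0**2)] = TISSUE_INTENSITY["fat"]

    # lungs: two ellipsoids spanning the mid-thoracic levels
    t_cents = cents[:12]
    lung_cy = float(t_cents[2:10, 1].mean())
    lung_cx = float(t_cents[:, 0].mean()) + 45.0
    half_span = float(t_cents[2, 1] - t_cents[9, 1]) / 2.0
    for side in (+1.0, -1.0):
        lung = ((x - lung_cx) / 45.0) ** 2 + ((y - lung_cy) / max(half_span, 30.0)) ** 2 + (
            (z - (cz + side * 60.0)) / 45.0
        ) ** 2 <= 1.0
        lung &= torso
        vol[lung] = TISSUE_INTENSITY["lung"]

    bone = instance_labels.voxels > 0
    if np.any(bone & ~torso & (np.asarray(vol) == TISSUE_INTENSITY["air"])):
        # spine must sit inside the torso; anything else is a sizing bug
        raise ValueError("bone voxels fall outside the torso compartment")
    vol[bone] = TISSUE_INTENSITY["bone"]

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        vol = vol + rng.normal(0.0, params.noise_sd, size=shape).astype(np.float32)
        vol[bone] = TISSUE_INTENSITY["bone"]

    return LabeledVolume(vol, affine.copy(), {})


def uniform_slab_volume(
    tissue: str, volume_cm3: float, voxel_size: float = 2.0
) -> LabeledVolume:
    """A homogeneous box of one tissue with an exact analytic volume.

    Useful for density bookkeeping checks: a 1000 cm^3 fat slab must weigh
    0.96 kg downstream at the default fat density of 0.96 g/cm^3.
    """
    n_vox_f = volume_cm3 * 1000.0 / voxel_size**3
    n_vox = int(round(n_vox_f))
    if abs(n_vox - n_vox_f) > 1e-9:
        raise ValueError("volume_cm3 not representable exactly at this voxel size")
    # near-cubic factorization n_vox = nx * ny * nz with exact product
    nx = max(int(round(n_vox ** (1.0 / 3.0))), 1)
    while n_vox % nx:
        nx -= 1
    rest = n_vox // nx
    ny = max(int(round(rest**0.5)), 1)
    while rest % ny:
        ny -= 1
    nz = rest // ny
    vox = np.full((nx + 2, ny + 2, nz + 2), TISSUE_INTENSITY["air"], dtype=np.float32)
    vox[1 : nx + 1, 1 : ny + 1, 1 : nz + 1] = TISSUE_INTENSITY[tissue]
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return LabeledVolume(vox, affine, {})


# ------------------------------------------------------------------------ toy problems


@dataclass
class ToySolution:
    forces: np.ndarray
    note: str = ""


def make_toy_problem(name: str):
    """Tiny single-joint statics problems with closed-form optima attached.

    The attached solutions come from the Karush-Kuhn-Tucker conditions of the
    cubic muscle-stress cost: with a single sagittal moment constraint
    ``sum(r_i F_i) = M`` and cost ``sum((F_i/PCSA_i)^3)``, active muscles share
    load as ``F_j/F_i = (PCSA_j/PCSA_i)^{3/2}`` and antagonists stay silent.
    """
    from .muscle_opt import OptimizationProblem

    if name == "single_muscle":
        arms = np.array([[0.05]])  # m, sagittal
        pcsa = np.array([10.0])
        target = np.array([10.0])
        expected = np.array([200.0])
    elif name == "antagonist_pair":
        arms = np.array([[0.05, -0.05]])
        pcsa = np.array([10.0, 10.0])
        target = np.array([10.0])
        expected = np.array([200.0, 0.0])
    elif name == "two_agonists":
        arms = np.array([[0.05, 0.05]])
        pcsa = np.array([10.0, 20.0])
        target = np.array([10.0])
        ratio = (pcsa[1] / pcsa[0]) ** 1.5
        f1 = target[0] / arms[0, 0] / (1.0 + ratio)
        expected = np.array([f1, ratio * f1])
    else:
        raise ValueError(f"unknown toy problem {name!r}")

    problem = OptimizationProblem(
        moment_arms=arms,
        pcsa=pcsa,
        target_moments=target,
        sigma_max_mpa=1.0,
        labels=[f"m{i}" for i in range(len(pcsa))],
        constraint_names=["toy:Mz"],
    )
    problem.expected = ToySolution(forces=expected)  # type: ignore[attr-defined]
    return problem
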