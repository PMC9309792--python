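"""Torso tissue classification and per-level mass partitioning.

Intensity volumes are classified into lung, fat and soft tissue by
configurable HU windows, the classified voxels are assigned to the nearest
vertebral level, and each level's segment gets a mass (tissue volume times
density) and a centre of mass.  Bone mass comes from the instance mask at a
fixed bone density.  Generic bodies (head-neck, simplified arms) are scaled
from anthropometric mass fractions shipped as a documented config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import VertebraGeometry
from .volume import LabeledVolume

__all__ = [
    "DensityTable",
    "TissueSegment",
    "DEFAULT_INTENSITY_RANGES",
    "TISSUE_CODES",
    "classify_tissues",
    "assign_to_levels",
    "bone_mass",
    "scale_generic_segments",
]

#: Half-open HU windows [lo, hi) per tissue class.  The classifier only
#: requires them to be pairwise disjoint; these defaults bracket typical
#: CT values for aerated lung, adipose and lean soft tissue.
DEFAULT_INTENSITY_RANGES: dict[str, tuple[float, float]] = {
    "lung": (-1000.0, -500.0),
    "fat": (-200.0, -20.0),
    "soft": (-20.0, 150.0),
}

TISSUE_CODES: dict[str, int] = {"lung": 1, "fat": 2, "soft": 3}


@dataclass
class DensityTable:
    """Average tissue densities, g/cm^3."""

    lung: float = 0.25
    fat: float = 0.96
    soft: float = 1.06
    bone: float = 1.5

    def __post_init__(self) -> None:
        for name in ("lung", "fat", "soft", "bone"):
            if getattr(self, name) <= 0:
                raise ValueError(f"density {name} must be positive")

    def get(self, tissue: str) -> float:
        return float(getattr(self, tissue))


@dataclass
class TissueSegment:
    """Soft-tissue mass attached to one vertebral level."""

    level: str
    mass_kg: float
    com_mm: np.ndarray
    composition_cm3: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "mass_kg": self.mass_kg,
            "com_mm": self.com_mm.tolist(),
            "composition_cm3": self.composition_cm3,
        }


def classify_tissues(
    intensities: LabeledVolume,
    ranges: dict[str, tuple[float, float]] | None = None,
    bone_mask: np.ndarray | None = None,
) -> LabeledVolume:
    """Label every voxel whose intensity falls in a tissue window.

    Voxels covered by ``bone_mask`` (typically the vertebra instance mask)
    are excluded regardless of intensity; voxels in no window stay 0.
    Overlapping windows are a configuration error.
    """
    ranges = dict(DEFAULT_INTENSITY_RANGES if ranges is None else ranges)
    items = sorted(ranges.items(), key=lambda kv: kv[1][0])
    for (na, (_, hi_a)), (nb, (lo_b, _)) in zip(items, items[1:]):
        if hi_a > lo_b:
            raise ValueError(f"intensity ranges for {na!r} and {nb!r} overlap")
    vox = np.asarray(intensities.voxels, dtype=float)
    labels = np.zeros(vox.shape, dtype=np.int8)
    for name, (lo, hi) in ranges.items():
        if name not in TISSUE_CODES:
            raise ValueError(f"unknown tissue class {name!r}")
        labels[(vox >= lo) & (vox < hi)] = TISSUE_CODES[name]
    if bone_mask is not None:
        labels[np.asarray(bone_mask, bool)] = 0
    return LabeledVolume(labels, intensities.affine.copy(), dict(TISSUE_CODES))


def assign_to_levels(
    tissue_labels: LabeledVolume,
    geometries: dict[str, VertebraGeometry],
    densities: DensityTable | None = None,
    levels: list[str] | None = None,
    transform=None,
) -> list[TissueSegment]:
    """Partition classified tissue into per-vertebral-level segments.

    Every labeled voxel goes to exactly one level — the vertebra whose
    centroid is nearest along the craniocaudal axis, which slices the torso
    into contiguous axial slabs.  Per level, tissue volumes are converted
    to mass with the density table and a mass-weighted centre of mass is
    accumulated.  ``transform`` (the craniocaudal realignment) maps voxel
    coordinates into the frame the geometries live in.
    """
    if densities is None:
        densities = DensityTable()
    if levels is None:
        levels = sorted(geometries, key=lambda lv: -geometries[lv].centroid[1])
    if not levels:
        raise ValueError("no vertebrae to assign tissue to")
    cent_y = np.array([geometries[lv].centroid[1] for lv in levels])
    order = np.argsort(cent_y)
    sorted_levels = [levels[i] for i in order]
    edges = 0.5 * (cent_y[order][1:] + cent_y[order][:-1])

    vox = tissue_labels.voxels
    vv_cm3 = tissue_labels.voxel_volume_mm3 / 1000.0
    segs: list[TissueSegment] = []
    by_level: dict[str, dict[str, float]] = {lv: {} for lv in sorted_levels}
    com_acc: dict[str, np.ndarray] = {lv: np.zeros(3) for lv in sorted_levels}
    mass_acc: dict[str, float] = {lv: 0.0 for lv in sorted_levels}

    for tissue, code in TISSUE_CODES.items():
        mask = vox == code
        if not mask.any():
            continue
        pts = tissue_labels.world_coords(mask)
        if transform is not None:
            pts = transform.apply(pts)
        rho = densities.get(tissue)
        bins = np.digitize(pts[:, 1], edges)
        for b in np.unique(bins):
            lv = sorted_levels[b]
            sel = pts[bins == b]
            v_cm3 = len(sel) * vv_cm3
            m_kg = v_cm3 * rho / 1000.0
            by_level[lv][tissue] = by_level[lv].get(tissue, 0.0) + v_cm3
            com_acc[lv] += m_kg * sel.mean(axis=0)
            mass_acc[lv] += m_kg

    for lv in sorted_levels:
        if mass_acc[lv] <= 0:
            continue
        segs.append(
            TissueSegment(
                level=lv,
                mass_kg=mass_acc[lv],
                com_mm=com_acc[lv] / mass_acc[lv],
                composition_cm3=by_level[lv],
            )
        )
    segs.sort(key=lambda s: -s.com_mm[1])
    return segs


def bone_mass(
    instance_mask: LabeledVolume, level: str, density_g_cm3: float = 1.5
) -> float:
    """Bony mass of one vertebra in kg: voxel volume times bone density."""
    lab = instance_mask.label_id(level)
    n = instance_mask.count(lab)
    v_cm3 = n * instance_mask.voxel_volume_mm3 / 1000.0
    return v_cm3 * density_g_cm3 / 1000.0


def scale_generic_segments(
    stature_m: float,
    torso_mass_kg: float,
    table: dict,
) -> dict:
    """Masses and geometric scale for the generic bodies.

    ``table`` holds anthropometric mass fractions (see
    ``data/anthropometry.json``): each segment entry gives a fraction and
    its reference ("body" or "torso"); whole-body mass is inferred from the
    torso mass through the table's ``torso_fraction``.  Returns segment
    masses in kg plus the stature-proportional geometric ``scale``.
    """
    if stature_m <= 0 or torso_mass_kg <= 0:
        raise ValueError("stature and torso mass must be positive")
    torso_fraction = float(table.get("torso_fraction", 0.497))
    if not 0 < torso_fraction < 1:
        raise ValueError("torso_fraction must lie in (0, 1)")
    body_mass = torso_mass_kg / torso_fraction
    out: dict[str, float] = {}
    frac_sum = 0.0
    for name, entry in table.get("segments", {}).items():
        frac = float(entry["fraction"])
        if not 0 < frac < 1:
            raise ValueError(f"fraction for {name} must lie in (0, 1)")
        ref = entry.get("reference", "body")
        base = body_mass if ref == "body" else torso_mass_kg
        n = int(entry.get("count", 1))
        frac_sum += frac * n * (1.0 if ref == "body" else torso_fraction)
        for i in range(n):
            key = name if n == 1 else f"{name}_{('left', 'right')[i] if n == 2 else i}"
            out[key] = frac * base
    if frac_sum * body_mass + torso_mass_kg > body_mass * (1 + 1e-9):
        raise ValueError("segment fractions plus torso exceed whole-body mass")
    out["scale"] = stature_m / float(table.get("reference_stature_m", 1.75))
    out["body_mass_kg"] = body_mass
    return out
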