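"""Voxel volumes with world-space affines.

All volumes in this package live on a regular voxel grid with a 4x4
voxel-to-world affine in millimetres.  The model frame is right-handed with
+X anterior, +Y superior (craniocaudal) and +Z subject-left; gravity acts
along -Y.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["LabeledVolume"]


@dataclass
class LabeledVolume:
    """A 3-D voxel grid plus its voxel-to-world affine.

    ``voxels`` holds either integer labels (instance or subregion masks) or
    scalar intensities (pseudo-CT).  For label volumes, ``label_map`` maps
    human-readable names to the integer codes present in the grid.
    """

    voxels: np.ndarray
    affine: np.ndarray
    label_map: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    # ------------------------------------------------------------------ geometry
    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_coords(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World-space (mm) coordinates of voxel centres.

        With ``mask`` given, returns an (N, 3) array for the masked voxels
        (0-based voxel indices mapped through the affine); otherwise for every
        voxel, which is rarely what you want on a full grid.
        """
        if mask is None:
            mask = np.ones(self.voxels.shape, dtype=bool)
        idx = np.argwhere(mask)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.voxels == label))

    def label_id(self, name: str) -> int:
        try:
            return self.label_map[name]
        except KeyError:
            raise KeyError(f"label {name!r} not in label_map") from None

    # ---------------------------------------------------------------------- I/O
    def save(self, path: str | Path) -> None:
        """Write a NIfTI volume plus a JSON sidecar with the label map."""
        path = Path(path)
        data = self.voxels
        if data.dtype == bool:
            data = data.astype(np.uint8)
        nib.save(nib.Nifti1Image(data, self.affine), str(path))
        if self.label_map:
            sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz
            sidecar = Path(str(sidecar) + ".json")
            sidecar.write_text(json.dumps({"label_map": self.label_map}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "LabeledVolume":
        path = Path(path)
        img = nib.load(str(path))
        label_map: dict[str, int] = {}
        sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json")
        if sidecar.exists():
            label_map = {k: int(v) for k, v in json.loads(sidecar.read_text())["label_map"].items()}
        data = np.asarray(img.dataobj)
        return cls(voxels=data, affine=np.asarray(img.affine), label_map=label_map)
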