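"""Minimal 3-D image containers used throughout the package.

Arrays are indexed ``[i, j, k]``; the affine maps voxel indices to world
coordinates in millimetres, following the NIfTI convention.  Only what the
pipeline needs is wrapped here -- everything else goes straight through
``nibabel`` / ``numpy``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "MaskVolume"]


@dataclass
class ImageVolume:
    """A 3-D intensity grid with voxel spacing and a grid-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm along each grid axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world coordinates in mm."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map world mm coordinates (..., 3) to (fractional) voxel indices."""
        pts = np.asarray(pts, dtype=float)
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj), img.affine)

    @classmethod
    def from_spacing(cls, data: np.ndarray, spacing) -> "ImageVolume":
        """Build a volume with a diagonal affine from a spacing triple (mm)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = spacing
        return cls(data, aff)


@dataclass
class MaskVolume(ImageVolume):
    """A binary (or probabilistic, in [0, 1]) mask with an optional side label."""

    side: str = "bilateral"  # left | right | bilateral

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.side not in ("left", "right", "bilateral"):
            raise ValueError(f"unknown side label {self.side!r}")

    def binarized(self, threshold: float = 0.5) -> np.ndarray:
        return np.asarray(self.data) >= threshold

    @property
    def n_voxels(self) -> int:
        return int(self.binarized().sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume
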