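"""Spatial transforms between template and native space.

Registration itself (bias correction, brain extraction, diffeomorphic
matching) is out of scope: transforms arrive precomputed, either as a 4x4
affine, as a dense displacement field sampled on the template grid, or both
composed.  The mapping is

    phi(p) = A @ (p + u(p)),    p in template world coordinates (mm),

where ``u`` is the (tri)linearly interpolated displacement.  The inverse is
evaluated by fixed-point iteration, which converges whenever ``u`` is a
contraction; constructors enforce an amplitude bound that guarantees this,
so every field the package builds is invertible on its grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["DeformationField"]


@dataclass
class DeformationField:
    """A template-to-native spatial map: affine plus optional dense displacement.

    Parameters
    ----------
    affine : (4, 4) array
        Affine applied after the displacement, world mm -> world mm.
    disp : (nx, ny, nz, 3) array, optional
        Displacement in mm sampled at template grid points.
    grid_affine : (4, 4) array, optional
        Grid-to-world affine of the displacement grid (required with ``disp``).
    """

    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    disp: np.ndarray | None = None
    grid_affine: np.ndarray | None = None
    direction: str = "template_to_native"

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular; transform not invertible")
        if self.disp is not None:
            self.disp = np.asarray(self.disp, dtype=float)
            if self.disp.ndim != 4 or self.disp.shape[-1] != 3:
                raise ValueError("disp must have shape (nx, ny, nz, 3)")
            if self.grid_affine is None:
                raise ValueError("grid_affine is required with a dense displacement")
            self.grid_affine = np.asarray(self.grid_affine, dtype=float)

    # ------------------------------------------------------------------ factories
    @classmethod
    def identity(cls) -> "DeformationField":
        return cls()

    @classmethod
    def from_affine(cls, affine: np.ndarray) -> "DeformationField":
        return cls(affine=np.asarray(affine, dtype=float))

    @classmethod
    def translation(cls, shift_mm) -> "DeformationField":
        aff = np.eye(4)
        aff[:3, 3] = shift_mm
        return cls(affine=aff)

    @classmethod
    def scaling(cls, scale, center_mm=(0.0, 0.0, 0.0)) -> "DeformationField":
        """Isotropic or per-axis scaling about a world-space centre."""
        s = np.broadcast_to(np.asarray(scale, dtype=float), (3,))
        c = np.asarray(center_mm, dtype=float)
        aff = np.eye(4)
        aff[:3, :3] = np.diag(s)
        aff[:3, 3] = c - s * c
        return cls(affine=aff)

    @classmethod
    def sinusoidal(
        cls,
        grid_shape,
        grid_affine: np.ndarray,
        amplitude_mm: float,
        period_mm: float = 20.0,
        phase=(0.0, 0.0, 0.0),
        affine: np.ndarray | None = None,
    ) -> "DeformationField":
        """Smooth sinusoidal displacement on the template grid, optionally
        composed with an affine.

        The amplitude is bounded (``2*pi*a/lambda < 1``) so the map is a
        contraction perturbation of the affine, hence injective and
        fixed-point invertible.
        """
        a, lam = float(amplitude_mm), float(period_mm)
        if lam <= 0:
            raise ValueError("period_mm must be positive")
        if a < 0 or 2.0 * np.pi * a / lam >= 1.0:
            raise ValueError(
                f"displacement amplitude {a} mm is not invertible at period "
                f"{lam} mm (requires amplitude < period / (2*pi) = {lam / (2 * np.pi):.3f} mm)"
            )
        grid_affine = np.asarray(grid_affine, dtype=float)
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij"), axis=-1
        ).astype(float)
        world = idx @ grid_affine[:3, :3].T + grid_affine[:3, 3]
        ph = np.asarray(phase, dtype=float)
        disp = np.empty(tuple(grid_shape) + (3,))
        # each component driven by the next spatial axis: divergence-poor, smooth
        for c in range(3):
            disp[..., c] = a * np.sin(2.0 * np.pi * world[..., (c + 1) % 3] / lam + ph[c])
        return cls(
            affine=np.eye(4) if affine is None else affine,
            disp=disp,
            grid_affine=grid_affine,
        )

    # ------------------------------------------------------------------ evaluation
    @property
    def max_displacement_mm(self) -> float:
        if self.disp is None:
            return 0.0
        return float(np.linalg.norm(self.disp, axis=-1).max())

    @property
    def has_inverse(self) -> bool:
        """True when the fixed-point inverse is available (always, by construction)."""
        return True

    def inverted(self) -> "_InvertedField":
        """A view of this field with the mapping direction swapped
        (``apply`` becomes the fixed-point inverse and vice versa)."""
        return _InvertedField(self)

    def _u(self, pts: np.ndarray) -> np.ndarray:
        """Interpolate the displacement at template world points (N, 3)."""
        if self.disp is None:
            return np.zeros_like(pts)
        inv = np.linalg.inv(self.grid_affine)
        idx = pts @ inv[:3, :3].T + inv[:3, 3]
        out = np.empty_like(pts)
        coords = idx.T
        for c in range(3):
            out[:, c] = map_coordinates(
                self.disp[..., c], coords, order=1, mode="nearest"
            )
        return out

    def apply(self, pts: np.ndarray) -> np.ndarray:
        """Map template world points (N, 3) to native world points."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        moved = pts + self._u(pts)
        return moved @ self.affine[:3, :3].T + self.affine[:3, 3]

    def apply_inverse(
        self, pts: np.ndarray, tol: float = 1e-6, max_iter: int = 100
    ) -> np.ndarray:
        """Map native world points back to template space (fixed-point iteration)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        ainv = np.linalg.inv(self.affine)
        base = pts @ ainv[:3, :3].T + ainv[:3, 3]
        if self.disp is None:
            return base
        p = base.copy()
        for _ in range(max_iter):
            p_new = base - self._u(p)
            err = np.abs(p_new - p).max()
            p = p_new
            if err < tol:
                break
        return p

    # ------------------------------------------------------------------ i/o
    def save(self, path: str | Path) -> None:
        """Write the affine as a 4x4 text matrix; the displacement (if any)
        as a vector-valued NIfTI next to it (.disp.nii.gz)."""
        path = Path(path)
        np.savetxt(path, self.affine, fmt="%.17g")
        if self.disp is not None:
            import nibabel as nib

            nib.save(
                nib.Nifti1Image(np.asarray(self.disp, dtype=np.float32), self.grid_affine),
                str(path.with_suffix(".disp.nii.gz")),
            )

    @classmethod
    def load(cls, path: str | Path) -> "DeformationField":
        path = Path(path)
        affine = np.loadtxt(path)
        disp_path = path.with_suffix(".disp.nii.gz")
        if disp_path.exists():
            import nibabel as nib

            img = nib.load(str(disp_path))
            return cls(affine=affine, disp=np.asanyarray(img.dataobj), grid_affine=img.affine)
        return cls(affine=affine)


class _InvertedField:
    """Direction-swapped view of a :class:`DeformationField`."""

    def __init__(self, base: DeformationField) -> None:
        self._base = base
        self.direction = (
            "native_to_template"
            if base.direction == "template_to_native"
            else "template_to_native"
        )

    @property
    def max_displacement_mm(self) -> float:
        return self._base.max_displacement_mm

    @property
    def has_inverse(self) -> bool:
        return True

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return self._base.apply_inverse(pts)

    def apply_inverse(self, pts: np.ndarray, **kw) -> np.ndarray:
        return self._base.apply(pts)

    def inverted(self) -> DeformationField:
        return self._base
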