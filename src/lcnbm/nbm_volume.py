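"""Nucleus basalis of Meynert (NBM) volumetry.

A template-space binary NBM mask (JuBrain-style Ch4 atlas region, or the
bundled synthetic stand-in) is brought to each subject's native 3D-T1 grid
through the subject's inverse spatial normalisation, the per-side volume is
read off as voxel count times voxel volume, and the side average is
normalised to intracranial volume (per-mil convention; raw mm^3 is always
reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .image import MaskVolume
from .transforms import DeformationField

__all__ = ["NBMResult", "warp_mask", "compute_nbm_volume", "split_bilateral_mask"]


@dataclass
class NBMResult:
    vol_left_mm3: float
    vol_right_mm3: float
    vol_mean_mm3: float
    icv_mm3: float
    vol_norm: float  # vol_mean / ICV * 1000 (per-mil)


def warp_mask(
    template_mask: MaskVolume,
    inverse_transform: DeformationField,
    target_shape,
    target_affine: np.ndarray,
    interpolation: str = "trilinear",
    threshold: float = 0.5,
) -> MaskVolume:
    """Warp a template mask onto a native grid through a template-to-native map.

    For each native voxel the template pre-image is evaluated and the mask is
    interpolated there: trilinear then thresholded at 0.5 (default), or
    nearest-neighbour.  An empty warped mask is an error.
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError("interpolation must be 'trilinear' or 'nearest'")
    target_shape = tuple(int(n) for n in target_shape)
    target_affine = np.asarray(target_affine, dtype=float)
    src = np.asarray(template_mask.binarized(), dtype=float)

    # bound the evaluation region by the forward image of the mask
    idx = np.argwhere(src > 0).astype(float)
    if len(idx) == 0:
        raise ValueError("template mask is empty")
    aff = np.asarray(template_mask.affine, dtype=float)
    world = idx @ aff[:3, :3].T + aff[:3, 3]
    tgt_inv = np.linalg.inv(target_affine)
    fwd = inverse_transform.apply(world) @ tgt_inv[:3, :3].T + tgt_inv[:3, 3]
    pad = 2 + int(np.ceil(inverse_transform.max_displacement_mm))
    lo = np.maximum(np.floor(fwd.min(axis=0)).astype(int) - pad, 0)
    hi = np.minimum(np.ceil(fwd.max(axis=0)).astype(int) + pad, np.array(target_shape) - 1)
    if (hi < lo).any():
        raise ValueError("warped mask is empty: mask maps outside the target grid")

    ranges = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
    sub = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    q = sub.astype(float) @ target_affine[:3, :3].T + target_affine[:3, 3]
    pre = inverse_transform.apply_inverse(q)
    tpl_inv = np.linalg.inv(aff)
    coords = (pre @ tpl_inv[:3, :3].T + tpl_inv[:3, 3]).T

    order = 1 if interpolation == "trilinear" else 0
    vals = map_coordinates(src, coords, order=order, mode="constant", cval=0.0)
    out = np.zeros(target_shape, dtype=bool)
    keep = vals >= threshold if interpolation == "trilinear" else vals > 0.5
    out[sub[keep, 0], sub[keep, 1], sub[keep, 2]] = True
    if not out.any():
        raise ValueError("warped mask is empty on the target grid")
    return MaskVolume(out, target_affine, side=template_mask.side)


def split_bilateral_mask(mask: MaskVolume) -> tuple[MaskVolume, MaskVolume]:
    """Split a bilateral mask into left/right halves at the mid-sagittal plane
    of its grid (first axis)."""
    data = mask.binarized()
    mid = data.shape[0] / 2.0
    xs = np.arange(data.shape[0])
    left = data & (xs[:, None, None] < mid)
    right = data & (xs[:, None, None] >= mid)
    return (
        MaskVolume(left, mask.affine, side="left"),
        MaskVolume(right, mask.affine, side="right"),
    )


def compute_nbm_volume(
    mask_left: MaskVolume, mask_right: MaskVolume, icv_mm3: float
) -> NBMResult:
    """Per-side native volumes, side average, and ICV-normalised volume."""
    if icv_mm3 <= 0:
        raise ValueError("icv_mm3 must be positive")
    for mask, side in ((mask_left, "left"), (mask_right, "right")):
        if mask.n_voxels == 0:
            raise ValueError(f"{side} NBM mask is empty")
    vl = mask_left.volume_mm3
    vr = mask_right.volume_mm3
    vmean = 0.5 * (vl + vr)
    return NBMResult(
        vol_left_mm3=vl,
        vol_right_mm3=vr,
        vol_mean_mm3=vmean,
        icv_mm3=float(icv_mm3),
        vol_norm=vmean / icv_mm3 * 1000.0,
    )
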