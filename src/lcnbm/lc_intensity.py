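"""Locus coeruleus signal intensity (LC-I) from a turbo-spin-echo slab.

The measurement follows the template-bounding-box design used in
neuromelanin-sensitive MRI: three boxes are defined once in template space —
a large rostral pontomesencephalic reference region (6200 mm^3) and one box
per LC (700 mm^3 each) — resampled onto each subject's native TSE grid, and
the LC signal is taken as the mean over the k = 10 brightest *connected*
voxels per side, normalised by the reference-region mean.

"Brightest connected" is formalised as deterministic greedy growth: seed at
the box maximum, then repeatedly add the brightest box voxel adjacent to the
current set.  The exact maximum-sum connected k-subset problem is NP-hard;
an exact enumerator is provided for small k as a slow cross-check.  All ties
break on the smallest linearised voxel index (x fastest, then y, then z) so
results are reproducible bit-for-bit.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .image import ImageVolume
from .transforms import DeformationField

__all__ = [
    "BoxGeometry",
    "BoxSet",
    "LCResult",
    "build_template_boxes",
    "resample_boxes",
    "select_brightest_connected",
    "exact_brightest_connected",
    "compute_lc_intensity",
]

BOX_NAMES = ("reference", "lc_left", "lc_right")

#: Target box volumes in mm^3: pontomesencephalic reference and per-side LC.
REFERENCE_VOLUME_MM3 = 6200.0
LC_VOLUME_MM3 = 700.0


# --------------------------------------------------------------------------- boxes
@dataclass
class BoxGeometry:
    """Where the template boxes sit and how wide they are.

    Offsets are in mm relative to the grid centre; in-plane extents are in mm
    and converted to whole voxels at the requested spacing.  The through-plane
    extent is whatever is needed to reach the target volume.
    """

    grid_shape: tuple[int, int, int] = (256, 256, 20)
    reference_center_mm: tuple[float, float, float] = (0.0, 10.0, 0.0)
    reference_inplane_mm: tuple[float, float] = (24.0, 28.0)
    lc_left_center_mm: tuple[float, float, float] = (-6.0, -12.0, 0.0)
    lc_inplane_mm: tuple[float, float] = (7.2, 10.8)
    reference_volume_mm3: float = REFERENCE_VOLUME_MM3
    lc_volume_mm3: float = LC_VOLUME_MM3
    min_lc_voxels: int = 10


@dataclass
class BoxSet:
    """The three bounding boxes as boolean masks on a common grid."""

    masks: dict[str, np.ndarray]
    affine: np.ndarray
    space: Literal["template", "native"] = "template"
    provenance: str = "constructed"
    n_ambiguous: int = 0  # native voxels whose pre-image fell in >1 box

    def __post_init__(self) -> None:
        for name in BOX_NAMES:
            if name not in self.masks:
                raise ValueError(f"missing box {name!r}")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise ValueError("box masks must share one grid")
        names = list(self.masks)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                if (self.masks[names[a]] & self.masks[names[b]]).any():
                    raise ValueError("boxes must be pairwise disjoint")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return next(iter(self.masks.values())).shape

    def indices(self, name: str) -> np.ndarray:
        """Voxel indices of a box, cached (masks are treated as immutable)."""
        cache = self.__dict__.setdefault("_idx_cache", {})
        if name not in cache:
            cache[name] = np.argwhere(self.masks[name])
        return cache[name]

    def bounds(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Inclusive (lo, hi) voxel bounds of a box."""
        idx = self.indices(name)
        return idx.min(axis=0), idx.max(axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(np.asarray(self.affine)[:3, :3])))

    def volume_mm3(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.voxel_volume


def _target_voxel_count(target_mm3: float, voxel_volume: float) -> int:
    """Voxel count whose total volume is closest to the target (ties: fewer)."""
    lo = math.floor(target_mm3 / voxel_volume)
    hi = lo + 1
    if abs(lo * voxel_volume - target_mm3) <= abs(hi * voxel_volume - target_mm3):
        return max(lo, 1)
    return hi


def _fill_box(
    grid_shape, center_idx, nx: int, ny: int, n_voxels: int, name: str
) -> np.ndarray:
    """Rasterise a quasi-rectangular box: full in-plane slices plus a partial
    final slice filled in linear order (x fastest) to hit the exact count."""
    per_slice = nx * ny
    nz_full, rem = divmod(n_voxels, per_slice)
    nz_used = nz_full + (1 if rem else 0)
    x0 = int(round(center_idx[0])) - nx // 2
    y0 = int(round(center_idx[1])) - ny // 2
    z0 = int(round(center_idx[2])) - nz_used // 2
    if (
        x0 < 0
        or y0 < 0
        or z0 < 0
        or x0 + nx > grid_shape[0]
        or y0 + ny > grid_shape[1]
        or z0 + nz_used > grid_shape[2]
    ):
        raise ValueError(
            f"box {name!r} ({nx}x{ny}x{nz_used} voxels at origin "
            f"({x0},{y0},{z0})) does not fit in grid {tuple(grid_shape)}"
        )
    mask = np.zeros(grid_shape, dtype=bool)
    mask[x0 : x0 + nx, y0 : y0 + ny, z0 : z0 + nz_full] = True
    if rem:
        flat = np.zeros(per_slice, dtype=bool)
        flat[:rem] = True
        # x fastest within the slice
        mask[x0 : x0 + nx, y0 : y0 + ny, z0 + nz_full] = flat.reshape(ny, nx).T
    return mask


def build_template_boxes(
    voxel_spacing, geometry: BoxGeometry | None = None
) -> BoxSet:
    """Construct the reference and bilateral LC boxes on a template grid.

    Voxel counts are rounded so each box volume is within one voxel volume of
    its target; the left and right LC boxes are exact mirror images about the
    mid-sagittal plane of the grid.
    """
    geom = geometry or BoxGeometry()
    spacing = np.asarray(voxel_spacing, dtype=float)
    if spacing.shape != (3,) or (spacing <= 0).any():
        raise ValueError("voxel_spacing must be three positive mm values")
    vv = float(np.prod(spacing))

    n_lc = _target_voxel_count(geom.lc_volume_mm3, vv)
    if n_lc < geom.min_lc_voxels:
        raise ValueError(
            f"voxel size {tuple(spacing)} mm too coarse: a {geom.lc_volume_mm3} mm^3 "
            f"LC box holds only {n_lc} voxel(s), fewer than k = {geom.min_lc_voxels}"
        )
    n_ref = _target_voxel_count(geom.reference_volume_mm3, vv)

    shape = tuple(geom.grid_shape)
    center = (np.asarray(shape) - 1) / 2.0  # grid centre in voxel coords

    def to_idx(offset_mm):
        return center + np.asarray(offset_mm) / spacing

    def inplane(extent_mm):
        return (
            max(1, int(round(extent_mm[0] / spacing[0]))),
            max(1, int(round(extent_mm[1] / spacing[1]))),
        )

    nx_r, ny_r = inplane(geom.reference_inplane_mm)
    reference = _fill_box(shape, to_idx(geom.reference_center_mm), nx_r, ny_r, n_ref, "reference")

    nx_l, ny_l = inplane(geom.lc_inplane_mm)
    lc_left = _fill_box(shape, to_idx(geom.lc_left_center_mm), nx_l, ny_l, n_lc, "lc_left")
    lc_right = lc_left[::-1, :, :].copy()  # mirror about the mid-sagittal plane

    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = spacing
    return BoxSet(
        masks={"reference": reference, "lc_left": lc_left, "lc_right": lc_right},
        affine=affine,
        space="template",
    )


def resample_boxes(
    boxes: BoxSet,
    transform: DeformationField,
    target_shape,
    target_affine: np.ndarray,
) -> BoxSet:
    """Resample template boxes onto a native grid by nearest-neighbour
    labelling: a native voxel joins a box iff its template pre-image rounds
    into that box."""
    if boxes.space != "template":
        raise ValueError("resample_boxes expects template-space boxes")
    target_shape = tuple(int(n) for n in target_shape)
    target_affine = np.asarray(target_affine, dtype=float)
    tpl_inv = np.linalg.inv(np.asarray(boxes.affine, dtype=float))

    # restrict evaluation to the forward image of the boxes, padded
    lo = np.array(target_shape)
    hi = np.zeros(3, dtype=int)
    tgt_inv = np.linalg.inv(target_affine)
    for name in boxes.masks:
        idx = boxes.indices(name).astype(float)
        world = idx @ np.asarray(boxes.affine)[:3, :3].T + np.asarray(boxes.affine)[:3, 3]
        native_idx = transform.apply(world) @ tgt_inv[:3, :3].T + tgt_inv[:3, 3]
        pad = 2 + int(np.ceil(transform.max_displacement_mm))
        lo = np.minimum(lo, np.floor(native_idx.min(axis=0)).astype(int) - pad)
        hi = np.maximum(hi, np.ceil(native_idx.max(axis=0)).astype(int) + pad)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(target_shape) - 1)
    if (hi < lo).any():
        raise ValueError("boxes map entirely outside the target grid")

    ranges = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
    sub = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    world = sub.astype(float) @ target_affine[:3, :3].T + target_affine[:3, 3]
    pre = transform.apply_inverse(world)
    tpl_idx = np.rint(pre @ tpl_inv[:3, :3].T + tpl_inv[:3, 3]).astype(int)
    inside = np.all((tpl_idx >= 0) & (tpl_idx < np.array(boxes.grid_shape)), axis=1)

    native_masks = {}
    claimed = np.zeros(len(sub), dtype=int)
    hits = {}
    for name, mask in boxes.masks.items():
        hit = np.zeros(len(sub), dtype=bool)
        ii = tpl_idx[inside]
        hit[inside] = mask[ii[:, 0], ii[:, 1], ii[:, 2]]
        hits[name] = hit
        claimed += hit
    ambiguous = claimed > 1  # impossible for a single-valued inverse; guarded anyway
    for name, hit in hits.items():
        nat = np.zeros(target_shape, dtype=bool)
        ok = hit & ~ambiguous
        nat[sub[ok, 0], sub[ok, 1], sub[ok, 2]] = True
        if not nat.any():
            raise ValueError(f"box {name!r} is empty after resampling to the native grid")
        native_masks[name] = nat

    return BoxSet(
        masks=native_masks,
        affine=target_affine,
        space="native",
        provenance="resampled",
        n_ambiguous=int(ambiguous.sum()),
    )


# ------------------------------------------------------------------- selection
_OFFSETS = {
    6: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) == 1
    ],
    18: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if 1 <= abs(dx) + abs(dy) + abs(dz) <= 2
    ],
    26: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
}


def _check_box(data: np.ndarray, box_mask: np.ndarray) -> np.ndarray:
    box_mask = np.asarray(box_mask, dtype=bool)
    if box_mask.shape != data.shape:
        raise ValueError("box mask and image must share one grid")
    if not box_mask.any():
        raise ValueError("box is empty")
    if not np.isfinite(data[box_mask]).all():
        raise ValueError("non-finite intensities inside the box")
    return box_mask


def select_brightest_connected(
    data: np.ndarray,
    box_mask: np.ndarray,
    k: int = 10,
    connectivity: int = 26,
) -> np.ndarray:
    """Greedy seeded growth of the k brightest connected voxels inside a box.

    Seeds at the box's maximum-intensity voxel, then repeatedly adds the
    highest-intensity voxel adjacent (under the given connectivity) to the
    grown set and still inside the box.  Stops at k voxels or when the
    frontier empties (the caller reports short sets through QC, not errors).
    Ties break on the smallest linear index, x varying fastest.

    Returns the selected voxel indices as an (m, 3) int array sorted by
    linear index, m <= k.
    """
    data = np.asarray(data)
    box_mask = _check_box(data, box_mask)
    if k < 1:
        raise ValueError("k must be >= 1")
    if connectivity not in _OFFSETS:
        raise ValueError("connectivity must be 6, 18, or 26")
    nx, ny, nz = data.shape
    offsets = _OFFSETS[connectivity]

    idx = np.argwhere(box_mask)
    lins = idx[:, 0] + nx * (idx[:, 1] + ny * idx[:, 2])
    vals = data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
    seed_pos = np.lexsort((lins, -vals))[0]
    seed = tuple(int(v) for v in idx[seed_pos])

    in_set = np.zeros(data.shape, dtype=bool)
    selected = [seed]
    in_set[seed] = True
    heap: list[tuple[float, int, int, int, int]] = []

    def push_neighbors(i, j, kk):
        for dx, dy, dz in offsets:
            x, y, z = i + dx, j + dy, kk + dz
            if 0 <= x < nx and 0 <= y < ny and 0 <= z < nz and box_mask[x, y, z] and not in_set[x, y, z]:
                heapq.heappush(heap, (-float(data[x, y, z]), x + nx * (y + ny * z), x, y, z))

    push_neighbors(*seed)
    while len(selected) < k and heap:
        _, _, x, y, z = heapq.heappop(heap)
        if in_set[x, y, z]:
            continue
        in_set[x, y, z] = True
        selected.append((x, y, z))
        push_neighbors(x, y, z)

    out = np.array(selected, dtype=int)
    order = np.argsort(out[:, 0] + nx * (out[:, 1] + ny * out[:, 2]))
    return out[order]


def exact_brightest_connected(
    data: np.ndarray,
    box_mask: np.ndarray,
    k: int,
    connectivity: int = 26,
    max_box_voxels: int = 512,
) -> np.ndarray:
    """Exact maximum-sum connected k-subset by exhaustive enumeration.

    Exponential in k; restricted to k <= 6 and small boxes.  Intended as a
    slow cross-check of the greedy rule, not for production use.  Ties break
    on the lexicographically smallest sorted linear-index tuple.
    """
    data = np.asarray(data)
    box_mask = _check_box(data, box_mask)
    if not 1 <= k <= 6:
        raise ValueError("exact search supports 1 <= k <= 6")
    idx = np.argwhere(box_mask)
    if len(idx) > max_box_voxels:
        raise ValueError(f"box too large for exact search ({len(idx)} > {max_box_voxels} voxels)")
    nx, ny, nz = data.shape
    lin_of = {tuple(v): int(v[0] + nx * (v[1] + ny * v[2])) for v in idx}
    by_lin = {l: v for v, l in lin_of.items()}
    offsets = _OFFSETS[connectivity]
    adj: dict[int, list[int]] = {}
    for (i, j, kk), l in lin_of.items():
        adj[l] = sorted(
            lin_of[(i + dx, j + dy, kk + dz)]
            for dx, dy, dz in offsets
            if (i + dx, j + dy, kk + dz) in lin_of
        )

    best: tuple[float, tuple[int, ...]] | None = None

    def consider(sub: frozenset[int]) -> None:
        nonlocal best
        key = tuple(sorted(sub))
        s = float(sum(data[by_lin[l]] for l in key))
        if best is None or s > best[0] + 1e-12 or (abs(s - best[0]) <= 1e-12 and key < best[1]):
            best = (s, key)

    def extend(sub: frozenset[int], ext: set[int], v: int, nbhd: set[int]) -> None:
        if len(sub) == k:
            consider(sub)
            return
        ext = set(ext)
        while ext:
            w = min(ext)
            ext.remove(w)
            new_ext = ext | {u for u in adj[w] if u > v and u not in sub and u not in nbhd}
            extend(sub | {w}, new_ext, v, nbhd | set(adj[w]))

    for v in sorted(by_lin):
        extend(frozenset([v]), {u for u in adj[v] if u > v}, v, set(adj[v]))

    assert best is not None
    return np.array([by_lin[l] for l in best[1]], dtype=int)


# ------------------------------------------------------------------- LC-I
@dataclass
class LCResult:
    """Per-subject LC intensity with QC flags."""

    selected_left: np.ndarray
    selected_right: np.ndarray
    lc_i_left: float | None
    lc_i_right: float | None
    lc_i: float | None
    reference_mean: float
    formula: str = "ratio"
    qc: dict[str, dict[str, bool]] = field(default_factory=dict)

    def side_valid(self, side: str) -> bool:
        return all(self.qc.get(side, {}).values())


def _qc_flags(sel: np.ndarray, box_mask: np.ndarray, k: int, connectivity: int) -> dict[str, bool]:
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    lo = sel.min(axis=0)
    m = np.zeros(sel.max(axis=0) - lo + 1, dtype=bool)
    loc = sel - lo
    m[loc[:, 0], loc[:, 1], loc[:, 2]] = True
    _, n_comp = ndimage.label(m, structure=structure)
    centroid = np.rint(sel.mean(axis=0)).astype(int)
    return {
        "connected": n_comp == 1,
        "inside_box": bool(box_mask[sel[:, 0], sel[:, 1], sel[:, 2]].all()),
        "full_size": len(sel) == k,
        "centroid_in_box": bool(box_mask[tuple(centroid)]),
    }


def compute_lc_intensity(
    image: ImageVolume,
    native_boxes: BoxSet,
    k: int = 10,
    connectivity: int = 26,
    formula: Literal["ratio", "contrast"] = "ratio",
) -> LCResult:
    """Normalised LC intensity: per-side brightest-connected mean over the
    reference-region mean (``ratio``, default) or contrast ``(m - r)/r``.

    Sides failing any QC flag are excluded from the bilateral average; if one
    side remains, its value is reported alone (flagged through ``qc``).
    """
    if formula not in ("ratio", "contrast"):
        raise ValueError("formula must be 'ratio' or 'contrast'")
    data = np.asarray(image.data, dtype=float)
    if native_boxes.grid_shape != data.shape:
        raise ValueError("boxes and image are on different grids")
    ref_idx = native_boxes.indices("reference")
    r = float(data[ref_idx[:, 0], ref_idx[:, 1], ref_idx[:, 2]].mean())
    if r <= 0:
        raise ValueError(f"reference mean {r} <= 0: normalization is not meaningful")

    sides = {}
    qc = {}
    for side, box_name in (("left", "lc_left"), ("right", "lc_right")):
        # run the search on the box's bounding window; indices map back by offset
        lo, hi = native_boxes.bounds(box_name)
        sl = tuple(slice(l, h + 1) for l, h in zip(lo, hi))
        sel = select_brightest_connected(
            data[sl], native_boxes.masks[box_name][sl], k, connectivity
        ) + lo
        m = float(data[sel[:, 0], sel[:, 1], sel[:, 2]].mean())
        value = m / r if formula == "ratio" else (m - r) / r
        sides[side] = (sel, value)
        qc[side] = _qc_flags(sel, native_boxes.masks[box_name], k, connectivity)

    valid = [sides[s][1] for s in ("left", "right") if all(qc[s].values())]
    lc_i = float(np.mean(valid)) if valid else None
    return LCResult(
        selected_left=sides["left"][0],
        selected_right=sides["right"][0],
        lc_i_left=sides["left"][1],
        lc_i_right=sides["right"][1],
        lc_i=lc_i,
        reference_mean=r,
        formula=formula,
        qc=qc,
    )
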