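"""Synthetic subjects with known ground truth.

Every downstream stage — box resampling, brightest-connected-voxel search,
mask warping, composite VOIs, ANCOVA and partial correlation — is validated
against phantoms generated here: a noisy brainstem-like TSE slab carrying
two compact hyperintense LC clusters inside the template boxes (plus
optional bright distractors outside them), a two-blob template NBM mask
pushed through a known invertible deformation, and a cohort table whose
group effects, covariate distributions and conditional correlations are set
by construction.

Default cohort conditions (group sizes, age and sex distributions, cognitive
and imaging measure means/SDs, the LC-I missingness pattern) follow the
clinical cohort this pipeline is designed around: four groups — Control,
AD, LATE, FTD — of 15/23/17/17 subjects.  Group effect sizes on LC contrast
and NBM scale are free parameters.

Determinism: each (design.seed, stage, subject) triple seeds its own
generator, so identical designs reproduce bit-identical images and tables
regardless of generation order.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .image import ImageVolume, MaskVolume
from .lc_intensity import BoxGeometry, BoxSet, build_template_boxes, resample_boxes
from .nbm_volume import warp_mask
from .transforms import DeformationField

__all__ = [
    "CovariateModel",
    "PhantomDesign",
    "PhantomSubject",
    "make_template_nbm_mask",
    "generate_lc_phantom",
    "generate_nbm_phantom",
    "generate_cohort",
    "subject_region_table",
]

DEFAULT_GROUPS = ("Control", "AD", "LATE", "FTD")
DEFAULT_N = (15, 23, 17, 17)

# per-group (Control, AD, LATE, FTD) means and SDs of the cohort measures
_MEASURE_TABLE: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "mmse": ((28.8, 24.4, 24.6, 20.9), (1.0, 3.1, 2.8, 5.2)),
    "mattis_drs": ((141.0, 126.0, 129.0, 110.0), (3.2, 7.6, 7.4, 25.5)),
    "memory_score": ((80.7, 32.7, 38.1, 38.2), (5.2, 16.1, 16.3, 25.6)),
    "parietal_score": ((185.6, 180.0, 182.5, 149.6), (1.8, 5.4, 3.0, 31.3)),
    "executive_score": ((61.6, 47.7, 48.2, 30.3), (8.8, 9.7, 9.2, 14.6)),
    "hippocampus_vol": ((2.45, 1.92, 1.72, 1.77), (0.24, 0.30, 0.35, 0.36)),
    "amygdala_vol": ((0.96, 0.75, 0.72, 0.68), (0.11, 0.11, 0.16, 0.23)),
    "entorhinal_vol": ((1.28, 0.93, 0.90, 0.85), (0.20, 0.31, 0.26, 0.30)),
    "temporal_meta_ct": ((2.86, 2.53, 2.55, 2.25), (0.12, 0.20, 0.22, 0.30)),
    "lateral_temporal_ct": ((2.78, 2.50, 2.48, 2.29), (0.13, 0.14, 0.22, 0.23)),
    "lateral_parietal_ct": ((2.33, 2.14, 2.15, 2.07), (0.15, 0.17, 0.15, 0.15)),
    "medial_parietal_ct": ((2.31, 2.13, 2.12, 1.99), (0.13, 0.16, 0.11, 0.19)),
    "frontal_ct": ((2.57, 2.39, 2.32, 2.19), (0.10, 0.15, 0.13, 0.19)),
}

COGNITIVE = ("mmse", "mattis_drs", "memory_score", "parietal_score", "executive_score")
IMAGING = tuple(m for m in _MEASURE_TABLE if m not in COGNITIVE)
MEASURES = ("lc_i", "nbm_vol_norm", *IMAGING, *COGNITIVE)


@dataclass
class CovariateModel:
    """Age/sex generating distributions per group."""

    age_mean: dict[str, float] = field(
        default_factory=lambda: dict(zip(DEFAULT_GROUPS, (68.7, 70.4, 77.3, 70.1)))
    )
    age_sd: dict[str, float] = field(
        default_factory=lambda: dict(zip(DEFAULT_GROUPS, (3.6, 6.5, 5.2, 8.6)))
    )
    female_p: dict[str, float] = field(
        default_factory=lambda: dict(
            zip(DEFAULT_GROUPS, (10 / 15, 11 / 23, 6 / 17, 8 / 17))
        )
    )
    # linear covariate effects on measures (zero when unspecified)
    age_slope: dict[str, float] = field(default_factory=dict)
    sex_shift: dict[str, float] = field(default_factory=dict)
    age_reference: float = 70.0

    def group_age(self, group: str) -> tuple[float, float]:
        return self.age_mean.get(group, 70.0), self.age_sd.get(group, 6.0)

    def group_female_p(self, group: str) -> float:
        return self.female_p.get(group, 0.5)


@dataclass
class PhantomDesign:
    """Full specification of a synthetic cohort.  Same design + seed means
    bit-identical output."""

    n_per_group: int | tuple[int, ...] = DEFAULT_N
    group_labels: tuple[str, ...] = DEFAULT_GROUPS
    lc_contrast_by_group: dict[str, float] = field(
        default_factory=lambda: {"Control": 1.30, "AD": 1.18, "LATE": 1.18, "FTD": 1.22}
    )
    nbm_scale_by_group: dict[str, float] = field(
        default_factory=lambda: {"Control": 1.00, "AD": 0.85, "LATE": 0.88, "FTD": 0.88}
    )
    noise_sigma: float = 2.0  # intensity units; background is 100
    noise_model: str = "gaussian"  # gaussian | rician
    background_intensity: float = 100.0
    tse_voxel: tuple[float, float, float] = (0.4, 0.4, 3.0)
    tse_grid: tuple[int, int, int] = (256, 256, 20)
    t1_voxel: tuple[float, float, float] = (1.0, 1.0, 1.0)
    nbm_grid: tuple[int, int, int] = (96, 96, 64)
    nbm_template_voxel: tuple[float, float, float] = (0.5, 0.5, 0.5)
    lc_cluster_voxels: int = 20
    n_distractors: int = 2
    distractor_contrast: float = 1.5
    tse_shift_mm: float = 1.5  # max |template->native| in-plane translation
    nbm_disp_amplitude_mm: float = 0.5
    nbm_disp_period_mm: float = 20.0
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    measure_means: dict[str, dict[str, float]] = field(default_factory=dict)
    measure_sds: dict[str, float] = field(default_factory=dict)
    lc_i_sd: float = 0.05
    nbm_norm_control: float = 0.28  # per-mil NBM volume of the control group
    nbm_norm_sd: float = 0.03
    partial_corr_targets: dict[tuple[str, str], float] = field(default_factory=dict)
    missing_lc_i: dict[str, int] = field(default_factory=lambda: {"LATE": 1, "FTD": 5})
    icv_mean: float = 1.45e6
    icv_sd: float = 1.2e5
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_per_group, int):
            self.n_per_group = tuple([self.n_per_group] * len(self.group_labels))
        self.n_per_group = tuple(int(n) for n in self.n_per_group)
        if len(self.n_per_group) != len(self.group_labels):
            raise ValueError("n_per_group and group_labels disagree in length")
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("n_per_group must be >= 1 everywhere")
        for g in self.group_labels:
            if self.lc_contrast_by_group.get(g, 1.0) <= 0:
                raise ValueError(f"LC contrast for group {g!r} must be > 0")
            if self.nbm_scale_by_group.get(g, 1.0) <= 0:
                raise ValueError(f"NBM scale for group {g!r} must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")

    # ---------------------------------------------------------------- helpers
    @property
    def n_total(self) -> int:
        return int(sum(self.n_per_group))

    def subject_group(self, index: int) -> str:
        if not 0 <= index < self.n_total:
            raise IndexError(f"subject_index {index} outside cohort of {self.n_total}")
        offset = 0
        for g, n in zip(self.group_labels, self.n_per_group):
            if index < offset + n:
                return g
            offset += n
        raise AssertionError

    def rng(self, stage: int, index: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage, index])

    def lc_contrast(self, group: str) -> float:
        return self.lc_contrast_by_group.get(group, 1.0)

    def nbm_scale(self, group: str) -> float:
        return self.nbm_scale_by_group.get(group, 1.0)

    def group_mean(self, measure: str, group: str) -> float:
        if measure in self.measure_means and group in self.measure_means[measure]:
            return self.measure_means[measure][group]
        if measure == "lc_i":
            return self.lc_contrast(group)
        if measure == "nbm_vol_norm":
            return self.nbm_norm_control * self.nbm_scale(group) ** 3
        means, _ = _MEASURE_TABLE[measure]
        by_group = dict(zip(DEFAULT_GROUPS, means))
        return by_group.get(group, means[0])

    def measure_sd(self, measure: str) -> float:
        if measure in self.measure_sds:
            return self.measure_sds[measure]
        if measure == "lc_i":
            return self.lc_i_sd
        if measure == "nbm_vol_norm":
            return self.nbm_norm_sd
        _, sds = _MEASURE_TABLE[measure]
        return float(np.mean(sds))


@dataclass
class PhantomSubject:
    subject_id: str
    group: str
    age: float | None = None
    sex: str | None = None
    icv_mm3: float | None = None
    scores: dict[str, float] = field(default_factory=dict)
    # LC fields
    tse_image: ImageVolume | None = None
    tse_transform: DeformationField | None = None
    true_lc_voxels: dict[str, np.ndarray] = field(default_factory=dict)
    true_lc_contrast: float | None = None
    # NBM fields
    t1_grid_shape: tuple[int, int, int] | None = None
    deformation: DeformationField | None = None
    native_nbm_mask: MaskVolume | None = None
    true_nbm_volume_mm3: float | None = None
    region_table: pd.DataFrame | None = None

    def save(self, out_dir: str | Path) -> None:
        """Write the subject to disk: NIfTI images/masks, the transform as a
        text affine (+ displacement NIfTI), and a ground-truth JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        truth: dict[str, object] = {
            "subject_id": self.subject_id,
            "group": self.group,
            "age": self.age,
            "sex": self.sex,
            "icv_mm3": self.icv_mm3,
            "scores": self.scores,
        }
        if self.tse_image is not None:
            self.tse_image.save(out / "tse.nii.gz")
            self.tse_transform.save(out / "tse_transform.txt")
            truth["true_lc_contrast"] = self.true_lc_contrast
            truth["true_lc_voxels"] = {
                side: np.asarray(v).tolist() for side, v in self.true_lc_voxels.items()
            }
        if self.native_nbm_mask is not None:
            self.native_nbm_mask.save(out / "nbm_native.nii.gz")
            self.deformation.save(out / "nbm_transform.txt")
            truth["true_nbm_volume_mm3"] = self.true_nbm_volume_mm3
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)


# ------------------------------------------------------------------ clusters
from .lc_intensity import _OFFSETS  # noqa: E402  (shared connectivity offsets)


def _compact_cluster(
    allowed: np.ndarray, n: int, spacing, center_idx=None
) -> np.ndarray:
    """Grow a compact 26-connected cluster of exactly n voxels inside a mask,
    closest (in mm) to the mask centroid first.  Deterministic."""
    allowed = np.asarray(allowed, dtype=bool)
    idx = np.argwhere(allowed)
    if len(idx) < n:
        raise ValueError(f"cluster of {n} voxels cannot fit: region holds {len(idx)}")
    spacing = np.asarray(spacing, dtype=float)
    if center_idx is None:
        center_idx = idx.mean(axis=0)
    d2 = (((idx - center_idx) * spacing) ** 2).sum(axis=1)
    nx, ny, nz = allowed.shape
    lins = idx[:, 0] + nx * (idx[:, 1] + ny * idx[:, 2])
    start = tuple(int(v) for v in idx[np.lexsort((lins, d2))[0]])

    def dist2(v):
        return float((((np.asarray(v) - center_idx) * spacing) ** 2).sum())

    in_set = np.zeros(allowed.shape, dtype=bool)
    in_set[start] = True
    members = [start]
    heap: list[tuple[float, int, int, int, int]] = []

    def push(i, j, k):
        for dx, dy, dz in _OFFSETS[26]:
            x, y, z = i + dx, j + dy, k + dz
            if 0 <= x < nx and 0 <= y < ny and 0 <= z < nz and allowed[x, y, z] and not in_set[x, y, z]:
                heapq.heappush(heap, (dist2((x, y, z)), x + nx * (y + ny * z), x, y, z))

    push(*start)
    while len(members) < n and heap:
        _, _, x, y, z = heapq.heappop(heap)
        if in_set[x, y, z]:
            continue
        in_set[x, y, z] = True
        members.append((x, y, z))
        push(x, y, z)
    if len(members) < n:
        raise ValueError(f"region too fragmented for a connected cluster of {n} voxels")
    out = np.array(members, dtype=int)
    order = np.argsort(out[:, 0] + nx * (out[:, 1] + ny * out[:, 2]))
    return out[order]


# ------------------------------------------------------------------ LC phantom
_BOX_CACHE: dict[tuple, "BoxSet"] = {}


def _template_boxes_cached(voxel: tuple, grid: tuple) -> BoxSet:
    """Default-geometry template boxes, memoised (they are never mutated)."""
    key = (voxel, grid)
    if key not in _BOX_CACHE:
        _BOX_CACHE[key] = build_template_boxes(voxel, BoxGeometry(grid_shape=grid))
    return _BOX_CACHE[key]


def _tse_affine(design: PhantomDesign) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = design.tse_voxel
    return aff


def generate_lc_phantom(
    design: PhantomDesign, subject_index: int, subject: PhantomSubject | None = None
) -> PhantomSubject:
    """TSE slab with bright LC clusters of known contrast inside the boxes.

    The slab has uniform background b, one compact cluster of intensity
    b * contrast(group) centred in each native LC box (ground truth recorded
    before noise), optional bright distractors outside all boxes, and
    additive Gaussian (or Rician) noise.
    """
    group = design.subject_group(subject_index)
    rng = design.rng(1, subject_index)
    boxes = _template_boxes_cached(tuple(design.tse_voxel), tuple(design.tse_grid))

    shift = rng.uniform(-design.tse_shift_mm, design.tse_shift_mm, size=2)
    transform = DeformationField.translation([shift[0], shift[1], 0.0])
    native_affine = _tse_affine(design)
    native_boxes = resample_boxes(boxes, transform, design.tse_grid, native_affine)

    b = design.background_intensity
    contrast = design.lc_contrast(group)
    data = np.full(design.tse_grid, b, dtype=float)
    spacing = np.asarray(design.tse_voxel)
    truth: dict[str, np.ndarray] = {}
    for side, name in (("left", "lc_left"), ("right", "lc_right")):
        lo, hi = native_boxes.bounds(name)
        sl = tuple(slice(l, h + 1) for l, h in zip(lo, hi))
        try:
            cluster = _compact_cluster(
                native_boxes.masks[name][sl], design.lc_cluster_voxels, spacing
            ) + lo
        except ValueError as exc:
            raise ValueError(f"box {name!r}: {exc}") from None
        data[cluster[:, 0], cluster[:, 1], cluster[:, 2]] = b * contrast
        truth[side] = cluster

    if design.n_distractors:
        # bright blobs strictly outside every (margin-padded) box bounding region
        bounds = []
        for m in native_boxes.masks.values():
            idx_m = np.argwhere(m)
            bounds.append((idx_m.min(axis=0) - 3, idx_m.max(axis=0) + 3))
        grid = np.asarray(design.tse_grid)
        half = np.array([2, 2, 1])  # distractor window half-size in voxels
        for _ in range(design.n_distractors):
            for _attempt in range(100):
                center = np.array([rng.integers(half[a], grid[a] - half[a]) for a in range(3)])
                clear = all(
                    ((center + half) < lo).any() or ((center - half) > hi).any()
                    for lo, hi in bounds
                )
                if clear:
                    break
            else:  # pragma: no cover - only with pathological geometry
                continue
            window = np.ones(2 * half + 1, dtype=bool)
            blob = _compact_cluster(window, 8, spacing, center_idx=half.astype(float))
            blob = blob + (center - half)
            data[blob[:, 0], blob[:, 1], blob[:, 2]] = b * design.distractor_contrast

    if design.noise_sigma > 0:
        # single-precision noise stream: MR magnitude data carry no more depth
        if design.noise_model == "gaussian":
            data = data + design.noise_sigma * rng.standard_normal(data.shape, dtype=np.float32)
        else:  # rician magnitude noise
            n1 = design.noise_sigma * rng.standard_normal(data.shape, dtype=np.float32)
            n2 = design.noise_sigma * rng.standard_normal(data.shape, dtype=np.float32)
            data = np.sqrt((data + n1) ** 2 + n2**2)

    subj = subject or PhantomSubject(subject_id=f"sub-{subject_index:03d}", group=group)
    subj.tse_image = ImageVolume(data, native_affine)
    subj.tse_transform = transform
    subj.true_lc_voxels = truth
    subj.true_lc_contrast = contrast
    return subj


# ------------------------------------------------------------------ NBM phantom
def make_template_nbm_mask(
    grid_shape=(96, 96, 64), spacing=(0.5, 0.5, 0.5)
) -> MaskVolume:
    """Bundled synthetic stand-in for an atlas NBM mask: two mirror-image
    ellipsoidal blobs (one per hemisphere) on a 0.5 mm grid.  Synthetic — not
    derived from any atlas.  The half-millimetre sampling keeps the
    discretisation error of so small a nucleus (~420 mm^3 per side) around a
    percent; semi-axes are deliberately off-lattice so the blob surface does
    not ride the voxel-centre shells."""
    shape = tuple(int(n) for n in grid_shape)
    sx = np.asarray(spacing, dtype=float)
    semi = np.array([3.55, 8.15, 3.45])  # mm
    cy, cz = (shape[1] - 1) / 2.0, (shape[2] - 1) / 2.0
    cx_l = (shape[0] - 1) / 2.0 - 10.0 / sx[0]
    cx_r = (shape[0] - 1) / 2.0 + 10.0 / sx[0]
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    mask = np.zeros(shape, dtype=bool)
    for cx in (cx_l, cx_r):
        d = (
            ((ii - cx) * sx[0] / semi[0]) ** 2
            + ((jj - cy) * sx[1] / semi[1]) ** 2
            + ((kk - cz) * sx[2] / semi[2]) ** 2
        )
        mask |= d <= 1.0
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = sx
    return MaskVolume(mask, aff, side="bilateral")


def generate_nbm_phantom(
    design: PhantomDesign,
    subject_index: int,
    template_mask: MaskVolume | None = None,
    subject: PhantomSubject | None = None,
) -> PhantomSubject:
    """Native NBM mask through a known deformation: isotropic scaling by the
    group factor about the mask centroid, composed with a low-amplitude
    sinusoidal displacement (invertible by construction)."""
    group = design.subject_group(subject_index)
    rng = design.rng(2, subject_index)
    template = template_mask or make_template_nbm_mask(design.nbm_grid, design.nbm_template_voxel)

    idx = np.argwhere(template.binarized()).astype(float)
    centroid = template.index_to_world(idx.mean(axis=0))
    scale_aff = DeformationField.scaling(design.nbm_scale(group), center_mm=centroid).affine
    phase = rng.uniform(0.0, 2.0 * np.pi, size=3)
    if design.nbm_disp_amplitude_mm > 0:
        field_ = DeformationField.sinusoidal(
            template.shape,
            template.affine,
            design.nbm_disp_amplitude_mm,
            design.nbm_disp_period_mm,
            phase=phase,
            affine=scale_aff,
        )
    else:
        field_ = DeformationField(affine=scale_aff)

    native = warp_mask(template, field_, template.shape, template.affine)
    icv = float(max(rng.normal(design.icv_mean, design.icv_sd), 8.0e5))

    subj = subject or PhantomSubject(subject_id=f"sub-{subject_index:03d}", group=group)
    subj.t1_grid_shape = template.shape
    subj.deformation = field_
    subj.native_nbm_mask = native
    subj.true_nbm_volume_mm3 = native.volume_mm3
    if subj.icv_mm3 is None:
        subj.icv_mm3 = icv
    return subj


# ------------------------------------------------------------------ cohort
def _residual_correlation(design: PhantomDesign) -> np.ndarray:
    """Correlation matrix of the measure residuals from the pairwise targets."""
    p = len(MEASURES)
    pos = {m: i for i, m in enumerate(MEASURES)}
    R = np.eye(p)
    for (a, b), rho in design.partial_corr_targets.items():
        if a not in pos or b not in pos:
            raise ValueError(f"unknown measure in partial_corr_targets: {(a, b)}")
        R[pos[a], pos[b]] = R[pos[b], pos[a]] = float(rho)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        raise ValueError("requested partial-correlation matrix is not positive definite") from None
    return L


def generate_cohort(
    design: PhantomDesign, include_images: bool = False
) -> tuple[pd.DataFrame, list[PhantomSubject]]:
    """Draw the cohort table (and, optionally, per-subject images).

    Measures and cognitive scores are a joint Gaussian built so that,
    conditional on group, age and sex, the requested pairwise correlations
    hold; group mean shifts and linear covariate effects are added on top.
    The LC-I missingness pattern is injected per group (last subjects of the
    group), mirroring real acquisition failures.
    """
    rng = design.rng(3)
    cm = design.covariate_model
    n = design.n_total
    groups = [design.subject_group(i) for i in range(n)]

    ages = np.empty(n)
    sexes: list[str] = []
    icvs = np.empty(n)
    for i, g in enumerate(groups):
        mu, sd = cm.group_age(g)
        ages[i] = rng.normal(mu, sd)
        sexes.append("F" if rng.uniform() < cm.group_female_p(g) else "M")
        icvs[i] = max(rng.normal(design.icv_mean, design.icv_sd), 8.0e5)

    L = _residual_correlation(design)
    z = rng.standard_normal((n, len(MEASURES))) @ L.T
    female = np.array([1.0 if s == "F" else 0.0 for s in sexes])

    data: dict[str, np.ndarray] = {}
    for j, measure in enumerate(MEASURES):
        mean = np.array([design.group_mean(measure, g) for g in groups])
        sd = design.measure_sd(measure)
        slope = cm.age_slope.get(measure, 0.0)
        shift = cm.sex_shift.get(measure, 0.0)
        data[measure] = mean + slope * (ages - cm.age_reference) + shift * female + sd * z[:, j]

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n)],
            "group": groups,
            "age": ages,
            "sex": sexes,
            "icv_mm3": icvs,
            **data,
        }
    )

    for g, m in design.missing_lc_i.items():
        if g in design.group_labels and m > 0:
            rows = table.index[table["group"] == g][-m:]
            table.loc[rows, "lc_i"] = np.nan

    subjects: list[PhantomSubject] = []
    template = make_template_nbm_mask(design.nbm_grid, design.nbm_template_voxel) if include_images else None
    for i in range(n):
        subj = PhantomSubject(
            subject_id=table.at[i, "subject_id"],
            group=groups[i],
            age=float(ages[i]),
            sex=sexes[i],
            icv_mm3=float(icvs[i]),
            scores={m: float(table.at[i, m]) for m in COGNITIVE},
        )
        if include_images:
            generate_lc_phantom(design, i, subject=subj)
            generate_nbm_phantom(design, i, template_mask=template, subject=subj)
            subj.icv_mm3 = float(icvs[i])
            subj.region_table = subject_region_table(table.iloc[i])
        subjects.append(subj)
    return table, subjects


# ------------------------------------------------------------------ region stats
def subject_region_table(row: pd.Series) -> pd.DataFrame:
    """Regional stats table consistent with a cohort row.

    Parcel thicknesses are the minimum-norm solution reproducing the drawn
    composite values exactly (parcels shared between composites get
    intermediate values); all parcels carry equal surface area, so the
    area-weighted and plain means coincide.  Subcortical and entorhinal
    volumes are written per side as ``value * ICV / 1000`` so that the
    side-averaged, ICV-normalised (per-mil) volume equals the drawn value.
    """
    from .roi_composites import default_voi_definitions

    defs = default_voi_definitions()
    thickness_defs = [d for d in defs if d.measure == "thickness"]
    parcels = sorted({m for d in thickness_defs for m in d.members})
    A = np.zeros((len(thickness_defs), len(parcels)))
    targets = np.empty(len(thickness_defs))
    for r_i, d in enumerate(thickness_defs):
        for m in d.members:
            A[r_i, parcels.index(m)] = 1.0 / len(d.members)
        targets[r_i] = float(row[d.name])
    base = 2.5
    correction, *_ = np.linalg.lstsq(A, targets - A @ np.full(len(parcels), base), rcond=None)
    thickness = dict(zip(parcels, base + correction))

    icv = float(row["icv_mm3"])
    rows: list[dict] = []
    for hemi in ("lh", "rh"):
        for parcel in parcels:
            vol = float(row["entorhinal_vol"]) * icv / 1000.0 if parcel == "entorhinal" else 800.0
            rows.append(
                {
                    "hemisphere": hemi,
                    "region": parcel,
                    "volume_mm3": vol,
                    "thickness_mm": thickness[parcel],
                    "area_mm2": 700.0,
                }
            )
        for region, measure in (("Hippocampus", "hippocampus_vol"), ("Amygdala", "amygdala_vol")):
            rows.append(
                {
                    "hemisphere": hemi,
                    "region": region,
                    "volume_mm3": float(row[measure]) * icv / 1000.0,
                    "thickness_mm": np.nan,
                    "area_mm2": np.nan,
                }
            )
    return pd.DataFrame(rows)


def design_to_yaml(design: PhantomDesign, path: str | Path) -> None:
    import yaml

    d = asdict(design)
    d["partial_corr_targets"] = {f"{a}|{b}": v for (a, b), v in design.partial_corr_targets.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(d), fh, sort_keys=False)


def design_from_yaml(path: str | Path) -> PhantomDesign:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "partial_corr_targets" in cfg:
        cfg["partial_corr_targets"] = {
            tuple(k.split("|")): v for k, v in cfg["partial_corr_targets"].items()
        }
    if "covariate_model" in cfg and isinstance(cfg["covariate_model"], dict):
        cfg["covariate_model"] = CovariateModel(**cfg["covariate_model"])
    for key in (
        "group_labels", "n_per_group", "tse_voxel", "tse_grid",
        "t1_voxel", "nbm_grid", "nbm_template_voxel",
    ):
        if key in cfg and isinstance(cfg[key], list):
            cfg[key] = tuple(cfg[key])
    return PhantomDesign(**cfg)


def _plain(obj):
    """Recursively convert numpy scalars/tuples for YAML serialisation."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
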