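"""End-to-end orchestration: subjects -> LC-I -> NBM -> VOIs -> statistics.

A run is driven by a :class:`RunConfig` holding either a phantom design or a
manifest of per-subject input paths.  Stages are independent per subject;
a failed stage is recorded in the failure manifest and the affected cells
are left missing (the statistics then proceed with listwise deletion, which
is also how genuinely missing acquisitions are handled).  Identical config
and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .group_stats import AnalysisPlan, run_analysis_plan
from .image import ImageVolume, MaskVolume
from .lc_intensity import BoxGeometry, build_template_boxes, compute_lc_intensity, resample_boxes
from .nbm_volume import compute_nbm_volume, split_bilateral_mask, warp_mask
from .phantom import (
    PhantomDesign,
    PhantomSubject,
    generate_cohort,
    make_template_nbm_mask,
)
from .roi_composites import (
    compute_composite_vois,
    default_voi_definitions,
    load_voi_definitions,
    normalize_volume,
    parse_region_stats,
    write_region_stats,
)
from .transforms import DeformationField

logger = logging.getLogger("lcnbm")

__all__ = ["RunConfig", "PipelineResults", "run_pipeline"]

VOLUME_VOIS = ("hippocampus_vol", "amygdala_vol", "entorhinal_vol")


@dataclass
class RunConfig:
    """One reproducible pipeline run.  Exactly one of ``design`` (phantom
    cohort) or ``manifest`` (paths to real inputs) must be set."""

    out_dir: str | Path = "lcnbm_run"
    design: PhantomDesign | None = None
    manifest: list[dict] | None = None
    k: int = 10
    connectivity: int = 26
    formula: str = "ratio"
    interpolation: str = "trilinear"
    voi_config: str | Path | None = None
    plan: AnalysisPlan | None = None
    run_stats: bool = True
    seed: int | None = None  # overrides design.seed when given
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.design is None) == (self.manifest is None):
            raise ValueError("exactly one of design or manifest must be provided")
        if self.design is not None and self.seed is not None:
            self.design.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        from .phantom import design_from_yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        if "design" in cfg and isinstance(cfg["design"], str):
            cfg["design"] = design_from_yaml(cfg["design"])
        elif "design" in cfg and isinstance(cfg["design"], dict):
            from .phantom import PhantomDesign as PD

            cfg["design"] = PD(**cfg["design"])
        if "plan" in cfg and isinstance(cfg["plan"], dict):
            cfg["plan"] = AnalysisPlan(**cfg["plan"])
        return cls(**cfg)

    def config_hash(self) -> str:
        """Stable hash of the run configuration for provenance."""
        from .phantom import _plain

        payload = {
            "k": self.k,
            "connectivity": self.connectivity,
            "formula": self.formula,
            "interpolation": self.interpolation,
            "seed": self.seed,
            "design": _plain(vars(self.design)) if self.design else None,
            "manifest": self.manifest,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResults:
    cohort: pd.DataFrame
    stats: object | None
    provenance: dict
    failures: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------- subject stages
def _lc_stage(subject: PhantomSubject, config: RunConfig, design: PhantomDesign) -> float | None:
    boxes = build_template_boxes(design.tse_voxel, BoxGeometry(grid_shape=design.tse_grid))
    native = resample_boxes(
        boxes, subject.tse_transform, subject.tse_image.shape, subject.tse_image.affine
    )
    res = compute_lc_intensity(
        subject.tse_image, native, k=config.k, connectivity=config.connectivity,
        formula=config.formula,
    )
    return res.lc_i


def _nbm_stage(subject: PhantomSubject, config: RunConfig, template: MaskVolume) -> float:
    native = warp_mask(
        template,
        subject.deformation,
        subject.t1_grid_shape,
        template.affine,
        interpolation=config.interpolation,
    )
    left, right = split_bilateral_mask(native)
    return compute_nbm_volume(left, right, subject.icv_mm3).vol_norm


def _voi_stage(subject: PhantomSubject, stats_paths, voi_defs, icv: float) -> dict[str, float]:
    table = parse_region_stats(stats_paths, subject_id=subject.subject_id)
    values = compute_composite_vois(table, voi_defs)
    for name in VOLUME_VOIS:
        if name in values:
            values[name] = normalize_volume(values[name], icv)
    return values


def run_pipeline(config: RunConfig) -> PipelineResults:
    """Execute every stage and write the cohort CSV, statistics tables and a
    provenance record under ``config.out_dir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    voi_defs = (
        load_voi_definitions(config.voi_config) if config.voi_config else default_voi_definitions()
    )
    failures: list[dict] = []

    if config.design is not None:
        design = config.design
        if design.n_total == 0:
            raise ValueError("empty cohort: nothing to run")
        table, subjects = generate_cohort(design, include_images=True)
        template = make_template_nbm_mask(design.nbm_grid, design.nbm_template_voxel)
        for i, subject in enumerate(subjects):
            sid = subject.subject_id
            acquired = not np.isnan(table.at[i, "lc_i"])  # missing-by-design acquisitions
            for stage, runner in (
                ("lc_intensity", lambda: _lc_stage(subject, config, design) if acquired else np.nan),
                ("nbm_volume", lambda: _nbm_stage(subject, config, template)),
            ):
                col = "lc_i" if stage == "lc_intensity" else "nbm_vol_norm"
                try:
                    table.at[i, col] = runner()
                except Exception as exc:  # recorded, not fatal
                    failures.append({"subject": sid, "stage": stage, "error": str(exc)})
                    table.at[i, col] = np.nan
                    logger.warning("subject %s stage %s failed: %s", sid, stage, exc)
            try:
                stats_dir = out / "subjects" / sid
                paths = write_region_stats(subject.region_table, stats_dir)
                values = _voi_stage(subject, paths, voi_defs, subject.icv_mm3)
                for name, val in values.items():
                    table.at[i, name] = val
            except Exception as exc:
                failures.append({"subject": sid, "stage": "roi_composites", "error": str(exc)})
                logger.warning("subject %s stage roi_composites failed: %s", sid, exc)
    else:
        if not config.manifest:
            raise ValueError("empty cohort: nothing to run")
        rows = []
        for entry in config.manifest:
            sid = entry["id"]
            row: dict[str, object] = {
                "subject_id": sid,
                "group": entry.get("group"),
                "age": entry.get("age"),
                "sex": entry.get("sex"),
                "icv_mm3": entry.get("icv_mm3"),
                **entry.get("scores", {}),
            }
            if entry.get("tse_image"):
                try:
                    image = ImageVolume.load(entry["tse_image"])
                    transform = (
                        DeformationField.load(entry["tse_transform"])
                        if entry.get("tse_transform")
                        else DeformationField.identity()
                    )
                    spacing = tuple(image.spacing)
                    boxes = build_template_boxes(spacing, BoxGeometry(grid_shape=image.shape))
                    native = resample_boxes(boxes, transform, image.shape, image.affine)
                    res = compute_lc_intensity(
                        image, native, k=config.k, connectivity=config.connectivity,
                        formula=config.formula,
                    )
                    row["lc_i"] = res.lc_i
                except Exception as exc:
                    failures.append({"subject": sid, "stage": "lc_intensity", "error": str(exc)})
            if entry.get("nbm_template_mask") and entry.get("nbm_transform"):
                try:
                    template = MaskVolume.load(entry["nbm_template_mask"])
                    transform = DeformationField.load(entry["nbm_transform"])
                    native = warp_mask(
                        template, transform, template.shape, template.affine,
                        interpolation=config.interpolation,
                    )
                    left, right = split_bilateral_mask(native)
                    nbm = compute_nbm_volume(left, right, float(entry["icv_mm3"]))
                    row["nbm_vol_norm"] = nbm.vol_norm
                    row["nbm_vol_mm3"] = nbm.vol_mean_mm3
                except Exception as exc:
                    failures.append({"subject": sid, "stage": "nbm_volume", "error": str(exc)})
            if entry.get("stats"):
                try:
                    table_s = parse_region_stats(entry["stats"], subject_id=sid)
                    values = compute_composite_vois(table_s, voi_defs)
                    for name in VOLUME_VOIS:
                        if name in values and entry.get("icv_mm3"):
                            values[name] = normalize_volume(values[name], float(entry["icv_mm3"]))
                    row.update(values)
                except Exception as exc:
                    failures.append({"subject": sid, "stage": "roi_composites", "error": str(exc)})
            rows.append(row)
        table = pd.DataFrame(rows)

    cohort_path = out / "cohort.csv"
    table.to_csv(cohort_path, index=False, float_format="%.12g")

    stats = None
    if config.run_stats:
        plan = config.plan
        if plan is None and config.design is not None:
            plan = AnalysisPlan(group_labels=tuple(config.design.group_labels))
        try:
            stats = run_analysis_plan(table, plan)
            stats.ancova.to_csv(out / "ancova.csv", index=False, float_format="%.12g")
            stats.partial_corr.to_csv(out / "partial_corr.csv", index=False, float_format="%.12g")
            stats.group_summary.to_csv(out / "group_summary.csv", index=False, float_format="%.12g")
            stats.r2_table.to_csv(out / "r2_table.csv", index=False, float_format="%.12g")
            with open(out / "test_manifest.json", "w") as fh:
                json.dump(stats.manifest, fh, indent=1, sort_keys=True)
        except Exception as exc:
            failures.append({"subject": None, "stage": "group_stats", "error": str(exc)})
            logger.warning("statistics stage failed: %s", exc)

    provenance = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.design.seed if config.design is not None else config.seed,
        "config_hash": config.config_hash(),
        "n_subjects": int(len(table)),
        "n_failures": len(failures),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    if failures:
        with open(out / "failures.json", "w") as fh:
            json.dump(failures, fh, indent=1)
    return PipelineResults(cohort=table, stats=stats, provenance=provenance, failures=failures)
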