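"""Composite cortical VOIs from regional statistics tables.

Parses the whitespace-delimited, ``#``-commented stats dialect produced by
cortical-surface pipelines (per-hemisphere ``aparc``-style tables carrying
parcel volume / mean thickness / surface area, and an ``aseg``-style table
for subcortical volumes), then aggregates named parcels into the composite
measures used in dementia imaging: a temporal meta-VOI (entorhinal,
parahippocampal, fusiform, inferior and middle temporal), lateral temporal,
lateral parietal, medial parietal and frontal thickness composites, plus
medial-temporal volumes.  Thickness composites are surface-area-weighted
means by default; volumes are sums; both are averaged across hemispheres.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VOIDefinition",
    "parse_region_stats",
    "write_region_stats",
    "load_voi_definitions",
    "default_voi_definitions",
    "compute_composite_vois",
    "normalize_volume",
]

REGION_COLUMNS = ["hemisphere", "region", "volume_mm3", "thickness_mm", "area_mm2"]

#: plausibility band for cortical thickness (mm); values outside warn
THICKNESS_BAND = (0.0, 6.0)


@dataclass(frozen=True)
class VOIDefinition:
    name: str
    members: tuple[str, ...]
    measure: str  # "volume" | "thickness"

    def __post_init__(self) -> None:
        if self.measure not in ("volume", "thickness"):
            raise ValueError(f"unknown measure kind {self.measure!r}")
        if not self.members:
            raise ValueError(f"VOI {self.name!r} has no member regions")


def load_voi_definitions(path: str | Path) -> list[VOIDefinition]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return [
        VOIDefinition(name=v["name"], members=tuple(v["members"]), measure=v["measure"])
        for v in cfg["vois"]
    ]


def default_voi_definitions() -> list[VOIDefinition]:
    ref = importlib.resources.files("lcnbm") / "data" / "voi_definitions.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_voi_definitions(path)


def _parse_one(path: Path) -> list[dict]:
    """Parse one stats file.  Two dialects are recognised from the ColHeaders
    line: aparc-style (per-parcel surface measures, hemisphere from the
    filename or an ``# hemi`` header) and aseg-style (segmentation volumes,
    hemisphere from Left-/Right- name prefixes)."""
    colheaders: list[str] | None = None
    hemi_hint: str | None = None
    name = path.name.lower()
    if name.startswith("lh.") or ".lh." in name:
        hemi_hint = "lh"
    elif name.startswith("rh.") or ".rh." in name:
        hemi_hint = "rh"

    rows: list[dict] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                body = line.lstrip()[1:].strip()
                if body.startswith("ColHeaders"):
                    colheaders = body.split()[1:]
                elif body.startswith("hemi"):
                    hemi_hint = body.split()[-1]
                continue
            if colheaders is None:
                raise ValueError(f"{path}:{lineno}: data row before ColHeaders header")
            fields = line.split()
            if len(fields) != len(colheaders):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(colheaders)} fields "
                    f"({' '.join(colheaders)}), got {len(fields)}"
                )
            rec = dict(zip(colheaders, fields))
            try:
                if "ThickAvg" in rec:  # aparc dialect
                    if hemi_hint not in ("lh", "rh"):
                        raise ValueError("hemisphere unknown (no lh/rh in filename or header)")
                    rows.append(
                        {
                            "hemisphere": hemi_hint,
                            "region": rec["StructName"],
                            "volume_mm3": float(rec["GrayVol"]),
                            "thickness_mm": float(rec["ThickAvg"]),
                            "area_mm2": float(rec["SurfArea"]),
                        }
                    )
                elif "Volume_mm3" in rec:  # aseg dialect
                    struct = rec["StructName"]
                    hemi = "lh" if struct.startswith("Left-") else "rh" if struct.startswith("Right-") else "bilateral"
                    region = struct.removeprefix("Left-").removeprefix("Right-")
                    rows.append(
                        {
                            "hemisphere": hemi,
                            "region": region,
                            "volume_mm3": float(rec["Volume_mm3"]),
                            "thickness_mm": np.nan,
                            "area_mm2": np.nan,
                        }
                    )
                else:
                    raise ValueError(
                        "unrecognised columns: need ThickAvg (aparc) or Volume_mm3 (aseg)"
                    )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
    return rows


def parse_region_stats(paths, subject_id: str | None = None) -> pd.DataFrame:
    """Consolidate one subject's stats files into a tidy region table.

    Columns: hemisphere (lh|rh|bilateral), region, volume_mm3, thickness_mm,
    area_mm2.  Unknown regions are preserved verbatim.  Negative volumes or
    areas are errors; thickness outside (0, 6) mm only warns.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    rows: list[dict] = []
    for p in paths:
        rows.extend(_parse_one(Path(p)))
    if not rows:
        raise ValueError("no data rows parsed")
    table = pd.DataFrame(rows, columns=REGION_COLUMNS)
    if subject_id is not None:
        table.insert(0, "subject_id", subject_id)
    if (table["volume_mm3"] < 0).any() or (table["area_mm2"].dropna() < 0).any():
        raise ValueError("negative volume or surface area in stats table")
    thick = table["thickness_mm"].dropna()
    if ((thick <= THICKNESS_BAND[0]) | (thick >= THICKNESS_BAND[1])).any():
        import warnings

        warnings.warn("thickness values outside the (0, 6) mm plausibility band", stacklevel=2)
    return table


def write_region_stats(table: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Write a region table back to the stats dialect (lh/rh aparc files plus
    an aseg file for rows without thickness).  Round-trips with
    :func:`parse_region_stats`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    cortical = table[table["thickness_mm"].notna()]
    for hemi in ("lh", "rh"):
        sub = cortical[cortical["hemisphere"] == hemi]
        if sub.empty:
            continue
        path = out_dir / f"{hemi}.aparc.stats"
        with open(path, "w") as fh:
            fh.write("# Table of cortical parcellation statistics\n")
            fh.write(f"# hemi {hemi}\n")
            fh.write("# ColHeaders StructName SurfArea GrayVol ThickAvg\n")
            for _, r in sub.iterrows():
                fh.write(
                    f"{r['region']} {r['area_mm2']:.4f} {r['volume_mm3']:.4f} {r['thickness_mm']:.6f}\n"
                )
        written.append(path)
    seg = table[table["thickness_mm"].isna()]
    if not seg.empty:
        path = out_dir / "aseg.stats"
        with open(path, "w") as fh:
            fh.write("# Segmentation volume statistics\n")
            fh.write("# ColHeaders Index SegId Volume_mm3 StructName\n")
            for i, (_, r) in enumerate(seg.iterrows(), start=1):
                prefix = {"lh": "Left-", "rh": "Right-"}.get(r["hemisphere"], "")
                fh.write(f"{i} {i} {r['volume_mm3']:.4f} {prefix}{r['region']}\n")
        written.append(path)
    return written


def _hemi_value(sub: pd.DataFrame, voi: VOIDefinition, hemi: str, weighted: bool) -> float:
    rows = sub[sub["hemisphere"].isin([hemi, "bilateral"])]
    vals, weights = [], []
    for member in voi.members:
        match = rows[rows["region"] == member]
        if match.empty:
            raise ValueError(f"VOI {voi.name!r}: member region {member!r} missing in {hemi}")
        row = match.iloc[0]
        if voi.measure == "volume":
            vals.append(row["volume_mm3"])
            weights.append(1.0)
        else:
            if not np.isfinite(row["thickness_mm"]):
                raise ValueError(f"VOI {voi.name!r}: member {member!r} has no thickness")
            vals.append(row["thickness_mm"])
            weights.append(row["area_mm2"] if weighted else 1.0)
    vals = np.asarray(vals, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if voi.measure == "volume":
        return float(vals.sum())
    return float(np.average(vals, weights=weights))


def compute_composite_vois(
    table: pd.DataFrame,
    definitions: list[VOIDefinition] | None = None,
    area_weighted: bool = True,
) -> dict[str, float]:
    """Per-subject composite measures: per-hemisphere aggregation (volume =
    sum, thickness = area-weighted mean), then left/right average."""
    defs = definitions if definitions is not None else default_voi_definitions()
    out: dict[str, float] = {}
    for voi in defs:
        lh = _hemi_value(table, voi, "lh", area_weighted)
        rh = _hemi_value(table, voi, "rh", area_weighted)
        out[voi.name] = 0.5 * (lh + rh)
    return out


def normalize_volume(volume_mm3: float, icv_mm3: float) -> float:
    """ICV normalisation, per-mil convention (matches the NBM output)."""
    if icv_mm3 <= 0:
        raise ValueError("icv_mm3 must be positive")
    return volume_mm3 / icv_mm3 * 1000.0
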