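"""Phantom generator: determinism, constructed effects, calibration."""

import numpy as np
import pandas as pd
import pytest

from lcnbm import (
    BoxGeometry,
    PhantomDesign,
    build_template_boxes,
    compute_composite_vois,
    compute_lc_intensity,
    generate_cohort,
    generate_lc_phantom,
    resample_boxes,
)
from lcnbm.phantom import subject_region_table
from lcnbm.roi_composites import normalize_volume


def _extract(design, subject, on_truth=False):
    boxes = build_template_boxes(design.tse_voxel, BoxGeometry(grid_shape=design.tse_grid))
    native = resample_boxes(
        boxes, subject.tse_transform, subject.tse_image.shape, subject.tse_image.affine
    )
    data = np.asarray(subject.tse_image.data, dtype=float)
    ref = native.indices("reference")
    r = data[ref[:, 0], ref[:, 1], ref[:, 2]].mean()
    if on_truth:
        vals = [
            data[s[:, 0], s[:, 1], s[:, 2]].mean() / r
            for s in subject.true_lc_voxels.values()
        ]
        return float(np.mean(vals))
    return compute_lc_intensity(subject.tse_image, native).lc_i


# ---------------------------------------------------------------- determinism
def test_identical_seed_reproduces_images_and_table(small_design):
    d1 = PhantomDesign(n_per_group=(3, 3), group_labels=("Control", "AD"), seed=42, missing_lc_i={})
    d2 = PhantomDesign(n_per_group=(3, 3), group_labels=("Control", "AD"), seed=42, missing_lc_i={})
    t1, _ = generate_cohort(d1)
    t2, _ = generate_cohort(d2)
    pd.testing.assert_frame_equal(t1, t2)
    s1 = generate_lc_phantom(d1, 1)
    s2 = generate_lc_phantom(d2, 1)
    assert np.array_equal(s1.tse_image.data, s2.tse_image.data)


def test_different_seeds_differ():
    a = PhantomDesign(n_per_group=2, group_labels=("Control",), seed=1, missing_lc_i={})
    b = PhantomDesign(n_per_group=2, group_labels=("Control",), seed=2, missing_lc_i={})
    assert not np.array_equal(
        generate_lc_phantom(a, 0).tse_image.data, generate_lc_phantom(b, 0).tse_image.data
    )


# -------------------------------------------------------------- LC construction
def test_noiseless_contrast_is_exact(noiseless_design):
    subject = generate_lc_phantom(noiseless_design, 0)
    assert _extract(noiseless_design, subject) == pytest.approx(1.3, rel=1e-12)


def test_unit_contrast_is_null_case():
    design = PhantomDesign(
        n_per_group=4,
        group_labels=("Control",),
        lc_contrast_by_group={"Control": 1.0},
        missing_lc_i={},
        seed=8,
    )
    vals = [_extract(design, generate_lc_phantom(design, i)) for i in range(4)]
    # selecting the brightest of pure noise inflates slightly; stays near 1
    assert abs(np.mean(vals) - 1.0) < 0.05


def test_extraction_tracks_truth_oracle():
    """Mean extracted LC-I agrees with extraction restricted to the true
    voxels of the same noisy images, within 3 SE (the residual gap is the
    brightest-voxel selection bias, identical in both pipelines only when
    selection finds the cluster)."""
    design = PhantomDesign(
        n_per_group=100,
        group_labels=("Control",),
        lc_contrast_by_group={"Control": 1.25},
        missing_lc_i={},
        seed=17,
    )
    extracted, oracle = [], []
    for i in range(100):
        s = generate_lc_phantom(design, i)
        extracted.append(_extract(design, s))
        oracle.append(_extract(design, s, on_truth=True))
    diff = np.asarray(extracted) - np.asarray(oracle)
    se = diff.std(ddof=1) / np.sqrt(len(diff))
    assert abs(diff.mean()) < 3 * se + 3 * 2.0 / 100 / np.sqrt(10)  # + selection-bias allowance


def test_cluster_too_large_for_box_raises():
    design = PhantomDesign(lc_cluster_voxels=5000, missing_lc_i={})
    with pytest.raises(ValueError, match="lc_left"):
        generate_lc_phantom(design, 0)


def test_rician_noise_keeps_magnitudes_positive():
    design = PhantomDesign(
        n_per_group=1, group_labels=("Control",), noise_model="rician",
        noise_sigma=5.0, missing_lc_i={},
    )
    s = generate_lc_phantom(design, 0)
    assert (np.asarray(s.tse_image.data) >= 0).all()


# ------------------------------------------------------------------- cohort
def test_default_missingness_pattern():
    table, _ = generate_cohort(PhantomDesign(seed=2))
    missing = table[table["lc_i"].isna()].groupby("group").size().to_dict()
    assert missing == {"LATE": 1, "FTD": 5}


def test_partial_correlation_targets_are_realised():
    design = PhantomDesign(
        n_per_group=500,
        partial_corr_targets={("nbm_vol_norm", "hippocampus_vol"): 0.7},
        missing_lc_i={},
        seed=23,
    )
    table, _ = generate_cohort(design)
    from lcnbm import partial_correlation

    res = partial_correlation(
        table, "nbm_vol_norm", "hippocampus_vol", covariates=("group", "age", "sex")
    )
    n, q = res.n, 5  # 3 group dummies + age + sex
    se = 1.0 / np.sqrt(n - q - 3)
    assert abs(np.arctanh(res.r) - np.arctanh(0.7)) < 3 * se


def test_non_positive_definite_targets_rejected():
    design = PhantomDesign(
        partial_corr_targets={
            ("lc_i", "mmse"): 0.95,
            ("lc_i", "memory_score"): 0.95,
            ("mmse", "memory_score"): -0.95,
        }
    )
    with pytest.raises(ValueError, match="positive definite"):
        generate_cohort(design)


def test_invalid_designs_rejected():
    with pytest.raises(ValueError, match="contrast"):
        PhantomDesign(lc_contrast_by_group={"Control": -1.0})
    with pytest.raises(ValueError, match="n_per_group"):
        PhantomDesign(n_per_group=(0, 3, 3, 3))
    with pytest.raises(ValueError, match="noise"):
        PhantomDesign(noise_sigma=-1.0)
    with pytest.raises(IndexError):
        PhantomDesign().subject_group(200)


def test_group_age_structure_matches_model():
    table, _ = generate_cohort(PhantomDesign(n_per_group=200, seed=31, missing_lc_i={}))
    means = table.groupby("group")["age"].mean()
    assert means["LATE"] > means["Control"] + 4  # LATE group is older by design


# ----------------------------------------------------------- region stats path
def test_region_table_reproduces_cohort_measures():
    table, _ = generate_cohort(PhantomDesign(n_per_group=(2, 2, 2, 2), missing_lc_i={}, seed=6))
    row = table.iloc[3]
    region = subject_region_table(row)
    values = compute_composite_vois(region)
    for name in (
        "temporal_meta_ct",
        "lateral_temporal_ct",
        "lateral_parietal_ct",
        "medial_parietal_ct",
        "frontal_ct",
    ):
        assert values[name] == pytest.approx(float(row[name]), rel=1e-9)
    for name in ("hippocampus_vol", "amygdala_vol", "entorhinal_vol"):
        normed = normalize_volume(values[name], float(row["icv_mm3"]))
        assert normed == pytest.approx(float(row[name]), rel=1e-9)
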