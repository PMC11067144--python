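"""ANCOVA, partial correlation, Bonferroni families, analysis plan."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats

from lcnbm import (
    AnalysisPlan,
    PhantomDesign,
    ancova_compare,
    bonferroni_adjust,
    generate_cohort,
    partial_correlation,
    run_analysis_plan,
)


@pytest.fixture(scope="module")
def cohort():
    table, _ = generate_cohort(PhantomDesign(seed=13))
    return table


# --------------------------------------------------------- partial correlation
def test_reduces_to_pearson_without_covariates(rng):
    df = pd.DataFrame({"x": rng.normal(size=60), "y": rng.normal(size=60)})
    res = partial_correlation(df, "x", "y")
    r, p = stats.pearsonr(df["x"], df["y"])
    assert abs(res.r - r) < 1e-12
    assert res.p_raw == pytest.approx(p, rel=1e-9)


def test_agrees_with_pingouin(rng):
    n = 120
    z = rng.normal(size=n)
    df = pd.DataFrame(
        {
            "x": 0.8 * z + rng.normal(size=n),
            "y": -0.5 * z + rng.normal(size=n),
            "z": z,
            "w": rng.normal(size=n),
        }
    )
    ours = partial_correlation(df, "x", "y", covariates=("z", "w"))
    ref = pg.partial_corr(df, x="x", y="y", covar=["z", "w"])
    assert ours.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
    assert ours.p_raw == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)
    assert ours.n == n and ours.df == n - 2 - 2


def test_confounded_pair_has_null_partial_correlation(rng):
    n = 4000
    z = rng.normal(size=n)
    df = pd.DataFrame({"x": z + rng.normal(size=n), "y": z + rng.normal(size=n), "z": z})
    plain = partial_correlation(df, "x", "y")
    partial = partial_correlation(df, "x", "y", covariates=("z",))
    se = 1.0 / np.sqrt(n - 1 - 3)
    assert abs(np.arctanh(partial.r)) < 3 * se
    assert plain.r > 0.3  # confounding through z


def test_recovers_generated_partial_correlation(rng):
    n = 5000
    rho = 0.5
    z = rng.normal(size=n)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    uv = rng.multivariate_normal([0, 0], cov, size=n)
    df = pd.DataFrame({"x": 1.5 * z + uv[:, 0], "y": -0.7 * z + uv[:, 1], "z": z})
    res = partial_correlation(df, "x", "y", covariates=("z",))
    se = 1.0 / np.sqrt(n - 1 - 3)
    assert abs(np.arctanh(res.r) - np.arctanh(rho)) < 3 * se


def test_affine_rescaling_invariance(rng):
    n = 80
    df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["x", "y", "z"])
    base = partial_correlation(df, "x", "y", covariates=("z",))
    scaled = df.assign(x=5 * df.x - 3, y=-2 * df.y + 7, z=0.1 * df.z + 2)
    res = partial_correlation(scaled, "x", "y", covariates=("z",))
    assert abs(abs(res.r) - abs(base.r)) < 1e-12
    assert np.sign(res.r) == -np.sign(base.r)  # y was negated


def test_zero_residual_variance_rejected(rng):
    df = pd.DataFrame({"z": rng.normal(size=30)})
    df["x"] = 2 * df.z
    df["y"] = rng.normal(size=30)
    with pytest.raises(ValueError, match="residual variance"):
        partial_correlation(df, "x", "y", covariates=("z",))


# ----------------------------------------------------------------------- ANCOVA
def test_ancova_agrees_with_pingouin(cohort):
    sub = cohort[cohort["group"].isin(["Control", "AD"])].dropna(subset=["lc_i"]).copy()
    sub["sex_code"] = (sub["sex"] == "M").astype(float)
    ours = ancova_compare(cohort, "lc_i", ("Control", "AD"))
    ref = pg.ancova(data=sub, dv="lc_i", between="group", covar=["age", "sex_code"])
    p_ref = float(ref.loc[ref["Source"] == "group", "p_unc"].iloc[0])
    f_ref = float(ref.loc[ref["Source"] == "group", "F"].iloc[0])
    assert ours.p_raw == pytest.approx(p_ref, rel=1e-6)
    assert ours.f_stat == pytest.approx(f_ref, rel=1e-6)
    assert ours.f_stat == pytest.approx(ours.t_stat**2, rel=1e-12)


def test_orthogonal_covariates_leave_difference_raw():
    ages = np.tile([60.0, 65.0, 70.0, 75.0], 2)
    sexes = np.tile(["F", "M"], 4)
    df = pd.DataFrame(
        {
            "group": ["A"] * 4 + ["B"] * 4,
            "age": ages,
            "sex": sexes,
            "m": [1.0, 2.0, 3.0, 4.0, 3.0, 4.0, 5.0, 6.0],
        }
    )
    res = ancova_compare(df, "m", ("A", "B"))
    raw = df[df.group == "B"].m.mean() - df[df.group == "A"].m.mean()
    assert res.adjusted_difference == pytest.approx(raw, abs=1e-10)


def test_listwise_deletion_reports_n(cohort):
    res = ancova_compare(cohort, "lc_i", ("Control", "FTD"))
    n_complete = (
        cohort[cohort.group.isin(["Control", "FTD"])]
        .dropna(subset=["lc_i", "age", "sex"])
        .shape[0]
    )
    assert res.n_used == n_complete  # 5 FTD LC-I values missing by design


def test_singular_design_rejected():
    df = pd.DataFrame(
        {
            "group": ["A"] * 5 + ["B"] * 5,
            "age": np.r_[np.arange(5), np.arange(5)] + 60.0,
            "sex": ["F"] * 5 + ["M"] * 5,  # sex == group indicator
            "m": np.arange(10.0),
        }
    )
    with pytest.raises(ValueError, match="singular|collinear"):
        ancova_compare(df, "m", ("A", "B"))


def test_small_group_rejected(cohort):
    tiny = cohort.head(4)
    with pytest.raises(ValueError, match="complete cases"):
        ancova_compare(tiny, "lc_i", ("Control", "AD"))


# ------------------------------------------------------------------ Bonferroni
@pytest.mark.parametrize(
    "p, family, expected",
    [(0.001, 48, 0.048), (0.2, 1, 0.2), (0.5, 6, 1.0)],
)
def test_bonferroni_values(p, family, expected):
    assert bonferroni_adjust([p], family)[0] == pytest.approx(expected)


def test_bonferroni_validation():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        bonferroni_adjust([1.2], 4)
    with pytest.raises(ValueError, match="smaller"):
        bonferroni_adjust([0.1, 0.2, 0.3], 2)


# ------------------------------------------------------------------ the plan
def test_default_plan_family_sizes(cohort):
    res = run_analysis_plan(cohort)
    assert res.manifest["A_lc_nbm_group"] == 6
    assert res.manifest["B_imaging_group"] == 48
    assert res.manifest["C_cognitive_group"] == 30
    assert res.manifest["D_imaging_corr"] == 64
    assert res.manifest["E_cognitive_corr"] == 48
    assert (res.ancova["p_adjusted"] >= res.ancova["p_raw"] - 1e-15).all()
    assert (res.ancova["p_adjusted"] <= 1.0).all()
    assert len(res.partial_corr[res.partial_corr.family == "D_imaging_corr"]) == 64
    assert len(res.partial_corr[res.partial_corr.family == "E_cognitive_corr"]) == 40


def test_two_group_plan_shrinks_family_b():
    plan = AnalysisPlan(group_labels=("Control", "AD"))
    assert plan.family_sizes()["B_imaging_group"] == 8


def test_plan_missing_column_rejected(cohort):
    broken = cohort.drop(columns=["mmse"])
    with pytest.raises(ValueError, match="mmse"):
        run_analysis_plan(broken)


def test_group_effects_detected_and_null_family_d_quiet(cohort):
    res = run_analysis_plan(cohort)
    fam_a = res.ancova[res.ancova.family == "A_lc_nbm_group"].set_index(["measure", "group_b"])
    # the large built-in deficits are detected after correction: LC-I in AD
    # (the biggest LC effect with the biggest group) and NBM everywhere.
    # The milder LC-I FTD effect and the age-confounded LATE contrast are
    # allowed to miss significance, as real cohorts of this size do.
    assert fam_a.loc[("lc_i", "AD"), "p_adjusted"] < 0.05
    for g in ("AD", "LATE", "FTD"):
        assert fam_a.loc[("nbm_vol_norm", g), "p_adjusted"] < 0.05
    # residuals are generated uncorrelated: Bonferroni keeps family D silent
    fam_d = res.partial_corr[res.partial_corr.family == "D_imaging_corr"]
    assert (fam_d["p_adjusted"] < 0.05).mean() <= 0.05


def test_r2_table_shape(cohort):
    res = run_analysis_plan(cohort)
    assert set(res.r2_table["analysis_set"]) == {"all_patients", "AD", "LATE", "FTD"}
    assert res.r2_table.shape[0] == 8  # 4 sets x {lc_i, nbm_vol_norm}
    vals = res.r2_table.drop(columns=["analysis_set", "x"]).to_numpy(dtype=float)
    assert ((vals >= 0) & (vals <= 1)).all()
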