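"""Group comparisons and partial correlations for the cohort table.

The inference layer mirrors a standard clinical-neuroimaging plan:

* pairwise group differences by ANCOVA (linear model of the measure on a
  group indicator plus age and sex), two-sided;
* partial correlations by least-squares residualisation of both variables on
  the covariate block (age, sex and, for pooled-patient analyses,
  diagnostic-group dummies), with p from the t distribution on
  ``n - 2 - q`` degrees of freedom;
* Bonferroni correction within declared test families.  A family may be
  declared larger than the number of tests actually computed.

Missing cells are handled by listwise deletion per test; the n actually used
is always reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AncovaResult",
    "PartialCorrResult",
    "AnalysisPlan",
    "ancova_compare",
    "partial_correlation",
    "bonferroni_adjust",
    "run_analysis_plan",
]

GROUP_COL = "group"
SEX_COL = "sex"
AGE_COL = "age"

DEFAULT_GROUPS = ("Control", "AD", "LATE", "FTD")

#: measures entering the default analysis plan
LC_NBM_MEASURES = ("lc_i", "nbm_vol_norm")
IMAGING_MEASURES = (
    "hippocampus_vol",
    "amygdala_vol",
    "entorhinal_vol",
    "temporal_meta_ct",
    "lateral_temporal_ct",
    "lateral_parietal_ct",
    "medial_parietal_ct",
    "frontal_ct",
)
COGNITIVE_MEASURES = ("mmse", "mattis_drs", "memory_score", "parietal_score", "executive_score")


@dataclass
class AncovaResult:
    measure: str
    group_a: str
    group_b: str
    adjusted_difference: float  # B minus A, covariate-adjusted
    t_stat: float
    f_stat: float
    p_raw: float
    n_used: int
    family: str | None = None
    p_adjusted: float | None = None


@dataclass
class PartialCorrResult:
    x: str
    y: str
    covariates: str
    n: int
    r: float
    r2: float
    p_raw: float
    df: int
    family: str | None = None
    p_adjusted: float | None = None


def _encode_sex(col: pd.Series) -> np.ndarray:
    """Single 0/1 indicator from a binary sex column (alphabetical reference)."""
    vals = pd.Series(col).astype(str)
    levels = sorted(vals.unique())
    if len(levels) > 2:
        raise ValueError(f"sex column has {len(levels)} levels: {levels}")
    return (vals == levels[-1]).to_numpy(dtype=float)


def _covariate_matrix(df: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    """Numeric covariate block: sex -> indicator, group -> reference dummies
    (first label in appearance order is the reference), others as numeric."""
    cols: list[np.ndarray] = []
    for cov in covariates:
        if cov == SEX_COL:
            cols.append(_encode_sex(df[cov]))
        elif cov == GROUP_COL:
            levels = list(pd.unique(df[cov]))
            for lev in levels[1:]:
                cols.append((df[cov] == lev).to_numpy(dtype=float))
        else:
            cols.append(pd.to_numeric(df[cov]).to_numpy(dtype=float))
    if not cols:
        return np.empty((len(df), 0))
    return np.column_stack(cols)


def ancova_compare(
    table: pd.DataFrame,
    measure: str,
    groups: tuple[str, str],
    covariates: Sequence[str] = (AGE_COL, SEX_COL),
) -> AncovaResult:
    """Two-group ANCOVA: OLS of the measure on a group indicator plus
    covariates, over the two groups' complete cases.  Reports the group
    coefficient (adjusted mean difference, two-sided t test; F = t^2)."""
    ga, gb = groups
    sub = table[table[GROUP_COL].isin(groups)]
    cols = [measure, GROUP_COL, *covariates]
    sub = sub.dropna(subset=[c for c in cols if c in sub.columns])
    counts = sub[GROUP_COL].value_counts()
    for g in groups:
        if counts.get(g, 0) < 3:
            raise ValueError(
                f"group {g!r} has {counts.get(g, 0)} complete cases for "
                f"{measure!r}; need >= 3"
            )
    indicator = (sub[GROUP_COL] == gb).to_numpy(dtype=float)
    X = np.column_stack([indicator, _covariate_matrix(sub, covariates)])
    X = sm.add_constant(X, prepend=True)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"singular ANCOVA design for {measure!r} ({ga} vs {gb}): a covariate "
            "is constant or collinear with the group indicator"
        )
    fit = sm.OLS(pd.to_numeric(sub[measure]).to_numpy(dtype=float), X).fit()
    t = float(fit.tvalues[1])
    return AncovaResult(
        measure=measure,
        group_a=ga,
        group_b=gb,
        adjusted_difference=float(fit.params[1]),
        t_stat=t,
        f_stat=t * t,
        p_raw=float(fit.pvalues[1]),
        n_used=int(len(sub)),
    )


def partial_correlation(
    table: pd.DataFrame,
    x: str,
    y: str,
    covariates: Sequence[str] = (),
) -> PartialCorrResult:
    """Partial correlation of x and y given a covariate block.

    Both variables are residualised on [1, covariates] by least squares; the
    partial r is the Pearson correlation of the residuals, with the p-value
    from ``t = r sqrt(df / (1 - r^2))`` on ``df = n - 2 - q`` degrees of
    freedom (q = number of covariate columns after encoding).  With an empty
    covariate set this reduces exactly to the plain Pearson correlation.
    """
    cols = [x, y, *covariates]
    sub = table.dropna(subset=[c for c in cols if c in table.columns])
    n = len(sub)
    C = _covariate_matrix(sub, covariates)
    q = C.shape[1]
    df = n - 2 - q
    if df < 1:
        raise ValueError(f"too few complete cases (n={n}, q={q}) for a partial correlation")
    Z = np.column_stack([np.ones(n), C])
    xv = pd.to_numeric(sub[x]).to_numpy(dtype=float)
    yv = pd.to_numeric(sub[y]).to_numpy(dtype=float)
    beta_x, *_ = np.linalg.lstsq(Z, xv, rcond=None)
    beta_y, *_ = np.linalg.lstsq(Z, yv, rcond=None)
    rx = xv - Z @ beta_x
    ry = yv - Z @ beta_y
    sx, sy = float(np.sqrt(rx @ rx)), float(np.sqrt(ry @ ry))
    tiny_x = sx <= 1e-10 * max(float(np.abs(xv).max()), 1.0)
    tiny_y = sy <= 1e-10 * max(float(np.abs(yv).max()), 1.0)
    if tiny_x or tiny_y:
        raise ValueError(
            f"zero residual variance: {x if tiny_x else y!r} is fully explained by the covariates"
        )
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrResult(
        x=x, y=y, covariates="+".join(covariates) or "none", n=n, r=r, r2=r * r, p_raw=p, df=df
    )


def bonferroni_adjust(p_values: Sequence[float], family_size: int) -> np.ndarray:
    """Elementwise ``min(1, p * family_size)``.  The declared family may be
    larger than the list of p-values but never smaller."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if family_size < len(p):
        raise ValueError(f"family size {family_size} smaller than number of tests {len(p)}")
    return np.minimum(1.0, p * family_size)


# ------------------------------------------------------------------- plan
@dataclass
class AnalysisPlan:
    """The default test families.

    * A — LC-I and NBM volume, each patient group vs controls (2 x 3 = 6);
    * B — other imaging measures, all pairwise group contrasts (8 x 6 = 48);
    * C — cognitive measures, all pairwise contrasts (5 x 6 = 30);
    * D — partial correlations of LC-I/NBM with imaging measures over four
      analysis sets: all patients pooled (group-dummy covariates) and each
      patient group alone (2 x 8 x 4 = 64);
    * E — partial correlations with cognitive scores (2 x 5 x 4 = 40 tests);
      its declared family size is configurable and defaults to 48.
    """

    group_labels: tuple[str, ...] = DEFAULT_GROUPS
    control_label: str = "Control"
    lc_nbm_measures: tuple[str, ...] = LC_NBM_MEASURES
    imaging_measures: tuple[str, ...] = IMAGING_MEASURES
    cognitive_measures: tuple[str, ...] = COGNITIVE_MEASURES
    ancova_covariates: tuple[str, ...] = (AGE_COL, SEX_COL)
    imaging_corr_covariates: tuple[str, ...] = (AGE_COL, SEX_COL)
    cognitive_corr_covariates: tuple[str, ...] = (AGE_COL,)
    cognitive_corr_family_size: int = 48
    alpha: float = 0.05

    @property
    def patient_labels(self) -> tuple[str, ...]:
        return tuple(g for g in self.group_labels if g != self.control_label)

    def pairwise_contrasts(self) -> list[tuple[str, str]]:
        labels = self.group_labels
        return [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))]

    def family_sizes(self) -> dict[str, int]:
        n_pairs = len(self.pairwise_contrasts())
        n_sets = 1 + len(self.patient_labels)
        return {
            "A_lc_nbm_group": len(self.lc_nbm_measures) * len(self.patient_labels),
            "B_imaging_group": len(self.imaging_measures) * n_pairs,
            "C_cognitive_group": len(self.cognitive_measures) * n_pairs,
            "D_imaging_corr": len(self.lc_nbm_measures) * len(self.imaging_measures) * n_sets,
            "E_cognitive_corr": self.cognitive_corr_family_size,
        }

    @classmethod
    def from_yaml(cls, path) -> "AnalysisPlan":
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        for key in ("group_labels", "lc_nbm_measures", "imaging_measures",
                    "cognitive_measures", "ancova_covariates",
                    "imaging_corr_covariates", "cognitive_corr_covariates"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)


@dataclass
class AnalysisResults:
    """Bundle returned by :func:`run_analysis_plan`."""

    ancova: pd.DataFrame
    partial_corr: pd.DataFrame
    group_summary: pd.DataFrame
    r2_table: pd.DataFrame
    manifest: dict[str, int]


def _check_columns(table: pd.DataFrame, plan: AnalysisPlan) -> None:
    needed = set(
        (GROUP_COL, *plan.ancova_covariates, *plan.lc_nbm_measures,
         *plan.imaging_measures, *plan.cognitive_measures)
    )
    missing = sorted(needed - set(table.columns))
    if missing:
        raise ValueError(f"analysis plan references missing columns: {missing}")


def run_analysis_plan(table: pd.DataFrame, plan: AnalysisPlan | None = None) -> AnalysisResults:
    """Execute the default analysis plan and return group-comparison and
    correlation tables plus a machine-readable family-size manifest."""
    plan = plan or AnalysisPlan()
    _check_columns(table, plan)
    sizes = plan.family_sizes()

    anc_rows: list[AncovaResult] = []
    # family A: LC-I / NBM vs controls
    for measure in plan.lc_nbm_measures:
        for patient in plan.patient_labels:
            res = ancova_compare(table, measure, (plan.control_label, patient), plan.ancova_covariates)
            res.family = "A_lc_nbm_group"
            anc_rows.append(res)
    # families B and C: all pairwise contrasts
    for family, measures in (
        ("B_imaging_group", plan.imaging_measures),
        ("C_cognitive_group", plan.cognitive_measures),
    ):
        for measure in measures:
            for pair in plan.pairwise_contrasts():
                res = ancova_compare(table, measure, pair, plan.ancova_covariates)
                res.family = family
                anc_rows.append(res)

    # correlation families over four analysis sets
    patients = table[table[GROUP_COL] != plan.control_label]
    analysis_sets: list[tuple[str, pd.DataFrame, bool]] = [("all_patients", patients, True)]
    analysis_sets += [
        (g, patients[patients[GROUP_COL] == g], False) for g in plan.patient_labels
    ]
    pc_rows: list[PartialCorrResult] = []
    for family, targets, covs in (
        ("D_imaging_corr", plan.imaging_measures, plan.imaging_corr_covariates),
        ("E_cognitive_corr", plan.cognitive_measures, plan.cognitive_corr_covariates),
    ):
        for set_name, sub, pooled in analysis_sets:
            cov = (GROUP_COL, *covs) if pooled else covs
            for x in plan.lc_nbm_measures:
                for y in targets:
                    res = partial_correlation(sub, x, y, cov)
                    res.family = family
                    res.covariates = f"{set_name}:{res.covariates}"
                    pc_rows.append(res)

    anc = pd.DataFrame([vars(r) for r in anc_rows])
    pc = pd.DataFrame([vars(r) for r in pc_rows])
    for frame in (anc, pc):
        frame["p_adjusted"] = np.nan
        for family, group in frame.groupby("family").groups.items():
            frame.loc[group, "p_adjusted"] = bonferroni_adjust(
                frame.loc[group, "p_raw"].to_numpy(), sizes[family]
            )

    # Table-1-style summary: group mean (SD) per measure plus significance flags
    measures = [*plan.lc_nbm_measures, *plan.imaging_measures, *plan.cognitive_measures]
    summary_rows = []
    for measure in measures:
        row: dict[str, object] = {"measure": measure}
        for g in plan.group_labels:
            vals = pd.to_numeric(table.loc[table[GROUP_COL] == g, measure], errors="coerce").dropna()
            row[f"{g}_mean"] = vals.mean()
            row[f"{g}_sd"] = vals.std(ddof=1)
            row[f"{g}_n"] = len(vals)
        sig = anc[
            (anc["measure"] == measure)
            & (anc["p_adjusted"] < plan.alpha)
            & ((anc["group_a"] == plan.control_label) | (anc["group_b"] == plan.control_label))
        ]
        row["sig_vs_control"] = ",".join(
            sorted(set(sig["group_a"]).union(sig["group_b"]) - {plan.control_label})
        )
        summary_rows.append(row)
    group_summary = pd.DataFrame(summary_rows)

    # Table-2-style r^2 matrix: one row per (analysis set, LC/NBM measure)
    pc = pc.assign(analysis_set=pc["covariates"].str.split(":").str[0])
    r2 = pc.pivot_table(index=["analysis_set", "x"], columns="y", values="r2")
    order = [*plan.cognitive_measures, *plan.imaging_measures]
    r2_table = r2[[c for c in order if c in r2.columns]].reset_index()

    return AnalysisResults(
        ancova=anc,
        partial_corr=pc,
        group_summary=group_summary,
        r2_table=r2_table,
        manifest=sizes,
    )
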