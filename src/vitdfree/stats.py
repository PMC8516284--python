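"""Statistical analysis stages for the cohort pipeline.

The analysis plan mirrors standard clinical-epidemiology practice:

* a Shapiro–Wilk normality gate choosing between parametric and
  rank-based two-group tests (skewed variables are ln-transformed);
* Kruskal–Wallis across the six Gc diplotype groups with Bonferroni-
  corrected pairwise Mann–Whitney post-hoc tests (15 pairs, threshold
  0.05/15 = 0.0033);
* Pearson correlation tables between clinical factors and vitamin D
  measures, with ln-transforms applied per variable;
* an interaction scan testing whether the metabolite→bone-Z slope differs
  by BMI category (normal vs overweight/obese); and
* covariate-adjusted OLS regressions (age, sex, FM_Z, LM_Z) with
  variance-inflation-factor collinearity screening (flag at VIF >= 3).

All p-values are two-sided; every stage is complete-case on the columns it
uses and reports the n it actually consumed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .binding import all_diplotypes

__all__ = [
    "ComparisonResult", "IsoformComparison", "RegressionResult",
    "AnalysisReport", "normality_gate", "compare_two_groups",
    "compare_categorical", "compare_isoform_groups", "correlation_table",
    "interaction_scan", "adjusted_regression", "run_table_suite",
    "METABOLITE_COLUMNS", "BONE_Z_COLUMNS",
]

#: Vitamin D measures analyzed throughout (derived-panel column names).
METABOLITE_COLUMNS = [
    "total_25ohd_ng_ml", "spe_bioa_ng_ml", "con_bioa_ng_ml",
    "spe_free_pg_ml", "con_free_pg_ml", "measured_free_pg_ml",
    "d24_25ohd3_ng_ml", "vmr_x100", "vdbp_ug_ml",
]

BONE_Z_COLUMNS = ["bmc_tb_z", "bmd_tb_z", "bmd_ls_z", "bmd_tblh_z"]

DEFAULT_COVARIATES = ("age_years", "sex", "fm_z", "lm_z")


@dataclass
class ComparisonResult:
    variable: str
    grouping: str
    test: str               # 't' | 'mann-whitney' | 'kruskal-wallis' | 'chi-squared'
    statistic: float
    p: float
    group_summaries: dict[str, str] = field(default_factory=dict)
    transformed: bool = False
    n: int = 0


@dataclass
class IsoformComparison:
    variable: str
    kw_statistic: float
    kw_p: float
    pairwise: pd.DataFrame   # columns: group1, group2, u, p, significant
    threshold: float
    n: int


@dataclass
class RegressionResult:
    outcome: str
    predictor: str
    covariates: tuple[str, ...]
    beta: float
    se: float
    p: float
    r2: float
    ci_low: float
    ci_high: float
    vif: dict[str, float]
    vif_flag: bool
    n: int


@dataclass
class AnalysisReport:
    """Container for the full table suite; serializable via io.write_report."""

    group_comparisons: pd.DataFrame
    correlations: pd.DataFrame
    isoform_tests: pd.DataFrame
    interactions: pd.DataFrame
    regressions: pd.DataFrame
    n_total: int

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "group_comparisons": self.group_comparisons,
            "correlations": self.correlations,
            "isoform_tests": self.isoform_tests,
            "interactions": self.interactions,
            "regressions": self.regressions,
        }


def normality_gate(x, alpha: float = 0.05) -> dict:
    """Shapiro–Wilk gate: decide normality and ln-transform skewed data.

    Returns ``{'is_normal', 'transformed_x', 'transform_applied'}``.  If the
    raw sample fails the test and is strictly positive, the natural log is
    applied and the decision is re-made on the transformed values.
    """
    x = np.asarray(pd.Series(x).dropna(), dtype=float)
    if x.size < 3:
        raise ValueError("normality gate needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("normality gate undefined for a constant vector")
    p_raw = sps.shapiro(x).pvalue
    if p_raw >= alpha:
        return {"is_normal": True, "transformed_x": x, "transform_applied": False}
    if (x > 0).all():
        lx = np.log(x)
        p_log = sps.shapiro(lx).pvalue
        if p_log >= alpha:
            return {"is_normal": True, "transformed_x": lx,
                    "transform_applied": True}
    return {"is_normal": False, "transformed_x": x, "transform_applied": False}


def compare_two_groups(x, group, variable: str = "x",
                       grouping: str = "group",
                       alpha: float = 0.05) -> ComparisonResult:
    """Two-group comparison: t-test if the gate passes, else Mann–Whitney U."""
    df = pd.DataFrame({"x": x, "g": group}).dropna()
    levels = sorted(df["g"].unique(), key=str)
    if len(levels) != 2 or (df.groupby("g").size() < 1).any():
        raise ValueError(f"need exactly two non-empty groups, got {levels}")
    a = df.loc[df["g"] == levels[0], "x"].to_numpy(dtype=float)
    b = df.loc[df["g"] == levels[1], "x"].to_numpy(dtype=float)
    gate = normality_gate(df["x"], alpha=alpha)
    if gate["is_normal"]:
        xa, xb = (np.log(a), np.log(b)) if gate["transform_applied"] else (a, b)
        stat, p = sps.ttest_ind(xa, xb)
        test = "t"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann-whitney"
    summaries = {
        str(lv): f"{np.mean(v):.2f} +/- {np.std(v, ddof=1):.2f}" if v.size > 1
        else f"{np.mean(v):.2f}"
        for lv, v in zip(levels, (a, b))
    }
    return ComparisonResult(variable, grouping, test, float(stat), float(p),
                            summaries, gate["transform_applied"], len(df))


def compare_categorical(flag, group, variable: str = "flag",
                        grouping: str = "group") -> ComparisonResult:
    """Chi-squared test of independence for a categorical variable."""
    df = pd.DataFrame({"f": flag, "g": group}).dropna()
    if df.empty:
        raise ValueError("no complete cases for the chi-squared test")
    table = pd.crosstab(df["f"], df["g"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("chi-squared test needs >= 2 levels on both axes")
    chi2, p, _, _ = sps.chi2_contingency(table)
    counts = {f"{c}": "/".join(str(v) for v in table[c]) for c in table.columns}
    return ComparisonResult(variable, grouping, "chi-squared",
                            float(chi2), float(p), counts, False, len(df))


def compare_isoform_groups(x, diplotype, variable: str = "x",
                           alpha: float = 0.05) -> IsoformComparison:
    """Kruskal–Wallis across the six Gc diplotypes + Bonferroni post hoc.

    The omnibus test is followed by all 15 pairwise two-sided Mann–Whitney
    tests; a pair is flagged significant below alpha / 15 (0.0033 for the
    conventional 0.05).
    """
    df = pd.DataFrame({"x": x, "d": [str(v) for v in diplotype]}).dropna()
    expected = [str(d) for d in all_diplotypes()]
    counts = df["d"].value_counts()
    missing = [d for d in expected if counts.get(d, 0) < 2]
    if missing:
        raise ValueError(
            f"need n >= 2 in all six diplotype groups; inadequate: {missing}")
    groups = [df.loc[df["d"] == d, "x"].to_numpy(dtype=float) for d in expected]
    kw_stat, kw_p = sps.kruskal(*groups)
    n_pairs = math.comb(len(expected), 2)
    threshold = alpha / n_pairs
    rows = []
    for (i, gi), (j, gj) in itertools.combinations(enumerate(expected), 2):
        u, p = sps.mannwhitneyu(groups[i], groups[j], alternative="two-sided")
        rows.append({"group1": gi, "group2": gj, "u": float(u),
                     "p": float(p), "significant": bool(p < threshold)})
    return IsoformComparison(variable, float(kw_stat), float(kw_p),
                             pd.DataFrame(rows), threshold, len(df))


def correlation_table(df: pd.DataFrame, variables: list[str],
                      metabolites: list[str],
                      transform_map: dict[str, bool] | None = None
                      ) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of factors vs metabolites.

    ``transform_map`` marks columns to ln-transform first (only applied to
    strictly positive pairwise-complete values).  Long format: one row per
    (variable, metabolite) with r, p and the n used.
    """
    transform_map = transform_map or {}
    rows = []
    for var in variables:
        for met in metabolites:
            cols = [var] if var == met else [var, met]
            sub = df[cols].dropna()
            n = len(sub)
            if n < 3:
                rows.append({"variable": var, "metabolite": met,
                             "r": np.nan, "p": np.nan, "n": n})
                continue
            a = sub[var].to_numpy(dtype=float)
            b = sub[met].to_numpy(dtype=float)
            if transform_map.get(var) and (a > 0).all():
                a = np.log(a)
            if transform_map.get(met) and (b > 0).all():
                b = np.log(b)
            r, p = sps.pearsonr(a, b)
            rows.append({"variable": var, "metabolite": met,
                         "r": float(r), "p": float(p), "n": n})
    return pd.DataFrame(rows)


def _design(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Numeric design matrix: sex and booleans become 0/1 indicators."""
    out = {}
    for c in cols:
        s = df[c]
        if s.dtype == bool:
            out[c] = s.astype(float)
        elif s.dtype == object:
            levels = sorted(s.unique(), key=str)
            if len(levels) != 2:
                raise ValueError(f"column {c!r} is not binary: {levels}")
            out[c] = (s == levels[1]).astype(float)
        else:
            out[c] = s.astype(float)
    return pd.DataFrame(out, index=df.index)


def interaction_scan(df: pd.DataFrame, outcome: str, metabolite: str,
                     bmi_col: str = "bmi_category",
                     covariates: tuple[str, ...] = DEFAULT_COVARIATES
                     ) -> dict:
    """p-value of the BMI-category x metabolite interaction term.

    Fits ``outcome ~ metabolite * I(overweight/obese) + covariates`` by OLS;
    BMI category is binarized as normal vs overweight-or-obese.  A
    significant product term means the metabolite→outcome slope differs
    between the weight groups.
    """
    cols = [outcome, metabolite, bmi_col, *covariates]
    sub = df[cols].dropna()
    owob = (sub[bmi_col] != "normal").astype(float)
    if owob.nunique() < 2:
        raise ValueError("both BMI categories must be present for the scan")
    X = _design(sub, [metabolite, *covariates])
    X["owob"] = owob
    X["interaction"] = X[metabolite] * owob
    X = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(sub[outcome].astype(float), X).fit()
    return {
        "outcome": outcome, "metabolite": metabolite,
        "p_interaction": float(fit.pvalues["interaction"]),
        "beta_interaction": float(fit.params["interaction"]),
        "n": int(fit.nobs),
    }


def adjusted_regression(df: pd.DataFrame, outcome: str, predictor: str,
                        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                        vif_limit: float = 3.0) -> RegressionResult:
    """OLS of ``outcome`` on ``predictor`` adjusted for the covariates.

    Complete-case; returns the predictor's beta, SE, two-sided p, model R²,
    95 % CI, and the VIF of every right-hand-side column (flag raised when
    any reaches ``vif_limit``).
    """
    cols = [outcome, predictor, *covariates]
    sub = df[cols].dropna()
    k = 1 + len(covariates)
    if len(sub) <= k + 2:
        raise ValueError(f"too few complete cases (n={len(sub)}) for {k} predictors")
    X = _design(sub, [predictor, *covariates])
    Xc = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(sub[outcome].astype(float), Xc).fit()
    vifs = {
        col: float(variance_inflation_factor(Xc.to_numpy(), i))
        for i, col in enumerate(Xc.columns) if col != "const"
    }
    ci = fit.conf_int().loc[predictor]
    return RegressionResult(
        outcome=outcome, predictor=predictor, covariates=tuple(covariates),
        beta=float(fit.params[predictor]), se=float(fit.bse[predictor]),
        p=float(fit.pvalues[predictor]), r2=float(fit.rsquared),
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        vif=vifs, vif_flag=bool(max(vifs.values()) >= vif_limit),
        n=int(fit.nobs),
    )


def run_table_suite(df: pd.DataFrame, alpha: float = 0.05,
                    vif_limit: float = 3.0) -> AnalysisReport:
    """Run the full analysis over a cohort table carrying the derived panel.

    Stages: metabolite comparisons across clinical strata, correlation
    table, diplotype-group tests, BMI-interaction scan, and BMI-stratified
    covariate-adjusted regressions of the bone Z-scores on each metabolite.
    """
    if df.empty:
        raise ValueError("cannot analyze an empty cohort")
    missing = {"bmi_category", "diplotype"} - set(df.columns)
    if missing:
        raise ValueError(f"derived panel missing: run derive first ({missing})")

    groupings = {
        "sex": df.get("sex"),
        "season": df.get("season"),
        "pubertal": df.get("pubertal"),
        "bmi_group": np.where(df["bmi_category"].isna(), None,
                              np.where(df["bmi_category"] == "normal",
                                       "normal", "overweight_obese")),
        "dri_ca": df.get("dri_ca_met"),
        "dri_vitd": df.get("dri_vitd_met"),
        "regular_activity": df.get("regular_activity"),
    }
    comp_rows = []
    for gname, gvals in groupings.items():
        if gvals is None:
            continue
        for met in METABOLITE_COLUMNS:
            if met not in df.columns:
                continue
            try:
                res = compare_two_groups(df[met], gvals, met, gname, alpha)
            except ValueError:
                continue
            comp_rows.append({
                "grouping": res.grouping, "variable": res.variable,
                "test": res.test, "statistic": res.statistic, "p": res.p,
                "ln_transformed": res.transformed, "n": res.n,
                **{f"group_{i+1}": s
                   for i, s in enumerate(res.group_summaries.values())},
            })
    comparisons = pd.DataFrame(comp_rows)

    factor_cols = ["age_years", "bmi_z", "vitd_intake_iu_day",
                   "ca_intake_mg_day", "daylight_hours_week", "ca_mg_dl",
                   "p_mg_dl", "alp_iu_l", "ipth_pg_ml"]
    transform = {c: True for c in ("vitd_intake_iu_day", "ca_intake_mg_day",
                                   "daylight_hours_week", "ipth_pg_ml",
                                   "total_25ohd_ng_ml", "spe_bioa_ng_ml",
                                   "con_bioa_ng_ml", "spe_free_pg_ml",
                                   "con_free_pg_ml", "measured_free_pg_ml",
                                   "d24_25ohd3_ng_ml")}
    correlations = correlation_table(
        df, [c for c in factor_cols if c in df.columns],
        [m for m in METABOLITE_COLUMNS if m in df.columns], transform)

    iso_rows = []
    for met in METABOLITE_COLUMNS:
        if met not in df.columns:
            continue
        try:
            iso = compare_isoform_groups(df[met], df["diplotype"], met, alpha)
        except ValueError:
            continue
        iso_rows.append({
            "variable": met, "kw_statistic": iso.kw_statistic,
            "kw_p": iso.kw_p, "threshold": iso.threshold,
            "n_significant_pairs": int(iso.pairwise["significant"].sum()),
            "n": iso.n,
        })
    isoforms = pd.DataFrame(iso_rows)

    inter_rows = []
    for outcome in BONE_Z_COLUMNS:
        if outcome not in df.columns:
            continue
        for met in METABOLITE_COLUMNS:
            if met not in df.columns:
                continue
            try:
                inter_rows.append(interaction_scan(df, outcome, met))
            except (ValueError, KeyError):
                continue
    interactions = pd.DataFrame(inter_rows)

    reg_rows = []
    strata = {
        "normal": df["bmi_category"] == "normal",
        "overweight_obese": df["bmi_category"].isin(["overweight", "obese"]),
    }
    for stratum, mask in strata.items():
        sub = df[mask]
        for outcome in BONE_Z_COLUMNS:
            if outcome not in sub.columns:
                continue
            for met in METABOLITE_COLUMNS:
                if met not in sub.columns:
                    continue
                try:
                    r = adjusted_regression(sub, outcome, met,
                                            vif_limit=vif_limit)
                except ValueError:
                    continue
                reg_rows.append({
                    "stratum": stratum, "outcome": r.outcome,
                    "predictor": r.predictor, "beta": r.beta, "se": r.se,
                    "p": r.p, "r2": r.r2, "ci_low": r.ci_low,
                    "ci_high": r.ci_high, "max_vif": max(r.vif.values()),
                    "vif_flag": r.vif_flag, "n": r.n,
                })
    regressions = pd.DataFrame(reg_rows)

    return AnalysisReport(comparisons, correlations, isoforms,
                          interactions, regressions, n_total=len(df))
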