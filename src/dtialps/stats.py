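"""Cohort statistics: paired tests, ANCOVA, ICC, regression battery.

Implements the statistical workflow used for the stroke cohort: paired
interhemispheric comparison, covariate-adjusted group comparisons of the
interhemispheric ratios, agreement between observers, normality and
collinearity checks, and univariable plus stepwise multivariable linear
regression of the ipsilateral index on clinical factors. Model fitting
is delegated to statsmodels / scipy; this module owns the report
assembly and the stepwise and ICC logic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .core import DegenerateInputError, InvalidParameterError

ALPHA = 0.05
P_ENTER = 0.05
P_REMOVE = 0.10

#: candidate predictors of the ipsilateral index, as cohort-table columns
CANDIDATE_PREDICTORS = (
    "age", "sex_code", "infarct_volume_cm3", "infarct_adc", "infarct_fa",
    "hemorrhage_code", "time_since_onset_days",
)


# ---------------------------------------------------------------------------
# elementary tests


def paired_t(x, y) -> tuple[float, int, float]:
    """Paired t-test on differences y - x; returns (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise DegenerateInputError("need paired samples of equal length >= 2")
    d = y - x
    if np.allclose(d.var(ddof=1), 0):
        raise DegenerateInputError("zero variance of paired differences")
    res = sps.ttest_rel(y, x)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def ks_normality(x) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against N(sample mean, sample SD)."""
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise DegenerateInputError("need at least 5 observations")
    res = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return float(res.statistic), float(res.pvalue)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor (intercept added internally)."""
    X = pd.DataFrame(design).astype(float)
    if X.shape[1] < 2 or X.shape[0] <= X.shape[1]:
        raise DegenerateInputError("need n > p >= 2 predictors")
    Xc = sm.add_constant(X, has_constant="add")
    with np.errstate(divide="ignore"):
        vals = [variance_inflation_factor(Xc.values, i + 1)
                for i in range(X.shape[1])]
    return pd.Series(vals, index=X.columns, name="vif")


# ---------------------------------------------------------------------------
# ANCOVA


@dataclass
class AncovaResult:
    """Covariate-adjusted two-group comparison."""

    groups: tuple[str, str]
    adjusted_means: dict
    difference: float            # adjusted mean of groups[1] minus groups[0]
    ci: tuple[float, float]
    p_value: float
    n: dict


def ancova_adjusted(outcome, group, age, sex_code) -> AncovaResult:
    """Linear model ``outcome ~ group + age + sex``.

    Reports covariate-adjusted marginal group means evaluated at the
    pooled covariate averages, and the adjusted difference (second group
    minus first, groups in sorted label order) with its 95% CI and p.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group)
    age = np.asarray(age, dtype=float)
    sex_code = np.asarray(sex_code, dtype=float)
    levels = sorted(pd.unique(g))
    if len(levels) != 2:
        raise DegenerateInputError("ANCOVA here expects exactly two groups")
    ind = (g == levels[1]).astype(float)
    X = sm.add_constant(np.column_stack([ind, age, sex_code]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateInputError("collinear ANCOVA design")
    fit = sm.OLS(y, X).fit()
    base = fit.params[0] + fit.params[2] * age.mean() + fit.params[3] * sex_code.mean()
    ci = fit.conf_int(alpha=ALPHA)[1]
    return AncovaResult(
        groups=(str(levels[0]), str(levels[1])),
        adjusted_means={str(levels[0]): float(base),
                        str(levels[1]): float(base + fit.params[1])},
        difference=float(fit.params[1]),
        ci=(float(ci[0]), float(ci[1])),
        p_value=float(fit.pvalues[1]),
        n={str(lv): int(np.sum(g == lv)) for lv in levels},
    )


# ---------------------------------------------------------------------------
# intraclass correlation


@dataclass
class ICCResult:
    """Single-measure absolute-agreement ICC from a two-way random model."""

    icc: float
    ci: tuple[float, float]
    var_subjects: float
    var_raters: float
    var_error: float


def icc_two_way_random_absolute(ratings, alpha: float = ALPHA) -> ICCResult:
    """ICC(A,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a subjects x raters matrix with no missing cells. The
    point estimate comes from the classical mean-square decomposition;
    the confidence interval uses the F-distribution approximation with
    Satterthwaite degrees of freedom.
    """
    M = np.asarray(ratings, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2 or M.shape[0] < 5:
        raise DegenerateInputError("need >= 5 subjects and >= 2 raters")
    if np.isnan(M).any():
        raise DegenerateInputError("missing cells are not supported")
    n, k = M.shape
    grand = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((M - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    if np.allclose([msr, msc, mse], 0):
        raise DegenerateInputError("constant ratings: variance undefined")

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a):
        v = ((a * msc + b * mse) ** 2
             / ((a * msc) ** 2 / (k - 1)
                + (b * mse) ** 2 / ((n - 1) * (k - 1))))
        f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
        denom = k * msc + (k * n - k - n) * mse
        lower = n * (msr - f1 * mse) / (f1 * denom + n * msr)
        upper = n * (f2 * msr - mse) / (denom + n * f2 * msr)
    else:
        lower = upper = 1.0
    return ICCResult(
        icc=float(icc),
        ci=(float(lower), float(upper)),
        var_subjects=float((msr - mse) / k),
        var_raters=float((msc - mse) / n),
        var_error=float(mse),
    )


# ---------------------------------------------------------------------------
# regression


@dataclass
class RegressionRow:
    """One predictor's coefficients in a linear regression."""

    predictor: str
    B: float                 # unstandardized coefficient
    SE: float
    beta: float              # standardized coefficient
    p_value: float
    in_model: bool = True


def _std_beta(B: float, x: np.ndarray, y: np.ndarray) -> float:
    return float(B * x.std(ddof=1) / y.std(ddof=1))


def ols_univariable(outcome, predictor, name: str = "x") -> RegressionRow:
    """Simple linear regression; beta equals the Pearson correlation."""
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if x.size < 3:
        raise DegenerateInputError("need at least 3 observations")
    if np.allclose(x.var(ddof=1), 0):
        raise DegenerateInputError("predictor has zero variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionRow(
        predictor=name,
        B=float(fit.params[1]),
        SE=float(fit.bse[1]),
        beta=_std_beta(fit.params[1], x, y),
        p_value=float(fit.pvalues[1]),
    )


def stepwise_ols(
    outcome,
    candidates: pd.DataFrame,
    p_enter: float = P_ENTER,
    p_remove: float = P_REMOVE,
    max_iter: int = 100,
) -> list[RegressionRow]:
    """Forward-entry / backward-removal stepwise linear regression.

    At each step the candidate with the smallest p-value below
    ``p_enter`` joins the model; any included predictor whose p-value
    rises above ``p_remove`` is dropped. Returns the retained
    predictors' coefficients (possibly an empty list).
    """
    y = np.asarray(outcome, dtype=float)
    X = pd.DataFrame(candidates).astype(float)
    included: list[str] = []
    for _ in range(max_iter):
        changed = False
        # forward step
        excluded = [c for c in X.columns if c not in included]
        best_p, best_c = np.inf, None
        for c in excluded:
            cols = included + [c]
            design = sm.add_constant(X[cols].values)
            if np.linalg.matrix_rank(design) < design.shape[1]:
                continue
            fit = sm.OLS(y, design).fit()
            p = fit.pvalues[-1]
            if p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p < p_enter:
            included.append(best_c)
            changed = True
        # backward step
        while included:
            fit = sm.OLS(y, sm.add_constant(X[included].values)).fit()
            pvals = pd.Series(fit.pvalues[1:], index=included)
            worst = pvals.idxmax()
            if pvals[worst] > p_remove:
                included.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break
    if not included:
        return []
    fit = sm.OLS(y, sm.add_constant(X[included].values)).fit()
    return [
        RegressionRow(
            predictor=c,
            B=float(fit.params[i + 1]),
            SE=float(fit.bse[i + 1]),
            beta=_std_beta(fit.params[i + 1], X[c].values, y),
            p_value=float(fit.pvalues[i + 1]),
        )
        for i, c in enumerate(included)
    ]


# ---------------------------------------------------------------------------
# report generation


@dataclass
class CohortReport:
    """Analogs of the study's four result tables plus a JSON view."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    notes: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        def df_dict(df):
            return None if df is None else df.replace({np.nan: None}).to_dict(
                orient="index")
        return {
            "table1_descriptives": df_dict(self.table1),
            "table2_ratio_ancova": df_dict(self.table2),
            "table3_stratified": df_dict(self.table3),
            "table4_regression": df_dict(self.table4),
            "notes": list(self.notes),
        }


def _code_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    out = cohort.copy()
    out["sex_code"] = (out["sex"] == "man").astype(float)
    if "hemorrhage" in out:
        out["hemorrhage_code"] = out["hemorrhage"].astype(float)
    return out


def _mean_sd(s: pd.Series) -> str:
    s = s.dropna()
    if s.empty:
        return "n/a"
    return f"{s.mean():.3f} ± {s.std(ddof=1):.3f}"


def _descriptives(cohort: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for grp in ("patient", "control"):
        sub = cohort[cohort["group"] == grp]
        rows[grp] = {
            "n": len(sub),
            "age": _mean_sd(sub["age"]),
            "men": int((sub["sex"] == "man").sum()),
            "women": int((sub["sex"] == "woman").sum()),
            "right_infarct": int((sub.get("infarct_side") == "right").sum()),
            "left_infarct": int((sub.get("infarct_side") == "left").sum()),
            "hemorrhage": int(sub.get("hemorrhage", pd.Series(dtype=object))
                              .eq(True).sum()),
            "infarct_volume_cm3": _mean_sd(sub.get(
                "infarct_volume_cm3", pd.Series(dtype=float))),
            "infarct_adc": _mean_sd(sub.get("infarct_adc",
                                            pd.Series(dtype=float))),
            "infarct_fa": _mean_sd(sub.get("infarct_fa",
                                           pd.Series(dtype=float))),
            "time_since_onset_days": _mean_sd(sub.get(
                "time_since_onset_days", pd.Series(dtype=float))),
            "alps_ipsi": _mean_sd(sub.get("alps_ipsi", pd.Series(dtype=float))),
            "alps_contra": _mean_sd(sub.get("alps_contra",
                                            pd.Series(dtype=float))),
        }
    return pd.DataFrame(rows).T


def _ratio_ancova_table(df: pd.DataFrame, notes: list) -> pd.DataFrame:
    rows = {}
    controls = df[df["group"] == "control"]
    for ratio_col, side in (("ratio_rl", "right"), ("ratio_lr", "left")):
        pats = df[(df["group"] == "patient") & (df["infarct_side"] == side)]
        key = f"{ratio_col}_{side}_infarct_vs_control"
        if pats.empty or controls.empty:
            rows[key] = {"n_patient": len(pats), "n_control": len(controls)}
            notes.append(f"{key}: empty stratum, ANCOVA skipped")
            continue
        both = pd.concat([pats, controls])
        rows[key] = {
            "n_patient": len(pats),
            "n_control": len(controls),
            "patient_mean_sd": _mean_sd(pats[ratio_col]),
            "control_mean_sd": _mean_sd(controls[ratio_col]),
        }
        try:
            res = ancova_adjusted(both[ratio_col], both["group"],
                                  both["age"], both["sex_code"])
        except DegenerateInputError as exc:
            notes.append(f"{key}: ANCOVA skipped ({exc})")
            continue
        rows[key].update(
            adjusted_difference=res.difference,
            ci_low=res.ci[0], ci_high=res.ci[1], p_value=res.p_value,
        )
    return pd.DataFrame(rows).T


def _stratified_table(pats: pd.DataFrame, notes: list,
                      vol_split: float = 20.0,
                      time_split: float = 14.0) -> pd.DataFrame:
    rows = {}
    strata = {
        f"volume_le_{vol_split:g}": pats["infarct_volume_cm3"] <= vol_split,
        f"volume_gt_{vol_split:g}": pats["infarct_volume_cm3"] > vol_split,
        f"time_le_{time_split:g}": pats["time_since_onset_days"] <= time_split,
        f"time_gt_{time_split:g}": pats["time_since_onset_days"] > time_split,
    }
    for key, mask in strata.items():
        sub = pats[mask]
        rows[key] = {
            "n": len(sub),
            "alps_ipsi_mean": sub["alps_ipsi"].mean() if len(sub) else np.nan,
            "alps_ipsi_sd": (sub["alps_ipsi"].std(ddof=1)
                             if len(sub) > 1 else np.nan),
        }
        if len(sub) == 0:
            notes.append(f"{key}: empty stratum")
    for factor, prefix in (("infarct_volume_cm3", "volume"),
                           ("time_since_onset_days", "time")):
        split = vol_split if prefix == "volume" else time_split
        grp = np.where(pats[factor] <= split, "a_low", "b_high")
        if len(set(grp)) == 2:
            try:
                res = ancova_adjusted(pats["alps_ipsi"], grp, pats["age"],
                                      pats["sex_code"])
            except DegenerateInputError as exc:
                notes.append(f"{prefix} strata: ANCOVA skipped ({exc})")
                continue
            for key in (f"{prefix}_le_{split:g}", f"{prefix}_gt_{split:g}"):
                rows[key].update({
                    "adjusted_difference": res.difference,
                    "ci_low": res.ci[0], "ci_high": res.ci[1],
                    "p_value": res.p_value,
                })
    return pd.DataFrame(rows).T


def _regression_table(pats: pd.DataFrame, notes: list,
                      p_enter: float, p_remove: float) -> pd.DataFrame:
    y = pats["alps_ipsi"]
    rows = {}
    usable = []
    for name in CANDIDATE_PREDICTORS:
        x = pats[name].astype(float)
        try:
            row = ols_univariable(y, x, name=name)
        except DegenerateInputError:
            notes.append(f"univariable {name}: degenerate predictor")
            continue
        usable.append(name)
        rows[name] = {"B": row.B, "SE": row.SE, "beta": row.beta,
                      "p_value": row.p_value, "selected": False}
    selected = stepwise_ols(y, pats[usable], p_enter=p_enter,
                            p_remove=p_remove)
    for row in selected:
        rows[row.predictor].update({
            "selected": True, "B_multivariable": row.B,
            "SE_multivariable": row.SE, "beta_multivariable": row.beta,
            "p_multivariable": row.p_value,
        })
    return pd.DataFrame(rows).T


def make_report(cohort: pd.DataFrame, p_enter: float = P_ENTER,
                p_remove: float = P_REMOVE) -> CohortReport:
    """Assemble the four-table cohort report.

    Expects one row per subject with the cohort-table columns (group,
    covariates, lesion metrics, per-hemisphere indices and ratios).
    Empty strata or degenerate predictors are flagged in ``notes``, not
    fatal; a cohort with no patients yields descriptives and marks the
    patient-only tables not applicable.
    """
    if cohort.empty:
        raise InvalidParameterError("empty cohort table")
    df = _code_columns(cohort)
    notes: list = []
    table1 = _descriptives(df)
    table2 = _ratio_ancova_table(df, notes)
    pats = df[df["group"] == "patient"]
    if pats.empty:
        notes.append("no patients: stratified and regression tables n/a")
        table3 = pd.DataFrame({"status": {"not_applicable": True}})
        table4 = pd.DataFrame({"status": {"not_applicable": True}})
    else:
        table3 = _stratified_table(pats, notes)
        table4 = _regression_table(pats, notes, p_enter, p_remove)
    return CohortReport(table1=table1, table2=table2, table3=table3,
                        table4=table4, notes=notes)
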