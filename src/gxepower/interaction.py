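"""Regression models for the GRS x physical-activity interaction analysis.

Two statsmodels-backed model classes follow the cohort analysis plan:

* :class:`BMIInteractionModel` — ordinary least squares for BMI with GRS,
  activity, their product, and the standard adjustment set (age, age^2,
  sex, study center for multi-center cohorts).  Age is centered before
  squaring; center enters as indicator contrasts and is dropped (with a
  warning) for single-center cohorts.
* :class:`ObesityModel` — logistic regression for obesity (BMI >= 30) vs
  normal weight (18.5 <= BMI < 25); overweight and underweight
  participants are excluded from the contrast.

Helpers implement the stratified per-activity genetic effects, adjusted
least-squares means by GRS x activity group, WHO BMI classification, and
the beta -> body-weight (grams at 1.70 m) conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

MIN_CASES = 50


def classify_bmi(bmi) -> pd.Series:
    """WHO categories on half-open intervals: underweight < 18.5 <= normal
    < 25 <= overweight < 30 <= obese."""
    bins = [-np.inf, 18.5, 25.0, 30.0, np.inf]
    labels = ["underweight", "normal", "overweight", "obese"]
    return pd.Series(
        pd.cut(pd.Series(bmi, dtype="float64"), bins=bins, labels=labels,
               right=False),
        name="bmi_category",
    )


def beta_to_weight(beta: float, height: float = 1.70) -> float:
    """Convert a BMI effect (kg/m^2) to grams of body weight for a person
    of the given height: grams = beta * height^2 * 1000.

    Exact and linear; round the result for display.
    """
    if height <= 0:
        raise ValueError("height must be > 0")
    return beta * height**2 * 1000.0


def _build_design(
    data: pd.DataFrame,
    terms: list[str],
    covariates: tuple[str, ...],
    center_col: str | None,
) -> pd.DataFrame:
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    for t in terms:
        X[t] = data[t].astype(float)
    for cov in covariates:
        if cov == "age":
            age_c = data["age"].astype(float) - data["age"].astype(float).mean()
            X["age_c"] = age_c
            X["age_c_sq"] = age_c**2
        else:
            X[cov] = data[cov].astype(float)
    if center_col is not None:
        levels = pd.unique(data[center_col])
        if len(levels) < 2:
            warnings.warn(
                f"single level in {center_col!r}: center adjustment dropped "
                "(multi-center adjustment only)", stacklevel=3,
            )
        else:
            dummies = pd.get_dummies(data[center_col], prefix="center",
                                     drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
    # drop linearly dependent columns (rank deficiency), keeping earlier terms
    arr = X.to_numpy(dtype=float)
    keep, rank = [], 0
    for j in range(arr.shape[1]):
        if np.linalg.matrix_rank(arr[:, keep + [j]]) > rank:
            keep.append(j)
            rank += 1
        else:
            warnings.warn(f"dropping collinear term {X.columns[j]!r}",
                          stacklevel=3)
    return X.iloc[:, keep]


@dataclass
class FitResult:
    """Per-term estimates from one fitted model."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    nobs: int
    scale_label: str  # "kg/m^2" or "log-odds"
    _sm_results: object = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if (self.bse <= 0).any():
            raise ValueError("standard errors must be positive")

    def term(self, name: str) -> tuple[float, float, float]:
        """(estimate, SE, two-sided p) for one model term."""
        return (float(self.params[name]), float(self.bse[name]),
                float(self.pvalues[name]))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame({
            "lower": self.params - z * self.bse,
            "upper": self.params + z * self.bse,
        })

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        if self.scale_label != "log-odds":
            raise ValueError("odds ratios only defined for logistic fits")
        ci = self.conf_int(alpha)
        return pd.DataFrame({
            "OR": np.exp(self.params),
            "lower": np.exp(ci["lower"]),
            "upper": np.exp(ci["upper"]),
            "p": self.pvalues,
        })

    def summary(self):
        return self._sm_results.summary()


class BMIInteractionModel:
    """OLS model of BMI on GRS, activity and their interaction.

    Parameters
    ----------
    data : DataFrame with columns for the GRS, activity, BMI and the
        adjustment covariates.
    grs, activity, outcome : column names (activity may be the binary 0/1
        variable or the CPAI level entered as a 1-4 trend).
    covariates : adjustment set; "age" expands to centered age + age^2.
    center : column of study-center labels, or None for single-center.
    interaction : include the GRS x activity product term (the marginal
        terms are always included).
    """

    def __init__(self, data: pd.DataFrame, grs: str = "grs",
                 activity: str = "activity_binary", outcome: str = "bmi",
                 covariates: tuple[str, ...] = ("age", "sex"),
                 center: str | None = None, interaction: bool = True,
                 min_cases: int = MIN_CASES):
        cols = [outcome, grs, activity, *covariates]
        if center is not None:
            cols.append(center)
        complete = data[cols].dropna()
        if len(complete) < min_cases:
            raise ValueError(f"need >= {min_cases} complete cases, "
                             f"got {len(complete)}")
        self.data = complete
        self.grs_term, self.activity_term, self.outcome = grs, activity, outcome
        self.interaction_term = f"{grs}:{activity}" if interaction else None
        design_data = complete.copy()
        terms = [grs, activity]
        if interaction:
            design_data[self.interaction_term] = (
                design_data[grs].astype(float) * design_data[activity].astype(float)
            )
            terms.append(self.interaction_term)
        self.exog = _build_design(design_data, terms, covariates, center)
        self.endog = complete[outcome].astype(float)

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "BMIInteractionModel":
        return cls(cohort.data, **kwargs)

    def fit(self) -> FitResult:
        res = sm.OLS(self.endog, self.exog).fit()
        return FitResult(params=res.params, bse=res.bse, pvalues=res.pvalues,
                         nobs=int(res.nobs), scale_label="kg/m^2",
                         _sm_results=res)


class ObesityModel:
    """Logistic model of obesity (vs normal weight) on the GRS.

    Restricts to the obese / normal-weight contrast (overweight and
    underweight excluded), matching the per-allele odds-ratio analysis.
    """

    def __init__(self, data: pd.DataFrame, grs: str = "grs",
                 outcome: str = "bmi",
                 covariates: tuple[str, ...] = ("age", "sex"),
                 center: str | None = None,
                 extra_terms: tuple[str, ...] = ()):
        cats = classify_bmi(data[outcome])
        keep = cats.isin(["obese", "normal"]).to_numpy()
        cols = [outcome, grs, *extra_terms, *covariates]
        if center is not None:
            cols.append(center)
        subset = data.loc[keep, cols].dropna()
        if len(subset) < MIN_CASES:
            raise ValueError(f"need >= {MIN_CASES} obese/normal cases, "
                             f"got {len(subset)}")
        self.data = subset
        self.endog = (classify_bmi(subset[outcome]) == "obese").astype(float)
        self.exog = _build_design(subset, [grs, *extra_terms], covariates, center)
        self.n_obese = int(self.endog.sum())
        self.n_normal = int((1 - self.endog).sum())

    def fit(self) -> FitResult:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error",
                                      sm.tools.sm_exceptions.PerfectSeparationWarning)
                res = sm.Logit(self.endog, self.exog).fit(disp=0)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as err:
            raise ValueError(
                f"complete separation in logistic fit "
                f"(n_obese={self.n_obese}, n_normal={self.n_normal}): {err}"
            ) from err
        return FitResult(params=res.params, bse=res.bse, pvalues=res.pvalues,
                         nobs=int(res.nobs), scale_label="log-odds",
                         _sm_results=res)


def stratified_effects(data: pd.DataFrame, strata: str = "activity_binary",
                       grs: str = "grs", outcome: str = "bmi",
                       covariates: tuple[str, ...] = ("age", "sex"),
                       center: str | None = None) -> pd.DataFrame:
    """Per-activity-stratum GRS effect on BMI.

    Refits the GRS main-effect model within each level of ``strata`` and,
    for a two-level stratification, appends a ``slope_difference`` row
    (last minus first stratum) approximating the interaction coefficient,
    with SE = sqrt(SE_1^2 + SE_0^2).
    """
    rows = []
    levels = sorted(pd.unique(data[strata].dropna()))
    for level in levels:
        sub = data[data[strata] == level]
        if len(sub.dropna(subset=[grs, outcome])) < MIN_CASES:
            warnings.warn(f"stratum {strata}={level!r} has < {MIN_CASES} "
                          "cases: omitted", stacklevel=2)
            continue
        exog = _build_design(sub.dropna(subset=[grs, outcome, *covariates]),
                             [grs], covariates, center)
        endog = sub.dropna(subset=[grs, outcome, *covariates])[outcome].astype(float)
        res = sm.OLS(endog, exog).fit()
        rows.append({"stratum": level, "n": int(res.nobs),
                     "beta_g": float(res.params[grs]),
                     "se": float(res.bse[grs]),
                     "p": float(res.pvalues[grs])})
    out = pd.DataFrame(rows)
    if len(out) == 2:
        diff = out.iloc[1]["beta_g"] - out.iloc[0]["beta_g"]
        se = float(np.hypot(out.iloc[0]["se"], out.iloc[1]["se"]))
        out = pd.concat([out, pd.DataFrame([{
            "stratum": "difference", "n": int(out["n"].sum()),
            "beta_g": diff, "se": se,
            "p": float(2 * norm.sf(abs(diff / se))),
        }])], ignore_index=True)
    return out


def lsmeans_by_group(data: pd.DataFrame, grs_binary: str, activity_binary: str,
                     covariates: tuple[str, ...] = ("age", "sex"),
                     outcome: str = "bmi", alpha: float = 0.05) -> dict:
    """Covariate-adjusted least-squares mean BMI per GRS x activity cell.

    Fits a cell-means model (one indicator per 2x2 cell, no intercept)
    with mean-centered covariates, so each cell coefficient is the
    predicted outcome at average covariate values.  Returns the per-cell
    means with CIs and the high-minus-low GRS difference within each
    activity group.
    """
    cols = [outcome, grs_binary, activity_binary, *covariates]
    d = data[cols].dropna().copy()
    cells = []
    X = pd.DataFrame(index=d.index)
    for g in (0, 1):
        for a in (0, 1):
            name = f"g{g}_a{a}"
            ind = ((d[grs_binary] == g) & (d[activity_binary] == a)).astype(float)
            if ind.sum() == 0:
                raise ValueError(f"empty GRS x activity cell (grs={g}, activity={a})")
            X[name] = ind
            cells.append(name)
    for cov in covariates:
        if cov == "age":
            age_c = d["age"] - d["age"].mean()
            X["age_c"], X["age_c_sq"] = age_c, age_c**2 - (age_c**2).mean()
        else:
            X[cov] = d[cov] - d[cov].mean()
    res = sm.OLS(d[outcome].astype(float), X).fit()
    z = norm.ppf(1 - alpha / 2)
    means = pd.DataFrame({
        "mean": res.params[cells],
        "se": res.bse[cells],
        "lower": res.params[cells] - z * res.bse[cells],
        "upper": res.params[cells] + z * res.bse[cells],
        "n": [int(X[c].sum()) for c in cells],
    })
    diffs = {}
    cov = res.cov_params()
    for a in (0, 1):
        hi, lo = f"g1_a{a}", f"g0_a{a}"
        est = res.params[hi] - res.params[lo]
        se = float(np.sqrt(cov.loc[hi, hi] + cov.loc[lo, lo] - 2 * cov.loc[hi, lo]))
        diffs[f"activity={a}"] = {"difference": float(est), "se": se,
                                  "lower": float(est - z * se),
                                  "upper": float(est + z * se)}
    return {"cell_means": means, "grs_differences": diffs}
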