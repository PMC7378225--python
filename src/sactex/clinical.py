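"""Clinical/imaging comparison arms: univariable screening and logistic models.

Continuous variables are screened with a normality check (Lilliefors-
corrected Kolmogorov-Smirnov, approximate) followed by a two-sample t test
between the expansion groups (Welch by default); categorical variables with
a chi-square test, falling back to Fisher's exact test on 2x2 tables with
any expected cell below 5.  Variables with P < 0.1, plus any forced for
clinical importance, enter a binary logistic regression whose predicted
probabilities feed the ROC analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .evaluation import ROCResult, optimal_cutoff, roc_auc

__all__ = [
    "ScreeningResult",
    "LogisticFit",
    "screen_univariable",
    "fit_logistic",
    "model_probability_roc",
    "CLINICAL_VARIABLES",
    "IMAGING_VARIABLES",
]

# variable -> kind, matching the cohort manifest columns
CLINICAL_VARIABLES = {
    "age_yr": "continuous",
    "sex_male": "categorical",
    "hypertension": "categorical",
    "hypertension_duration_yr": "continuous",
    "systolic_mmHg": "continuous",
    "diastolic_mmHg": "continuous",
    "heart_disease": "categorical",
    "diabetes": "categorical",
    "smoking_history": "categorical",
    "current_smoking": "categorical",
    "smoking_duration_yr": "continuous",
    "alcohol_history": "categorical",
    "current_drinking": "categorical",
    "total_cholesterol": "continuous",
    "triglyceride": "continuous",
    "hdl_c": "continuous",
    "ldl_c": "continuous",
}

IMAGING_VARIABLES = {
    "max_diameter_mm": "continuous",
    "endoleak": "categorical",
    "V1": "continuous",
    "V2": "continuous",
}

#: variables forced into the regression regardless of screening P value
DEFAULT_FORCED = ("endoleak", "max_diameter_mm")


@dataclass(frozen=True)
class ScreeningResult:
    variable: str
    test: str
    p_value: float
    selected: bool
    normal_p: float | None = None  # normality-test P for continuous variables
    note: str = ""


@dataclass
class LogisticFit:
    variables: list[str]
    params: pd.Series
    odds_ratios: pd.Series
    p_values: pd.Series
    probabilities: np.ndarray
    converged: bool
    diagnostics: str = ""


def _lilliefors_p(x: np.ndarray) -> float:
    from statsmodels.stats.diagnostic import lilliefors

    if x.size < 4 or np.std(x) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = lilliefors(x, dist="norm")
    return float(p)


def screen_univariable(
    cohort: pd.DataFrame,
    variables: dict[str, str],
    label_column: str = "label",
    positive: str = "expansion",
    alpha: float = 0.1,
    forced: tuple[str, ...] = (),
    equal_var: bool = False,
) -> list[ScreeningResult]:
    """Univariable group comparison for each variable, flagged at P < ``alpha``.

    ``variables`` maps column names to "continuous" or "categorical".
    Zero-variance variables are flagged with a NaN P value, never selected
    (unless forced), and do not raise.
    """
    y = cohort[label_column] == positive
    results = []
    for var, kind in variables.items():
        x = cohort[var]
        note = ""
        normal_p = None
        if x.nunique(dropna=True) <= 1:
            results.append(
                ScreeningResult(var, "none", float("nan"), var in forced,
                                note="zero variance")
            )
            continue
        if kind == "continuous":
            a = x[y].to_numpy(dtype=float)
            b = x[~y].to_numpy(dtype=float)
            normal_p = min(filter(np.isfinite, [_lilliefors_p(a), _lilliefors_p(b)]),
                           default=float("nan"))
            if np.isfinite(normal_p) and normal_p < 0.05:
                note = "normality rejected (approximate KS); t test applied anyway"
            test = "welch_t" if not equal_var else "pooled_t"
            _, p = stats.ttest_ind(a, b, equal_var=equal_var)
        elif kind == "categorical":
            table = pd.crosstab(x, y).to_numpy()
            expected = stats.contingency.expected_freq(table)
            if table.shape == (2, 2) and (expected < 5).any():
                test = "fisher_exact"
                _, p = stats.fisher_exact(table)
            else:
                test = "chi_square"
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = stats.chi2_contingency(table, correction=False).pvalue
        else:
            raise ValueError(f"unknown variable kind {kind!r} for {var!r}")
        p = float(p)
        selected = (np.isfinite(p) and p < alpha) or var in forced
        results.append(ScreeningResult(var, test, p, selected, normal_p, note))
    return results


def _design_matrix(cohort: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    cols = {}
    for var in variables:
        x = cohort[var]
        if var == "endoleak" or x.dtype == object:
            dummies = pd.get_dummies(x, prefix=var, dtype=float)
            ref = f"{var}_none" if f"{var}_none" in dummies else dummies.columns[0]
            for c in dummies.columns:
                if c != ref:  # reference level carries OR 1.0 implicitly
                    cols[c] = dummies[c]
        else:
            cols[var] = x.astype(float)
    return pd.DataFrame(cols, index=cohort.index)


def fit_logistic(
    cohort: pd.DataFrame,
    variables: list[str],
    label_column: str = "label",
    positive: str = "expansion",
) -> LogisticFit:
    """Maximum-likelihood binary logistic regression (IRLS via statsmodels).

    Categorical variables are dummy-coded with "none" (or the first level)
    as the reference.  A constant outcome or a constant predictor column
    raises with an explicit diagnostic; complete or quasi-complete
    separation is reported in ``diagnostics`` (with a warning), since the
    predicted probabilities remain usable for ROC analysis even when the
    coefficients diverge.
    """
    y = (cohort[label_column] == positive).astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("separation diagnostic: all outcomes identical; "
                         "logistic regression is undefined")
    X = _design_matrix(cohort, variables)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        raise ValueError(f"separation diagnostic: constant predictor columns {constant}")
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    names = ["const"] + list(X.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception:
            # Newton's Hessian goes singular under (quasi-)separation;
            # BFGS still yields usable predicted probabilities
            try:
                res = sm.Logit(y, design).fit(disp=0, method="bfgs", maxiter=500)
            except Exception as exc:
                raise ValueError(f"logistic regression failed: {exc}") from exc
    params = pd.Series(res.params, index=names)
    converged = bool(res.mle_retvals.get("converged", True))
    diagnostics = ""
    if not np.isfinite(params).all() or np.abs(params).max() > 50:
        diagnostics = (
            "separation diagnostic: diverging coefficients suggest complete "
            "or quasi-complete separation; odds ratios are unreliable"
        )
        warnings.warn(diagnostics, UserWarning, stacklevel=2)
    elif not converged:
        diagnostics = "IRLS did not converge in 200 iterations"
    return LogisticFit(
        variables=list(variables),
        params=params,
        odds_ratios=np.exp(params),
        p_values=pd.Series(res.pvalues, index=names),
        probabilities=np.asarray(res.predict(design)),
        converged=converged,
        diagnostics=diagnostics,
    )


def model_probability_roc(
    cohort: pd.DataFrame,
    arms: dict[str, list[str]],
    label_column: str = "label",
    positive: str = "expansion",
) -> dict[str, ROCResult]:
    """Fit one logistic model per arm and return its prediction-probability ROC."""
    y = (cohort[label_column] == positive).astype(int).to_numpy()
    out = {}
    for name, variables in arms.items():
        fit = fit_logistic(cohort, variables, label_column, positive)
        out[name] = optimal_cutoff(roc_auc(fit.probabilities, y))
    return out
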