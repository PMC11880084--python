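"""Cohort-level statistics: univariate OLS, correlations, LOOCV-RMSE.

All analyses are complete-case: rows missing the response or any involved
predictor are dropped (and counted), never imputed — matching how a study
with per-parameter echo completeness would analyze its table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.diagnostic import het_breuschpagan

from .errors import DegenerateDesignError, InsufficientDataError

__all__ = [
    "RegressionResult",
    "PredictionComparison",
    "fit_univariate",
    "pearson_r",
    "loocv_rmse",
    "loocv_rmse_closed_form",
    "compare_predictors",
]


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression summary with residual diagnostics.

    ``diagnostics`` holds p-values of a residual normality test
    (Shapiro-Wilk) and a homoscedasticity test (Breusch-Pagan); they are
    reported, never used to reject a fit automatically.
    """

    response: str
    predictor: str
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    p_value: float
    r: float
    n_used: int
    n_dropped: int
    diagnostics: dict

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictor": self.predictor,
            "slope": self.slope,
            "intercept": self.intercept,
            "ci95": [self.ci_low, self.ci_high],
            "p_value": self.p_value,
            "r": self.r,
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
            "diagnostics": self.diagnostics,
        }


@dataclass(frozen=True)
class PredictionComparison:
    """LOOCV-RMSE of several univariate predictors on a shared complete-case subset."""

    response: str
    rmse: dict[str, float]
    n_used: int

    @property
    def ranking(self) -> list[str]:
        """Predictors from best (lowest RMSE) to worst."""
        return sorted(self.rmse, key=self.rmse.get)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "rmse_pct": self.rmse,
            "ranking": self.ranking,
            "n_used": self.n_used,
        }


def _complete_cases(cohort: pd.DataFrame, columns: list[str]) -> tuple[pd.DataFrame, int]:
    sub = cohort[columns].dropna()
    return sub, len(cohort) - len(sub)


def fit_univariate(cohort: pd.DataFrame, response: str, predictor: str) -> RegressionResult:
    """OLS of ``response`` on ``predictor`` with 95% CI, p-value and diagnostics.

    The CI uses the t distribution with n−2 degrees of freedom; the
    two-sided p tests slope = 0.
    """
    sub, dropped = _complete_cases(cohort, [response, predictor])
    if len(sub) < 3:
        raise InsufficientDataError(f"need >= 3 complete cases, got {len(sub)}")
    x = sub[predictor].to_numpy(float)
    y = sub[response].to_numpy(float)
    if np.ptp(x) == 0:
        raise DegenerateDesignError(f"predictor {predictor!r} is constant")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    r = float(np.corrcoef(x, y)[0, 1]) if np.ptp(y) > 0 else 0.0
    diagnostics: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            diagnostics["shapiro_p"] = float(sps.shapiro(fit.resid).pvalue)
        except Exception:
            diagnostics["shapiro_p"] = float("nan")
        try:
            diagnostics["breusch_pagan_p"] = float(het_breuschpagan(fit.resid, X)[3])
        except Exception:
            diagnostics["breusch_pagan_p"] = float("nan")
    return RegressionResult(
        response=response,
        predictor=predictor,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        p_value=float(fit.pvalues[1]),
        r=r,
        n_used=len(sub),
        n_dropped=dropped,
        diagnostics=diagnostics,
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDesignError("zero variance in one of the variables")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def loocv_rmse(cohort: pd.DataFrame, response: str, predictor: str) -> float:
    """Leave-one-out cross-validated RMSE of a univariate linear predictor.

    Each complete case is predicted from an OLS fit to all other complete
    cases (explicit refits; the hat-matrix shortcut is kept separately in
    :func:`loocv_rmse_closed_form` as an independent cross-check).
    """
    sub, _ = _complete_cases(cohort, [response, predictor])
    if len(sub) < 4:
        raise InsufficientDataError(f"need >= 4 complete cases for LOOCV, got {len(sub)}")
    x = sub[predictor].to_numpy(float)
    y = sub[response].to_numpy(float)
    n = len(x)
    errors = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        xi, yi = x[keep], y[keep]
        if np.ptp(xi) == 0:
            raise DegenerateDesignError(
                f"predictor {predictor!r} constant after leaving out case {sub.index[i]}"
            )
        slope, intercept = np.polyfit(xi, yi, 1)
        errors[i] = y[i] - (intercept + slope * x[i])
    return float(np.sqrt(np.mean(errors**2)))


def loocv_rmse_closed_form(cohort: pd.DataFrame, response: str, predictor: str) -> float:
    """Hat-matrix (PRESS) form of the LOOCV-RMSE: sqrt(mean((e_i/(1-h_ii))^2))."""
    sub, _ = _complete_cases(cohort, [response, predictor])
    if len(sub) < 4:
        raise InsufficientDataError(f"need >= 4 complete cases for LOOCV, got {len(sub)}")
    x = sub[predictor].to_numpy(float)
    y = sub[response].to_numpy(float)
    if np.ptp(x) == 0:
        raise DegenerateDesignError(f"predictor {predictor!r} is constant")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    h = (X * (X @ np.linalg.inv(X.T @ X))).sum(axis=1)
    return float(np.sqrt(np.mean((fit.resid / (1.0 - h)) ** 2)))


def compare_predictors(
    cohort: pd.DataFrame, response: str, predictors: list[str]
) -> PredictionComparison:
    """LOOCV-RMSE of each predictor on the rows complete for *all* columns.

    Restricting every predictor to the shared complete-case subset keeps
    the RMSEs comparable.
    """
    if len(predictors) < 2:
        raise InsufficientDataError("need >= 2 predictors to compare")
    sub, _ = _complete_cases(cohort, [response, *predictors])
    rmse = {pred: loocv_rmse(sub, response, pred) for pred in predictors}
    return PredictionComparison(response=response, rmse=rmse, n_used=len(sub))
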