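"""Cohort-level statistics: which morphology parameter predicts strength.

The statistical design mirrors the comparison of candidate predictors
of vertebral strength: simple ordinary-least-squares regressions of
the outcome on each morphology parameter (Pearson correlation with a
two-sided t test on r), paired comparison of two predictors via their
absolute regression residuals, paired comparison of two outcomes'
regression slopes on a common predictor via leave-one-out (jackknife)
slope estimates, Bonferroni adjustment for families of paired tests,
and the two-predictor multiple regression of strength on total bone
volume fraction and vertical tissue fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionReport",
    "PairedTestResult",
    "MultipleRegressionReport",
    "fit_simple_regression",
    "compare_predictors_residuals",
    "compare_predictors_slopes",
    "multiple_regression",
    "bonferroni_adjust",
]


@dataclass
class RegressionReport:
    predictor: str
    outcome: str
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    p_value: float
    residuals: np.ndarray
    specimen_ids: np.ndarray


@dataclass
class PairedTestResult:
    mean_difference: float
    t_statistic: float
    df: int
    p_value: float
    note: str = ""


@dataclass
class MultipleRegressionReport:
    outcome: str
    predictors: list
    coefficients: dict
    p_values: dict
    r_squared: float
    simple_r_squared: dict = field(default_factory=dict)
    model: object = None

    def summary(self):
        return self.model.summary()


def _columns(table: pd.DataFrame, *names: str) -> list[np.ndarray]:
    out = []
    for name in names:
        if name not in table.columns:
            raise KeyError(f"column {name!r} not in cohort table")
        col = np.asarray(table[name], float)
        if not np.all(np.isfinite(col)):
            raise ValueError(f"column {name!r} contains missing or non-finite values")
        out.append(col)
    return out


def fit_simple_regression(table: pd.DataFrame, predictor: str, outcome: str) -> RegressionReport:
    """OLS of ``outcome`` on ``predictor`` with Pearson r and its
    two-sided p from the t distribution on n - 2 degrees of freedom."""
    x, y = _columns(table, predictor, outcome)
    if len(x) < 3:
        raise ValueError("simple regression needs n >= 3 specimens")
    if np.var(x) == 0:
        raise ValueError(f"predictor {predictor!r} has zero variance")
    fit = stats.linregress(x, y)
    residuals = y - (fit.intercept + fit.slope * x)
    ids = np.asarray(table["specimen_id"]) if "specimen_id" in table else np.arange(len(x))
    return RegressionReport(
        predictor=predictor,
        outcome=outcome,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        residuals=residuals,
        specimen_ids=ids,
    )


def compare_predictors_residuals(report_a: RegressionReport, report_b: RegressionReport) -> PairedTestResult:
    """Paired two-sided t test on per-specimen |residual_A| - |residual_B|.

    A significantly negative mean difference means predictor A leaves
    smaller absolute residuals, i.e. explains the outcome better.
    """
    if report_a.outcome != report_b.outcome:
        raise ValueError("residual comparison requires the same outcome")
    if len(report_a.residuals) != len(report_b.residuals) or not np.array_equal(
        report_a.specimen_ids, report_b.specimen_ids
    ):
        raise ValueError("residual comparison requires the same specimens in the same order")
    d = np.abs(report_a.residuals) - np.abs(report_b.residuals)
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        return PairedTestResult(mean, 0.0 if mean == 0 else np.inf, n - 1, 1.0 if mean == 0 else 0.0,
                                note="zero variance of paired differences")
    t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(mean, float(t), n - 1, float(p))


def _loo_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = len(x)
    slopes = np.empty(n)
    for i in range(n):
        sel = np.arange(n) != i
        slopes[i] = stats.linregress(x[sel], y[sel]).slope
    return slopes


def compare_predictors_slopes(
    table: pd.DataFrame,
    predictor: str,
    outcome_a: str,
    outcome_b: str,
) -> PairedTestResult:
    """Paired comparison of the regression slopes of two outcomes
    (e.g. intact vs shell-removed stiffness) on a common predictor.

    Pairing is by leave-one-out: dropping specimen i from both
    regressions yields a slope pair, and the jackknife slope
    differences enter a two-sided paired t test.
    """
    x, ya, yb = _columns(table, predictor, outcome_a, outcome_b)
    n = len(x)
    if n < 4:
        raise ValueError("slope comparison needs n >= 4 specimens")
    if np.var(x) == 0:
        raise ValueError(f"predictor {predictor!r} has zero variance")
    sa, sb = _loo_slopes(x, ya), _loo_slopes(x, yb)
    d = sa - sb
    scale = max(np.max(np.abs(sa)), np.max(np.abs(sb)), 1e-300)
    if np.max(np.abs(d)) <= 1e-9 * scale:
        # identical slopes up to floating-point noise
        return PairedTestResult(0.0, 0.0, n - 1, 1.0, note="slope differences at numerical noise level")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        return PairedTestResult(mean, 0.0 if mean == 0 else np.inf, n - 1, 1.0 if mean == 0 else 0.0,
                                note="zero variance of jackknife slope differences")
    t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(mean, float(t), n - 1, float(p))


def multiple_regression(
    table: pd.DataFrame,
    outcome: str,
    predictors=("BV_TV", "vBV_BV"),
) -> MultipleRegressionReport:
    """OLS of the outcome on several predictors with an intercept,
    per-coefficient t tests, total R², and each predictor's simple r²
    for comparison. Rank-deficient designs are rejected."""
    predictors = list(predictors)
    cols = _columns(table, outcome, *predictors)
    y, xs = cols[0], np.column_stack(cols[1:])
    if len(y) < len(predictors) + 2:
        raise ValueError("too few specimens for the requested design")
    std = xs.std(axis=0)
    if np.any(std == 0):
        raise ValueError("a predictor has zero variance")
    cond = np.linalg.cond((xs - xs.mean(axis=0)) / std)
    if cond > 1e8:
        raise ValueError(
            f"predictors are collinear (condition number {cond:.3g}); "
            "drop or combine redundant columns"
        )
    design = sm.add_constant(pd.DataFrame(xs, columns=predictors))
    fit = sm.OLS(y, design).fit()
    simple = {
        p: fit_simple_regression(table, p, outcome).r_squared for p in predictors
    }
    return MultipleRegressionReport(
        outcome=outcome,
        predictors=predictors,
        coefficients={k: float(v) for k, v in fit.params.items()},
        p_values={k: float(v) for k, v in fit.pvalues.items()},
        r_squared=float(fit.rsquared),
        simple_r_squared=simple,
        model=fit,
    )


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, m * p)`` with ``m`` the size of
    the comparison family (defaults to the number of p values)."""
    p = np.atleast_1d(np.asarray(p_values, float))
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("family size m must be at least the number of p values")
    return np.minimum(1.0, m * p)
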