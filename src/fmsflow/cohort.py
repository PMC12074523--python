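"""Cohort-level statistics on the log-scale flowmotion parameters.

VM and HS span orders of magnitude; their base-10 logarithms are close to
normally distributed and are the scale on which all cohort statistics run:
ordinary least squares of log(HS) on log(VM), Pearson correlation, two-sided
t tests for group or before/after comparisons, Shapiro-Wilk normality, and
linear age trends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubjectRecord",
    "RegressionFit",
    "fit_loglinear",
    "pearson_with_p",
    "ttest_two_sided",
    "shapiro_wilk",
    "age_trend",
    "format_p",
]


@dataclass(frozen=True)
class SubjectRecord:
    """One cohort row; VM and HS on the linear scale, logs derived."""

    subject_id: str
    group: str
    sex: str
    age: float
    vm: float
    hs: float

    def __post_init__(self) -> None:
        if not (self.vm > 0 and self.hs > 0):
            raise ValueError(f"subject {self.subject_id}: vm and hs must be positive")
        if self.age < 0:
            raise ValueError(f"subject {self.subject_id}: age must be >= 0")


@dataclass(frozen=True)
class RegressionFit:
    """Simple OLS fit with coefficient standard errors and Pearson r."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    pearson_r: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_se": self.slope_se,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "pearson_r": self.pearson_r,
            "p_value": format_p(self.p_value),
            "n": self.n,
        }


def format_p(p: float) -> float | str:
    """p-values below representable precision are reported as a bound."""
    return "<1e-300" if p < 1e-300 else float(p)


def _log10_column(records: pd.DataFrame, param: str) -> np.ndarray:
    values = np.asarray(records[param], dtype=float)
    if (values <= 0).any():
        raise ValueError(f"{param} contains non-positive values; cannot log-transform")
    return np.log10(values)


def _simple_ols(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    if x.size < 3:
        raise ValueError("at least 3 records required for a regression fit")
    if np.ptp(x) == 0.0:
        raise ValueError("predictor has zero variance; regression is degenerate")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        intercept_se=float(res.intercept_stderr),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def fit_loglinear(records: pd.DataFrame, x_param: str = "vm", y_param: str = "hs") -> RegressionFit:
    """OLS of log10(y_param) on log10(x_param) across subjects.

    This is the calibration fit of the method: across a cohort,
    ``log(HS) = slope * log(VM) + intercept`` with Pearson r quantifying
    how well resting myogenic activity predicts the hypoxic response.
    """
    return _simple_ols(_log10_column(records, x_param), _log10_column(records, y_param))


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("at least 3 observations required")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def ttest_two_sided(a: np.ndarray, b: np.ndarray, paired: bool = False) -> tuple[float, float]:
    """Two-sided t test; paired variant for before/after designs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(a.size, b.size) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires samples of equal length")
        if np.all(a == b):
            return 0.0, 1.0  # zero differences: no effect, by convention
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)


def shapiro_wilk(x: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0.0:
        raise ValueError("Shapiro-Wilk undefined for constant input")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def age_trend(records: pd.DataFrame, param: str = "vm") -> RegressionFit:
    """OLS of log10(param) on age; slope in a.u. per year."""
    if "age" not in records.columns:
        raise ValueError("records have no age column")
    ages = np.asarray(records["age"], dtype=float)
    if np.isnan(ages).any():
        raise ValueError("records contain missing ages")
    return _simple_ols(ages, _log10_column(records, param))
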