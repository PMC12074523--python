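"""Diagnostic classification, ROC threshold selection, discordance rates.

Subjects are classified into three adaptation classes -- impaired,
acceptable, optimal -- by two log10 cut-offs on VM or HS.  The lower VM
cut-off is calibrated against the hypoxic response itself: taking
``log(HS) >= 1`` as a proper response, a ROC curve of VM as a predictor
gives the AUC and the Youden-optimal operating point.  Because VM only
predicts HS through a noisy log-linear relation, some subjects are
discordant; :func:`misclassification_rates` quantifies the false-negative
(low VM, proper HS response) and false-positive fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "IMPAIRED",
    "ACCEPTABLE",
    "OPTIMAL",
    "CLASS_LABELS",
    "ThresholdScheme",
    "ROCCurve",
    "classify",
    "classify_cohort",
    "roc_from_scores",
    "roc_curve",
    "youden_optimal",
    "misclassification_rates",
    "percent_round",
    "distribution_summary",
]

IMPAIRED = "impaired"
ACCEPTABLE = "acceptable"
OPTIMAL = "optimal"
CLASS_LABELS = (IMPAIRED, ACCEPTABLE, OPTIMAL)


@dataclass(frozen=True)
class ThresholdScheme:
    """Two log10 cut-offs defining the three adaptation classes.

    impaired: log10(value) < lower_log; acceptable: lower_log <=
    log10(value) < upper_log; optimal: log10(value) >= upper_log.
    """

    name: str
    lower_log: float
    upper_log: float
    applies_to: str = "vm"

    def __post_init__(self) -> None:
        if not self.lower_log < self.upper_log:
            raise ValueError("lower_log must be below upper_log")
        if self.applies_to not in ("vm", "hs"):
            raise ValueError("applies_to must be 'vm' or 'hs'")

    @property
    def lower_linear(self) -> float:
        return 10.0**self.lower_log

    @property
    def upper_linear(self) -> float:
        return 10.0**self.upper_log


def classify(value: float, scheme: ThresholdScheme) -> str:
    """Class label of one linear-scale VM or HS value."""
    if not (np.isfinite(value) and value > 0):
        raise ValueError(f"classification requires a positive value, got {value!r}")
    lg = math.log10(value)
    if lg < scheme.lower_log:
        return IMPAIRED
    if lg < scheme.upper_log:
        return ACCEPTABLE
    return OPTIMAL


def classify_cohort(records: pd.DataFrame, scheme: ThresholdScheme) -> pd.Series:
    """Vectorized :func:`classify` over the scheme's parameter column."""
    values = np.asarray(records[scheme.applies_to], dtype=float)
    if (values <= 0).any():
        raise ValueError(f"{scheme.applies_to} contains non-positive values")
    lg = np.log10(values)
    labels = np.where(
        lg < scheme.lower_log, IMPAIRED, np.where(lg < scheme.upper_log, ACCEPTABLE, OPTIMAL)
    )
    return pd.Series(labels, index=records.index, name="class")


@dataclass(frozen=True)
class ROCCurve:
    """ROC operating points, AUC and the Youden-optimal point.

    Positive prediction at threshold tau means score >= tau; thresholds are
    in descending order (sklearn convention, leading +inf), so fpr and tpr
    are non-decreasing along the arrays.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    youden_threshold: float
    youden_tpr: float
    youden_fpr: float

    @property
    def tnr(self) -> np.ndarray:
        return 1.0 - self.fpr

    @property
    def youden_j(self) -> float:
        return self.youden_tpr - self.youden_fpr

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "youden_threshold": self.youden_threshold,
            "youden_tpr": self.youden_tpr,
            "youden_fpr": self.youden_fpr,
            "youden_j": self.youden_j,
            "n_points": int(self.thresholds.size),
        }


def roc_from_scores(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC over every distinct score threshold (nothing dropped).

    The trapezoid AUC of this full sweep equals the pairwise rank statistic
    P(score_pos > score_neg) + 0.5 * P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC requires both positive and negative records")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    area = float(_trapezoid_auc(fpr, tpr))

    j = tpr - fpr
    best = np.flatnonzero(j == j.max())[-1]  # thresholds descend: last max = smallest
    return ROCCurve(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=area,
        youden_threshold=float(thresholds[best]),
        youden_tpr=float(tpr[best]),
        youden_fpr=float(fpr[best]),
    )


def roc_curve(
    records: pd.DataFrame, score_param: str = "vm", hs_log_cut: float = 1.0
) -> ROCCurve:
    """ROC of a flowmotion score predicting a proper hypoxic response.

    Positives are subjects with ``log10(HS) >= hs_log_cut``; the score is
    the linear-scale column ``score_param`` (the curve is invariant under
    the log transform, which is strictly monotone).
    """
    hs = np.asarray(records["hs"], dtype=float)
    if (hs <= 0).any():
        raise ValueError("hs contains non-positive values")
    labels = np.log10(hs) >= hs_log_cut
    return roc_from_scores(np.asarray(records[score_param], dtype=float), labels)


def youden_optimal(roc: ROCCurve) -> tuple[float, float, float]:
    """Threshold maximizing J = TPR - FPR, with its operating point."""
    return roc.youden_threshold, roc.youden_tpr, roc.youden_fpr


def misclassification_rates(
    records: pd.DataFrame, vm_log_cut: float = 0.3, hs_log_cut: float = 1.0
) -> tuple[float, float]:
    """Discordance fractions between the VM cut-off and the HS response.

    false negative: log(VM) strictly below the cut yet log(HS) >= hs cut
    (proper response despite low resting myogenic activity); false
    positive: log(VM) strictly above the cut yet log(HS) < hs cut.
    Records with log(VM) exactly at the cut count in neither (strict
    inequalities on the VM side).
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    log_vm = np.log10(np.asarray(records["vm"], dtype=float))
    log_hs = np.log10(np.asarray(records["hs"], dtype=float))
    n = log_vm.size
    fn = float(np.count_nonzero((log_vm < vm_log_cut) & (log_hs >= hs_log_cut))) / n
    fp = float(np.count_nonzero((log_vm > vm_log_cut) & (log_hs < hs_log_cut))) / n
    return fn, fp


def percent_round(count: int, total: int) -> int:
    """Percentage of total rounded half-up to a whole percent."""
    return int(math.floor(100.0 * count / total + 0.5))


def distribution_summary(records: pd.DataFrame, scheme: ThresholdScheme) -> dict:
    """Counts and whole-percent shares per class, overall and by group."""
    labels = classify_cohort(records, scheme)
    total = len(records)
    overall = {
        label: {
            "count": int((labels == label).sum()),
            "percent": percent_round(int((labels == label).sum()), total),
        }
        for label in CLASS_LABELS
    }
    by_group = {
        str(group): {
            label: int((labels[records["group"] == group] == label).sum())
            for label in CLASS_LABELS
        }
        for group in records["group"].unique()
    }
    return {"scheme": scheme.name, "n": total, "overall": overall, "by_group": by_group}
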