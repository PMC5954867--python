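"""ROC threshold calibration and the fatigue alarm decision.

The alarm fires when the combined deviation D_C strictly exceeds the
threshold in force.  The ROC curve is therefore built under the same
strict-exceedance convention: each distinct score is a candidate
threshold, with TPR/FPR the fraction of fatigued/alert epochs scoring
strictly above it.  The area under the curve (trapezoid rule) equals
the Mann-Whitney probability that a random fatigued epoch outscores a
random alert epoch, ties counted one half.

Threshold selection maximizes Youden's J = TPR - FPR (ties broken
toward the lowest candidate, and the returned operating point is the
midpoint between that candidate and the next distinct score above it),
or simply returns a fixed value — the package default fixed threshold
is 6.0, the operating point of the original monitoring system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "DEFAULT_FATIGUE_THRESHOLD",
    "ROCCurve",
    "roc_curve",
    "select_threshold",
    "percentile_threshold",
    "detect",
    "debounced_alarms",
    "ThresholdAlarm",
]

#: Default fixed fatigue threshold on the D_C scale.
DEFAULT_FATIGUE_THRESHOLD = 6.0

_POSITIVE_LABELS = {"fatigued", "fatigue", "1", "true"}
_NEGATIVE_LABELS = {"alert", "0", "false"}


def _as_binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels
    if np.issubdtype(labels.dtype, np.number):
        return labels.astype(float) != 0
    out = np.empty(labels.shape, dtype=bool)
    for i, lab in enumerate(labels.ravel()):
        key = str(lab).strip().lower()
        if key in _POSITIVE_LABELS:
            out.ravel()[i] = True
        elif key in _NEGATIVE_LABELS:
            out.ravel()[i] = False
        else:
            raise ValueError(f"unrecognized state label {lab!r}")
    return out


@dataclass
class ROCCurve:
    """ROC curve of D_C scores against alert/fatigued labels.

    ``thresholds`` are the distinct scores in descending order with a
    final ``-inf`` sentinel; ``tpr[i]``/``fpr[i]`` are the rates of the
    strict rule ``score > thresholds[i]``, so the curve runs from
    (0, 0) to (1, 1).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    selected_threshold: float | None = None
    selection_method: str | None = None

    def youden_j(self) -> np.ndarray:
        return self.tpr - self.fpr


def roc_curve(scores, labels) -> ROCCurve:
    """Build the ROC curve of scores against binary state labels.

    Labels may be booleans, 0/1, or the strings ``"alert"`` /
    ``"fatigued"`` (fatigued = positive).  Both classes must be
    present.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"both classes required for ROC analysis (got {n_pos} fatigued, "
            f"{n_neg} alert)"
        )
    thresholds = np.r_[np.unique(scores)[::-1], -np.inf]
    pos, neg = scores[y], scores[~y]
    tpr = np.array([(pos > t).mean() for t in thresholds])
    fpr = np.array([(neg > t).mean() for t in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def select_threshold(
    roc: ROCCurve | None = None,
    method: str = "youden",
    fixed_value: float = DEFAULT_FATIGUE_THRESHOLD,
) -> float:
    """Choose the alarm threshold from a ROC curve.

    ``method="youden"`` maximizes J = TPR - FPR over the candidate
    scores; among ties the lowest candidate wins, and the returned
    value is the midpoint between it and the next distinct score above
    (so the operating point sits strictly inside the score gap).
    ``method="fixed"`` returns ``fixed_value`` (default 6.0).
    """
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("method='fixed' requires fixed_value")
        return float(fixed_value)
    if method != "youden":
        raise ValueError(f"unknown selection method {method!r}")
    if roc is None:
        raise ValueError("method='youden' requires a ROC curve")
    candidates = roc.thresholds[:-1]  # drop the -inf sentinel
    j = roc.youden_j()[:-1]
    best = np.flatnonzero(j == j.max())
    idx = int(best[-1])  # thresholds descend, so the last max is the lowest
    roc.selection_method = "youden"
    if idx == 0:
        roc.selected_threshold = float(candidates[0])
    else:
        roc.selected_threshold = float((candidates[idx] + candidates[idx - 1]) / 2)
    return roc.selected_threshold


def percentile_threshold(
    scores, percentile: float = 99.9, method: str = "lognormal"
) -> float:
    """Alarm threshold at an upper percentile of alert-state scores.

    ``method="lognormal"`` (default) fits a lognormal to the positive
    scores and returns its percentile point: D_C on an alert session
    is right-skewed, and the parametric tail estimate is far more
    stable at extreme percentiles than the sample order statistic from
    a calibration run of a few hundred epochs.  ``method="empirical"``
    returns the plain sample percentile.
    """
    from scipy import stats as _stats

    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 scores")
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must lie in (0, 100), got {percentile}")
    if method == "empirical":
        return float(np.percentile(scores, percentile))
    if method != "lognormal":
        raise ValueError(f"unknown method {method!r}")
    logs = np.log(np.maximum(scores, 1e-12))
    z = _stats.norm.ppf(percentile / 100)
    return float(np.exp(logs.mean() + z * logs.std()))


def detect(d_c, threshold: float):
    """Alarm decision: fatigue iff ``d_c`` is strictly larger than the
    threshold.  Accepts a scalar or an array of scores."""
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    d_c = np.asarray(d_c, dtype=float)
    alarm = d_c > threshold
    return bool(alarm) if alarm.ndim == 0 else alarm


def debounced_alarms(alarms, k: int = 1) -> np.ndarray:
    """Suppress alarms until ``k`` consecutive epochs exceed the
    threshold (k = 1 leaves the sequence unchanged)."""
    alarms = np.asarray(alarms, dtype=bool)
    if k <= 1:
        return alarms.copy()
    out = np.zeros_like(alarms)
    run = 0
    for i, a in enumerate(alarms):
        run = run + 1 if a else 0
        out[i] = run >= k
    return out


class ThresholdAlarm(BaseEstimator):
    """Scikit-learn style alarm calibrator.

    ``fit`` builds the ROC curve from labeled D_C scores and selects
    the operating threshold; ``predict`` applies the strict-exceedance
    alarm rule (with optional debouncing) to new scores.

    Parameters
    ----------
    method : {"youden", "fixed"}
        Threshold selection method.
    fixed_value : float
        Threshold used when ``method="fixed"`` (default 6.0).
    debounce : int
        Alarm only after this many consecutive exceedances.
    """

    def __init__(
        self,
        method: str = "youden",
        fixed_value: float = DEFAULT_FATIGUE_THRESHOLD,
        debounce: int = 1,
    ):
        self.method = method
        self.fixed_value = fixed_value
        self.debounce = debounce

    def fit(self, scores, labels=None):
        scores = np.ravel(np.asarray(scores, dtype=float))
        if self.method == "fixed":
            self.roc_ = None
            if labels is not None and len(scores):
                self.roc_ = roc_curve(scores, labels)
            self.threshold_ = select_threshold(
                self.roc_, method="fixed", fixed_value=self.fixed_value
            )
        else:
            if labels is None:
                raise ValueError("labels are required for ROC-based calibration")
            self.roc_ = roc_curve(scores, labels)
            self.threshold_ = select_threshold(self.roc_, method=self.method)
        return self

    def predict(self, scores) -> np.ndarray:
        if not hasattr(self, "threshold_"):
            raise ValueError("ThresholdAlarm must be fitted before predict")
        alarms = detect(np.ravel(np.asarray(scores, dtype=float)), self.threshold_)
        return debounced_alarms(alarms, self.debounce)
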