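"""ROC analysis for depletion cut-off derivation.

A single depletion score discriminates sensitizers (high depletion) from
non-sensitizers.  The classification rule is oriented ``score >= threshold ->
sensitizer``.  Candidate thresholds are the midpoints between consecutive
distinct observed scores, plus one sentinel below the minimum and one above
the maximum, so every achievable confusion matrix appears exactly once and
the reported cut-off does not coincide with any observed value — any
threshold inside the same inter-score interval induces the identical
classification, so a cut-off is meaningful only up to that interval.

The optimum is Youden's J = sensitivity + specificity - 1 (equivalently
balanced accuracy, since BA = (J+1)/2), with ties broken toward higher
specificity and then toward the larger threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import HazardLabel
from .exceptions import DegenerateDataError

__all__ = ["RocCurve", "CutoffResult", "roc_curve", "optimal_cutoff", "YoudenThresholdClassifier"]


def _as_bool_labels(labels) -> np.ndarray:
    out = np.empty(len(labels), dtype=bool)
    for i, lab in enumerate(labels):
        if isinstance(lab, HazardLabel):
            out[i] = lab is HazardLabel.SENSITIZER
        elif isinstance(lab, str):
            out[i] = lab == "sensitizer"
        else:
            out[i] = bool(lab)
    return out


@dataclass(frozen=True)
class RocCurve:
    """Candidate thresholds with their sensitivities and false-positive rates.

    Thresholds are sorted ascending; with the ``>=`` orientation both ``tpr``
    and ``fpr`` are non-increasing along the array.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    scores: np.ndarray
    labels: np.ndarray

    @property
    def youden_j(self) -> np.ndarray:
        return self.tpr - self.fpr

    @property
    def auc(self) -> float:
        """Area under the ROC staircase (trapezoidal, (FPR, TPR)-lex order)."""
        order = np.lexsort((self.tpr, self.fpr))
        return float(np.trapezoid(self.tpr[order], self.fpr[order]))


@dataclass(frozen=True)
class CutoffResult:
    """An optimal cut-off with its achieved operating point.

    ``tie_interval`` is the half-open interval ``(low, high]`` of thresholds
    inducing the same classification as ``threshold`` under the ``>=`` rule;
    the reported ``threshold`` is its midpoint (sentinel cut-offs sit one unit
    outside the score range).
    """

    threshold: float
    criterion: str
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    youden_j: float
    tie_interval: tuple[float, float]


def roc_curve(scores, labels) -> RocCurve:
    """Build the ROC operating points of ``score >= t -> sensitizer``.

    Both classes must be present; otherwise sensitivity or specificity is
    undefined and a :class:`DegenerateDataError` is raised.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_bool_labels(labels)
    if scores.shape[0] != y.shape[0]:
        raise ValueError(f"length mismatch: {scores.shape[0]} scores vs {y.shape[0]} labels")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("ROC analysis needs both classes present")
    distinct = np.unique(scores)
    thresholds = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )
    pred = scores[None, :] >= thresholds[:, None]
    tpr = (pred & y).sum(axis=1) / n_pos
    fpr = (pred & ~y).sum(axis=1) / n_neg
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, scores=scores, labels=y)


def _tie_interval(scores: np.ndarray, threshold: float) -> tuple[float, float]:
    below = scores[scores < threshold]
    at_or_above = scores[scores >= threshold]
    low = float(below.max()) if below.size else float(threshold - 1.0)
    high = float(at_or_above.min()) if at_or_above.size else float(threshold + 1.0)
    return (low, high)


def optimal_cutoff(curve: RocCurve, criterion: str = "youden") -> CutoffResult:
    """Pick the cut-off maximizing Youden's J (== balanced accuracy).

    Ties on J are broken toward higher specificity (fewer false positives),
    then toward the larger threshold.
    """
    if criterion not in ("youden", "balanced_accuracy"):
        raise ValueError(f"unknown criterion {criterion!r}")
    j = curve.youden_j
    spec = 1.0 - curve.fpr
    # lexicographic argmax over (J, specificity, threshold); thresholds ascend
    best = max(range(len(j)), key=lambda i: (j[i], spec[i], curve.thresholds[i]))
    t = float(curve.thresholds[best])
    return CutoffResult(
        threshold=t,
        criterion=criterion,
        sensitivity=float(curve.tpr[best]),
        specificity=float(spec[best]),
        balanced_accuracy=float((curve.tpr[best] + spec[best]) / 2.0),
        youden_j=float(j[best]),
        tie_interval=_tie_interval(curve.scores, t),
    )


class YoudenThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Single-score threshold classifier fitted by ROC analysis.

    ``fit(X, y)`` takes depletion scores (shape ``(n,)`` or ``(n, 1)``) and
    binary hazard labels, derives the Youden-optimal cut-off and stores it as
    ``threshold_``; ``predict`` applies ``score >= threshold_``.

    Parameters
    ----------
    criterion : "youden" or "balanced_accuracy" (equivalent maximizers).

    Attributes
    ----------
    threshold_ : derived cut-off (midpoint of its tie interval).
    tie_interval_ : (low, high] interval of classification-equivalent cut-offs.
    sensitivity_, specificity_, balanced_accuracy_ : achieved on training data.
    curve_ : the full :class:`RocCurve`.
    """

    def __init__(self, criterion: str = "youden"):
        self.criterion = criterion

    @staticmethod
    def _scores(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("expected a single score column, got shape %r" % (X.shape,))
        return X

    def fit(self, X, y):
        scores = self._scores(X)
        y_bool = _as_bool_labels(y)
        self.classes_ = np.array(
            [HazardLabel.NON_SENSITIZER.value, HazardLabel.SENSITIZER.value]
        )
        self.curve_ = roc_curve(scores, y_bool)
        result = optimal_cutoff(self.curve_, self.criterion)
        self.threshold_ = result.threshold
        self.tie_interval_ = result.tie_interval
        self.sensitivity_ = result.sensitivity
        self.specificity_ = result.specificity
        self.balanced_accuracy_ = result.balanced_accuracy
        self.youden_j_ = result.youden_j
        self.n_features_in_ = 1
        return self

    def decision_function(self, X):
        check_is_fitted(self, "threshold_")
        return self._scores(X) - self.threshold_

    def predict(self, X):
        return np.where(
            self.decision_function(X) >= 0.0,
            HazardLabel.SENSITIZER.value,
            HazardLabel.NON_SENSITIZER.value,
        )
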