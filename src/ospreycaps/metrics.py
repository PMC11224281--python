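"""Classification evaluation indexes from a confusion matrix.

Percent-scaled precision, recall, accuracy, specificity and F1,
the F-beta score (β = 2 by default), linear-weighted Cohen's kappa,
rank-based AUC and the Jaccard set index.  Binary decompositions treat
class index 1 as the positive (leukemic) class.

Undefined metrics (zero denominators, degenerate chance agreement,
single-class AUC input) raise ``UndefinedMetricError`` rather than
returning sentinel values.

The published F-beta formula this package mirrors carries an extra
``(1 + β²)`` prefactor that pushes values above 1; the standard form is
the default and the prefactored form is available as
``variant="as_printed"`` for fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "UndefinedMetricError",
    "precision",
    "recall",
    "accuracy",
    "specificity",
    "f1",
    "f_beta",
    "weighted_kappa",
    "auc",
    "jaccard",
    "METRIC_FUNCTIONS",
]


class UndefinedMetricError(ValueError):
    """A metric's denominator vanished; the value is undefined."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """k×k count table; rows are true classes, columns predictions."""

    f: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.f)
        if f.ndim != 2 or f.shape[0] != f.shape[1] or f.shape[0] < 2:
            raise ValueError("confusion matrix must be square, k >= 2")
        if np.any(f < 0) or not np.issubdtype(f.dtype, np.integer):
            raise ValueError("confusion matrix entries must be non-negative integers")
        object.__setattr__(self, "f", f)

    @classmethod
    def from_predictions(cls, y_true, y_pred, k: int | None = None):
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("label/prediction length mismatch")
        if k is None:
            k = int(max(y_true.max(), y_pred.max())) + 1
        f = np.zeros((k, k), dtype=int)
        np.add.at(f, (y_true, y_pred), 1)
        return cls(f)

    @classmethod
    def from_binary_counts(cls, tp: int, fp: int, fn: int, tn: int):
        """2×2 matrix with class 1 positive: rows/cols ordered (neg, pos)."""
        return cls(np.array([[tn, fp], [fn, tp]]))

    @property
    def k(self) -> int:
        return self.f.shape[0]

    @property
    def n(self) -> int:
        return int(self.f.sum())

    def _binary(self):
        if self.k != 2:
            raise ValueError("binary decomposition needs a 2x2 matrix")
        tn, fp = int(self.f[0, 0]), int(self.f[0, 1])
        fn, tp = int(self.f[1, 0]), int(self.f[1, 1])
        return tp, fp, fn, tn

    @property
    def tp(self):
        return self._binary()[0]

    @property
    def fp(self):
        return self._binary()[1]

    @property
    def fn(self):
        return self._binary()[2]

    @property
    def tn(self):
        return self._binary()[3]


def _ratio(num, den, name):
    if den == 0:
        raise UndefinedMetricError(f"{name} undefined: zero denominator")
    return num / den


def precision(cm: ConfusionMatrix) -> float:
    """TP / (TP + FP), in percent."""
    tp, fp, _, _ = cm._binary()
    return 100.0 * _ratio(tp, tp + fp, "precision")


def recall(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN), in percent."""
    tp, _, fn, _ = cm._binary()
    return 100.0 * _ratio(tp, tp + fn, "recall")


def accuracy(cm: ConfusionMatrix) -> float:
    """Trace over total, in percent (any k)."""
    return 100.0 * _ratio(np.trace(cm.f), cm.n, "accuracy")


def specificity(cm: ConfusionMatrix) -> float:
    """TN / (TN + FP), in percent."""
    _, fp, _, tn = cm._binary()
    return 100.0 * _ratio(tn, tn + fp, "specificity")


def f1(cm: ConfusionMatrix) -> float:
    """Harmonic mean of precision and recall, in percent."""
    pr = precision(cm) / 100.0
    rc = recall(cm) / 100.0
    return 100.0 * 2.0 * _ratio(pr * rc, pr + rc, "f1")


def f_beta(cm: ConfusionMatrix, beta: float = 2.0,
           variant: str = "standard") -> float:
    """F-beta score on [0, 1] (``standard``), or the published
    prefactored form (``as_printed``) which exceeds 1."""
    tp, fp, fn, _ = cm._binary()
    b2 = 1.0 + beta**2
    value = _ratio(b2 * tp, b2 * tp + beta**2 * fn + fp, "f_beta")
    if variant == "standard":
        return value
    if variant == "as_printed":
        return b2 * value
    raise ValueError(f"unknown f_beta variant {variant!r}")


def weighted_kappa(cm: ConfusionMatrix) -> float:
    """Linear-weighted Cohen's kappa.

    Agreement weights ``w_ij = 1 − |i−j|/(k−1)``; observed and expected
    weighted agreement are compared as ``(P_o − P_e)/(1 − P_e)``.  For
    k = 2 the weights reduce to the identity and this is plain Cohen's
    kappa.
    """
    f = cm.f.astype(float)
    k, n = cm.k, cm.n
    if n == 0:
        raise UndefinedMetricError("kappa undefined: empty matrix")
    i, j = np.indices((k, k))
    w = 1.0 - np.abs(i - j) / (k - 1)
    r = f.sum(axis=1)
    c = f.sum(axis=0)
    po = np.sum(w * f) / n
    pe = np.sum(w * np.outer(r, c)) / n**2
    if pe == 1.0:
        raise UndefinedMetricError("kappa undefined: chance agreement is 1")
    return float((po - pe) / (1.0 - pe))


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann–Whitney rank statistic.

    Probability that a random positive outscores a random negative,
    with ties credited 0.5.  Labels are binary with 1 positive.
    """
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    u = np.sum(ranks[labels == 1]) - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def jaccard(pred_set, true_set) -> float:
    """|A ∩ B| / |A ∪ B| for two sets."""
    a, b = set(pred_set), set(true_set)
    union = a | b
    if not union:
        raise UndefinedMetricError("Jaccard undefined: both sets empty")
    return len(a & b) / len(union)


# registry used by the experiment harnesses for per-fold reports
METRIC_FUNCTIONS = {
    "precision": precision,
    "recall": recall,
    "accuracy": accuracy,
    "specificity": specificity,
    "f1": f1,
    "f_beta": f_beta,
    "kappa": weighted_kappa,
}
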