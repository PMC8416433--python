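"""Binary-classification evaluation: confusion matrix, sensitivity,
specificity, balanced accuracy, Matthews correlation coefficient, and AUC.

Conventions chosen for machine-readable reports: an undefined sensitivity or
specificity (empty class) is reported as 0 with a flag rather than NaN; a
zero factor in the MCC denominator yields 0; AUC is the Mann-Whitney
statistic with mid-ranks for ties. Printed reports round to 2 decimals,
half-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_binary(y) -> np.ndarray:
    arr = np.asarray(y)
    if not np.isin(arr, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    return arr.astype(int)


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """2x2 counts; the positive class is label 1 (DILI-positive)."""
    t, p = _as_binary(y_true), _as_binary(y_pred)
    if len(t) != len(p):
        raise ValueError("y_true and y_pred lengths differ")
    return ConfusionMatrix(
        tp=int(((t == 1) & (p == 1)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def sensitivity(cm: ConfusionMatrix) -> tuple[float, bool]:
    """TP / (TP + FN); returns (value, defined-flag). Undefined -> (0, False)."""
    denom = cm.tp + cm.fn
    if denom == 0:
        return 0.0, False
    return cm.tp / denom, True


def specificity(cm: ConfusionMatrix) -> tuple[float, bool]:
    """TN / (TN + FP); returns (value, defined-flag). Undefined -> (0, False)."""
    denom = cm.tn + cm.fp
    if denom == 0:
        return 0.0, False
    return cm.tn / denom, True


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Mean of sensitivity and specificity (undefined halves contribute 0)."""
    return (sensitivity(cm)[0] + specificity(cm)[0]) / 2.0


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; zero denominator factor -> 0."""
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(float(denom_sq))


def auc(scores, y_true) -> float:
    """Area under the ROC curve via the Mann-Whitney rank-sum statistic.

    Ties in the scores receive mid-ranks, so a constant score gives 0.5.
    Requires both classes present.
    """
    y = _as_binary(y_true)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)  # mid-ranks for ties
    rank_sum_pos = ranks[y == 1].sum()
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up, as used for printed report tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EvalReport:
    """One model's test-set metrics, mirroring the printed performance table."""

    dataset: str
    dili_class: str
    algorithm: str
    auc: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    mcc: float
    #: metrics that were undefined (empty class) and reported as 0
    flags: list[str] = field(default_factory=list)

    @classmethod
    def from_predictions(
        cls, dataset: str, dili_class: str, algorithm: str, y_true, y_pred, scores
    ) -> "EvalReport":
        cm = confusion(y_true, y_pred)
        sens, sens_ok = sensitivity(cm)
        spec, spec_ok = specificity(cm)
        flags = [name for name, ok in (("sensitivity", sens_ok), ("specificity", spec_ok)) if not ok]
        return cls(
            dataset=dataset,
            dili_class=dili_class,
            algorithm=algorithm,
            auc=auc(scores, y_true),
            sensitivity=sens,
            specificity=spec,
            balanced_accuracy=balanced_accuracy(cm),
            mcc=mcc(cm),
            flags=flags,
        )

    def to_row(self, rounded: bool = True) -> dict:
        r = (lambda v: round_half_up(v, 2)) if rounded else (lambda v: v)
        row = {
            "dataset": self.dataset,
            "dili_class": self.dili_class,
            "algorithm": self.algorithm,
            "test_sensitivity": r(self.sensitivity),
            "test_specificity": r(self.specificity),
            "test_mcc": r(self.mcc),
            "test_balanced_accuracy": r(self.balanced_accuracy),
            "test_auc": r(self.auc),
        }
        if rounded and self.flags:
            row["flags"] = "*" + ",".join(self.flags)
        elif not rounded:
            row["flags"] = list(self.flags)
        return row


def reports_to_frame(reports: list[EvalReport], rounded: bool = True) -> pd.DataFrame:
    return pd.DataFrame([r.to_row(rounded=rounded) for r in reports])
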