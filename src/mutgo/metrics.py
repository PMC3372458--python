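"""Confusion counting and class-wise scoring indices.

The cancer class is treated as positive.  For each class the report
gives Sp, the class predictive value TP_c/(TP_c+FP_c), and Sn, the
class recall TP_c/(TP_c+FN_c); overall accuracy Q2 and the Matthews
correlation coefficient complete the summary.  With two classes these
four class-wise numbers are the standard way to read performance on an
imbalanced set, where Q2 alone is dominated by the majority class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from mutgo.dataset_io import Label

#: Prediction value for variants a method cannot score (uncovered aspect
#: or no usable homolog); excluded from the confusion counts but tallied
#: in ``n_unpredicted`` to support coverage columns.
UNPREDICTED = "UNPREDICTED"


@dataclass(frozen=True)
class ConfusionSummary:
    """TP/TN/FP/FN counts with derived indices (cancer = positive)."""

    tp: int
    tn: int
    fp: int
    fn: int
    n_unpredicted: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def q2(self) -> float:
        """Overall accuracy (TP+TN)/N."""
        return (self.tp + self.tn) / self.n if self.n else float("nan")

    @property
    def mcc(self) -> float:
        """Matthews correlation coefficient; 0 when a marginal is empty."""
        num = self.tp * self.tn - self.fp * self.fn
        den = (
            (self.tp + self.fp)
            * (self.tp + self.fn)
            * (self.tn + self.fp)
            * (self.tn + self.fn)
        )
        if den == 0:
            return 0.0
        return num / math.sqrt(den)

    @property
    def mcc_defined(self) -> bool:
        return (
            (self.tp + self.fp) > 0
            and (self.tp + self.fn) > 0
            and (self.tn + self.fp) > 0
            and (self.tn + self.fn) > 0
        )

    @property
    def sp_cancer(self) -> float:
        """Predictive value on the cancer class; NaN when nothing predicted cancer."""
        den = self.tp + self.fp
        return self.tp / den if den else float("nan")

    @property
    def sn_cancer(self) -> float:
        """Recall on the cancer class."""
        den = self.tp + self.fn
        return self.tp / den if den else float("nan")

    @property
    def sp_other(self) -> float:
        den = self.tn + self.fn
        return self.tn / den if den else float("nan")

    @property
    def sn_other(self) -> float:
        den = self.tn + self.fp
        return self.tn / den if den else float("nan")

    @property
    def coverage(self) -> float:
        """Fraction of submitted variants that received a prediction."""
        total = self.n + self.n_unpredicted
        return self.n / total if total else float("nan")

    def __add__(self, other: "ConfusionSummary") -> "ConfusionSummary":
        return ConfusionSummary(
            tp=self.tp + other.tp,
            tn=self.tn + other.tn,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
            n_unpredicted=self.n_unpredicted + other.n_unpredicted,
        )

    def as_row(self) -> dict[str, float]:
        """Report row with the conventional column names."""
        return {
            "n": self.n,
            "coverage": self.coverage,
            "Q": self.q2,
            "MCC": self.mcc,
            "Sp(C)": self.sp_cancer,
            "Sn(C)": self.sn_cancer,
            "Sp(O)": self.sp_other,
            "Sn(O)": self.sn_other,
        }


def confusion_counts(
    predicted: Sequence[object], observed: Sequence[Label]
) -> ConfusionSummary:
    """Count the confusion matrix of predictions against labels.

    ``predicted`` entries are :class:`Label` values or the sentinel
    :data:`UNPREDICTED`; unpredicted entries are excluded from the
    counts and tallied separately (they feed the coverage columns).
    """
    if len(predicted) != len(observed):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions, "
            f"{len(observed)} observations"
        )
    tp = tn = fp = fn = unpred = 0
    for p, o in zip(predicted, observed):
        if p == UNPREDICTED:
            unpred += 1
            continue
        if o == Label.CANCER:
            if p == Label.CANCER:
                tp += 1
            else:
                fn += 1
        else:
            if p == Label.CANCER:
                fp += 1
            else:
                tn += 1
    return ConfusionSummary(tp=tp, tn=tn, fp=fp, fn=fn, n_unpredicted=unpred)
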