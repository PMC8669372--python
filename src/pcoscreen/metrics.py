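"""Confusion matrices, per-class error decomposition, and accuracy.

The validation study reports per-class true/false positives and negatives
computed from a rows-as-actual confusion matrix with a convention that
swaps the usual roles of rows and columns: FP of a class is its *row* sum
minus the diagonal and FN its *column* sum minus the diagonal.  That
convention is reproduced (``convention="study"``, the default, matching
the shipped reference tables) alongside the textbook orientation
(``convention="standard"``).  True negatives use the inclusion–exclusion
form ``TN = total − rowsum − colsum + TP`` under both conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .questionnaire import CATEGORIES


@dataclass(frozen=True)
class ConfusionMatrix:
    """Actual × predicted counts over an ordered class list."""

    classes: tuple[str, ...]
    counts: np.ndarray  # rows = actual, columns = predicted

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (len(self.classes), len(self.classes)):
            raise ValueError("counts must be square over the class list")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_text(self) -> str:
        """Render in the actual-by-predicted layout used in screening reports."""
        width = max(4, *(len(c) for c in self.classes))
        head = "Actual \\ Predicted  " + " ".join(f"{c:>{width}}" for c in self.classes)
        rows = [
            f"{c:<19} " + " ".join(f"{int(v):>{width}}" for v in row)
            for c, row in zip(self.classes, self.counts)
        ]
        return "\n".join([head, *rows])


def confusion_matrix(
    actual: Sequence[str], predicted: Sequence[str], classes: Sequence[str] = CATEGORIES
) -> ConfusionMatrix:
    """Tally actual × predicted counts; labels outside the class set raise."""
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    bad = sorted({*actual, *predicted} - set(classes))
    if bad:
        raise ValueError(f"labels outside the class set: {bad}")
    counts = _sk_confusion(list(actual), list(predicted), labels=list(classes))
    return ConfusionMatrix(tuple(classes), counts)


def per_class_counts(cm: ConfusionMatrix, convention: str = "study") -> dict[str, dict[str, int]]:
    """Per-class TP/FP/FN/TN decomposition.

    ``convention="study"`` uses the validation study's row/column reading
    (FP from the class's actual row, FN from its predicted column);
    ``"standard"`` is the textbook orientation with the two swapped.
    """
    if convention not in ("study", "standard"):
        raise ValueError(f"unknown convention {convention!r}")
    counts = cm.counts
    total = cm.total
    out = {}
    for k, cls in enumerate(cm.classes):
        tp = int(counts[k, k])
        rowsum = int(counts[k, :].sum())
        colsum = int(counts[:, k].sum())
        row_err, col_err = rowsum - tp, colsum - tp
        fp, fn = (row_err, col_err) if convention == "study" else (col_err, row_err)
        out[cls] = {
            "TP": tp,
            "FP": fp,
            "FN": fn,
            "TN": total - rowsum - colsum + tp,
        }
    return out


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy as a percentage, ``100 × trace / total``."""
    if cm.total == 0:
        raise ValueError("accuracy undefined for an empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def metrics_report(cm: ConfusionMatrix, convention: str = "study") -> str:
    """Plain-text summary: the matrix, per-class decomposition, and accuracy."""
    per = per_class_counts(cm, convention)
    lines = [cm.to_text(), ""]
    lines.append("class  " + "  ".join(f"{c:>5}" for c in cm.classes))
    for key in ("TP", "FP", "FN", "TN"):
        lines.append(f"{key:<6} " + "  ".join(f"{per[c][key]:>5}" for c in cm.classes))
    lines.append("")
    lines.append(f"accuracy: {accuracy(cm):.2f}%  ({int(np.trace(cm.counts))}/{cm.total})")
    return "\n".join(lines)
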