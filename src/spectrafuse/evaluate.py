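"""Confusion-matrix evaluation of origin predictions.

Convention: confusion rows are PREDICTED classes, columns are TRUE classes
(the transpose of the more common layout; a ``transpose`` flag on
:func:`evaluate` is provided for interoperability). The diagonal counts
correct predictions; per-class TP/TN/FP/FN, precision and recall follow.
Undefined precision/recall (zero denominator, e.g. a class never predicted)
is reported as NaN, never silently 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion


@dataclass
class EvaluationReport:
    """Confusion matrix (rows = predicted, columns = true) and accuracy."""

    confusion: np.ndarray
    class_order: list
    n_test: int

    @property
    def accuracy(self) -> float:
        """Overall accuracy in percent: 100 * trace / n_test."""
        return 100.0 * np.trace(self.confusion) / self.n_test

    def per_class(self) -> dict:
        """TP/TN/FP/FN, precision and recall for each class.

        Under the rows-predicted convention FP_c is the row-c sum minus the
        diagonal and FN_c the column-c sum minus the diagonal.
        """
        cm = self.confusion
        out = {}
        for i, cls in enumerate(self.class_order):
            tp = int(cm[i, i])
            fp = int(cm[i, :].sum() - tp)
            fn = int(cm[:, i].sum() - tp)
            tn = self.n_test - tp - fp - fn
            out[cls] = {
                "TP": tp, "TN": tn, "FP": fp, "FN": fn,
                "precision": tp / (tp + fp) if tp + fp else float("nan"),
                "recall": tp / (tp + fn) if tp + fn else float("nan"),
            }
        return out


def evaluate(true_labels, predicted_labels, class_order,
             transpose: bool = False) -> EvaluationReport:
    """Build an :class:`EvaluationReport` from label vectors.

    With ``transpose=True`` the confusion matrix is stored in the more
    common rows-true orientation instead (per-class FP/FN swap roles
    accordingly).

    Raises
    ------
    ValueError
        On length mismatch or a label outside ``class_order``.
    """
    true_labels = np.asarray(true_labels, dtype=object)
    predicted_labels = np.asarray(predicted_labels, dtype=object)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("true and predicted label vectors differ in length")
    known = set(class_order)
    for vec, which in ((true_labels, "true"), (predicted_labels, "predicted")):
        bad = [l for l in vec if l not in known]
        if bad:
            raise ValueError(f"{which} label outside class_order: {bad[0]!r}")
    # sklearn uses rows = true; transpose to the rows-predicted convention
    cm = _sk_confusion(true_labels, predicted_labels, labels=list(class_order))
    if not transpose:
        cm = cm.T
    return EvaluationReport(
        confusion=cm, class_order=list(class_order), n_test=len(true_labels)
    )


def report_to_text(report: EvaluationReport) -> str:
    """Deterministic plain-text rendering: confusion matrix with class
    headers, then accuracy to 2 decimal places and per-class metrics."""
    classes = [str(c) for c in report.class_order]
    width = max(max(len(c) for c in classes), 5) + 2
    lines = ["Confusion matrix (rows = predicted, columns = true)"]
    lines.append(" " * width + "".join(c.rjust(width) for c in classes))
    for i, cls in enumerate(classes):
        row = "".join(str(int(v)).rjust(width) for v in report.confusion[i])
        lines.append(cls.rjust(width) + row)
    lines.append(f"Accuracy: {report.accuracy:.2f}% (n_test = {report.n_test})")
    lines.append("class".rjust(width) + "".join(
        h.rjust(8) for h in ("TP", "TN", "FP", "FN", "prec", "recall")))
    for cls, m in report.per_class().items():
        prec = "undef" if np.isnan(m["precision"]) else f"{m['precision']:.3f}"
        rec = "undef" if np.isnan(m["recall"]) else f"{m['recall']:.3f}"
        lines.append(str(cls).rjust(width)
                     + "".join(str(m[k]).rjust(8) for k in ("TP", "TN", "FP", "FN"))
                     + prec.rjust(8) + rec.rjust(8))
    return "\n".join(lines) + "\n"
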