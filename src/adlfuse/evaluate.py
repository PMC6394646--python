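"""Recognition metrics: confusion matrix, per-class precision/recall/F1.

F1 is the harmonic mean of precision and recall, 2PR/(P+R), taken as 0 when
P + R = 0.  Macro averages are unweighted means over classes; overall
accuracy is the sample-weighted (micro) accuracy, i.e. the trace of the
confusion matrix over the sample count.  Classes absent from both the
predictions and the gold labels have undefined precision/recall; they are
reported as 0 and flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from adlfuse.frame import Frame


@dataclass
class EvalReport:
    """Per-class and aggregate recognition metrics (rows = truth)."""

    labels: tuple[str, ...]
    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    absent_classes: tuple[str, ...] = field(default_factory=tuple)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def per_class(self) -> dict[str, dict[str, float]]:
        return {
            l: {
                "precision": float(self.precision[i]),
                "recall": float(self.recall[i]),
                "f1": float(self.f1[i]),
                "support": int(self.support[i]),
            }
            for i, l in enumerate(self.labels)
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "accuracy": self.accuracy,
                "macro_precision": self.macro_precision,
                "macro_recall": self.macro_recall,
                "macro_f1": self.macro_f1,
                "per_class": self.per_class(),
                "confusion": self.confusion.tolist(),
                "labels": list(self.labels),
                "absent_classes": list(self.absent_classes),
            },
            indent=1,
        )

    def to_text(self) -> str:
        lines = [f"{'class':<6} {'P':>7} {'R':>7} {'F1':>7} {'n':>5}"]
        for l, row in self.per_class().items():
            lines.append(
                f"{l:<6} {row['precision']:7.4f} {row['recall']:7.4f} "
                f"{row['f1']:7.4f} {row['support']:5d}"
            )
        lines.append(
            f"accuracy {self.accuracy:.4f}  macro-F1 {self.macro_f1:.4f}"
        )
        return "\n".join(lines)


def evaluate(
    predictions: Sequence[str], gold: Sequence[str], frame: Frame
) -> EvalReport:
    """Score aligned prediction/gold label sequences over a frame."""
    if len(predictions) != len(gold):
        raise ValueError("predictions and gold differ in length")
    if len(gold) == 0:
        raise ValueError("nothing to evaluate")
    labels = list(frame.labels)
    cm = confusion_matrix(gold, predictions, labels=labels)
    p, r, f1, support = precision_recall_fscore_support(
        gold, predictions, labels=labels, zero_division=0
    )
    seen = set(gold) | set(predictions)
    absent = tuple(l for l in labels if l not in seen)
    return EvalReport(
        labels=tuple(labels),
        confusion=cm,
        precision=p,
        recall=r,
        f1=f1,
        support=support,
        absent_classes=absent,
    )
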