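"""Evaluation: accuracy, per-class recall, macro recall, model comparison.

Macro recall (the unweighted mean of per-class recalls) is the headline
number for imbalanced tasks: a classifier that ignores the minority class can
score high accuracy but not high macro recall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from .elm import ordered_classes

__all__ = ["EvaluationReport", "evaluate", "relative_improvement", "load_reference_model_scores"]

_DATA_DIR = Path(__file__).parent / "data"


@dataclass
class EvaluationReport:
    accuracy: float
    per_class_recall: dict
    macro_recall: float
    confusion: pd.DataFrame  # rows: truth, columns: prediction
    n: int

    def to_text(self) -> str:
        lines = [
            f"n = {self.n}",
            f"accuracy     = {self.accuracy:.4f}",
            f"macro recall = {self.macro_recall:.4f}",
        ]
        for c, r in self.per_class_recall.items():
            lines.append(f"recall[{c}]  = {'nan' if r is None else format(r, '.4f')}")
        lines.append("confusion (rows = truth):")
        lines.append(self.confusion.to_string())
        return "\n".join(lines)


def evaluate(truth: Sequence, pred: Sequence) -> EvaluationReport:
    """Score predictions against truth.

    Classes absent from the truth get recall ``None`` and are excluded from
    the macro average (with a warning).
    """
    truth, pred = np.asarray(truth), np.asarray(pred)
    if len(truth) != len(pred):
        raise ValueError("truth and pred must have equal length")
    classes = ordered_classes(np.concatenate([truth, pred]))
    cm = confusion_matrix(truth, pred, labels=classes)
    conf = pd.DataFrame(cm, index=classes, columns=classes)
    support = cm.sum(axis=1)
    recalls: dict = {}
    usable = []
    for i, c in enumerate(classes):
        if support[i] == 0:
            warnings.warn(f"class {c!r} absent from truth; excluded from macro recall",
                          stacklevel=2)
            recalls[c] = None
        else:
            r = cm[i, i] / support[i]
            recalls[c] = float(r)
            usable.append(r)
    return EvaluationReport(
        accuracy=float(np.trace(cm) / len(truth)),
        per_class_recall=recalls,
        macro_recall=float(np.mean(usable)),
        confusion=conf,
        n=len(truth),
    )


def relative_improvement(new: float, baseline: float) -> float:
    """Percentage change of ``new`` over ``baseline``: 100 (new - base) / base."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (new - baseline) / baseline


def load_reference_model_scores() -> pd.DataFrame:
    """Bundled accuracy/recall scores of six classifiers (reference table).

    Columns are models, rows ``accuracy`` and ``recall``; from a published
    stress-classification comparison.  Used by the worked comparison-arithmetic
    example.
    """
    return pd.read_csv(_DATA_DIR / "reference_model_scores.csv", index_col=0)
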