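"""Confusion matrix, the four headline metrics, and a per-class report.

Conventions: label 1 = tumor = positive.  The metrics are

    accuracy  = (TP + TN) / total
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Any 0/0 cell evaluates to 0 and sets a degeneracy flag instead of
raising, so reports on degenerate splits still render.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = ["ConfusionMatrix", "Metrics", "ClassificationReport",
           "confusion", "metrics", "report", "render_report"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    degenerate: bool = False   # some 0/0 cell was coerced to 0


@dataclass(frozen=True)
class ClassificationReport:
    """Per-class precision/recall/F1/support plus the summary rows."""

    per_class: dict[int, Metrics]
    support: dict[int, int]
    accuracy: float
    macro: Metrics
    weighted: Metrics
    total: int


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    """2x2 cross-tabulation with 1 = tumor = positive."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.ndim != 1 or len(yt) == 0:
        raise ValueError("y_true and y_pred must be equal-length nonempty 1-D")
    if not (np.isin(yt, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise ValueError("labels must be in {0, 1}")
    return ConfusionMatrix(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def metrics(cm: ConfusionMatrix) -> Metrics:
    accuracy = (cm.tp + cm.tn) / cm.total
    precision, d1 = _safe_div(cm.tp, cm.tp + cm.fp)
    recall, d2 = _safe_div(cm.tp, cm.tp + cm.fn)
    f1, d3 = _safe_div(2 * precision * recall, precision + recall)
    return Metrics(accuracy, precision, recall, f1, d1 or d2 or d3)


def report(y_true: Sequence[int], y_pred: Sequence[int]) -> ClassificationReport:
    """Per-class metrics (each class as positive in turn) with macro and
    support-weighted averages."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if len(yt) == 0:
        raise ValueError("report requires at least one sample")
    classes = (0, 1)
    per_class: dict[int, Metrics] = {}
    support: dict[int, int] = {}
    for cls in classes:
        cm_cls = ConfusionMatrix(
            tp=int(((yt == cls) & (yp == cls)).sum()),
            fp=int(((yt != cls) & (yp == cls)).sum()),
            tn=int(((yt != cls) & (yp != cls)).sum()),
            fn=int(((yt == cls) & (yp != cls)).sum()),
        )
        per_class[cls] = metrics(cm_cls)
        support[cls] = int((yt == cls).sum())

    total = len(yt)
    accuracy = float((yt == yp).mean())
    n_cls = len(classes)
    macro = Metrics(
        accuracy,
        sum(per_class[c].precision for c in classes) / n_cls,
        sum(per_class[c].recall for c in classes) / n_cls,
        sum(per_class[c].f1 for c in classes) / n_cls,
        any(per_class[c].degenerate for c in classes),
    )
    weighted = Metrics(
        accuracy,
        sum(per_class[c].precision * support[c] for c in classes) / total,
        sum(per_class[c].recall * support[c] for c in classes) / total,
        sum(per_class[c].f1 * support[c] for c in classes) / total,
        macro.degenerate,
    )
    return ClassificationReport(per_class, support, accuracy, macro,
                                weighted, total)


def render_report(rep: ClassificationReport) -> str:
    """Aligned text rendering of the per-class report."""
    lines = [f"{'':>16} {'Precision':>9} {'Recall':>9} {'F1-score':>9} {'Support':>9}"]
    for cls in sorted(rep.per_class):
        m = rep.per_class[cls]
        lines.append(f"{cls:>16} {m.precision:>9.2f} {m.recall:>9.2f} "
                     f"{m.f1:>9.2f} {rep.support[cls]:>9}")
    lines.append(f"{'Accuracy':>16} {rep.accuracy:>9.2f} {rep.accuracy:>9.2f} "
                 f"{rep.accuracy:>9.2f} {rep.total:>9}")
    for name, m in (("Macro average", rep.macro), ("Weighted average", rep.weighted)):
        lines.append(f"{name:>16} {m.precision:>9.2f} {m.recall:>9.2f} "
                     f"{m.f1:>9.2f} {rep.total:>9}")
    return "\n".join(lines)


def report_to_json(rep: ClassificationReport) -> str:
    doc = {
        "per_class": {str(c): asdict(m) for c, m in rep.per_class.items()},
        "support": {str(c): s for c, s in rep.support.items()},
        "accuracy": rep.accuracy,
        "macro": asdict(rep.macro),
        "weighted": asdict(rep.weighted),
        "total": rep.total,
    }
    return json.dumps(doc, indent=2)
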