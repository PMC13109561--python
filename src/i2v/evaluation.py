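"""Accuracy and macro-averaged metrics with growth-stage and group breakdowns.

Accuracy is Σᵢ TPᵢ / N over the C classes; precision, recall and F1 are
computed per class from the confusion matrix and macro-averaged (unweighted
mean over classes) so rare accessions count equally.  Per-class ratios with a
zero denominator are defined as 0 and stay in the macro mean — with hundreds
of classes and a 20 % test split, empty classes do occur, and dropping them
would inflate the averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import date_sort_key


@dataclass
class EvalReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: pd.DataFrame
    per_stage: pd.DataFrame | None = None
    confusion_partition: tuple[int, int] | None = None
    n: int = 0

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "n": self.n,
        }
        if self.confusion_partition is not None:
            d["within_group_errors"], d["across_group_errors"] = \
                self.confusion_partition
        return d


def _validated(preds, labels, num_classes: int):
    preds = np.asarray(preds, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if preds.shape != labels.shape or preds.ndim != 1:
        raise ValueError("preds and labels must be 1-D and the same length")
    if num_classes < 1:
        raise ValueError("num_classes must be >= 1")
    for name, arr in (("preds", preds), ("labels", labels)):
        if arr.size and (arr.min() < 0 or arr.max() >= num_classes):
            raise ValueError(f"{name} contain values outside [0, {num_classes})")
    return preds, labels


def confusion_matrix(preds, labels, num_classes: int) -> np.ndarray:
    """counts[i, j] = number of samples with true class i predicted as j."""
    preds, labels = _validated(preds, labels, num_classes)
    cm = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(cm, (labels, preds), 1)
    return cm


def compute_metrics(preds, labels, num_classes: int,
                    class_names: list[str] | None = None) -> EvalReport:
    """Accuracy plus macro precision/recall/F1 from the confusion matrix."""
    preds, labels = _validated(preds, labels, num_classes)
    if preds.size == 0:
        raise ValueError("empty prediction set")
    cm = confusion_matrix(preds, labels, num_classes)
    tp = np.diag(cm).astype(np.float64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    names = class_names if class_names is not None else \
        [str(i) for i in range(num_classes)]
    per_class = pd.DataFrame({
        "class": names,
        "tp": tp.astype(int), "fp": fp.astype(int), "fn": fn.astype(int),
        "precision": precision, "recall": recall, "f1": f1,
    })
    n = len(labels)
    return EvalReport(
        accuracy=float(tp.sum() / n),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        per_class=per_class,
        n=n,
    )


def stage_accuracy(preds, labels, stages) -> pd.DataFrame:
    """Accuracy and image count per growth stage, in natural stage order.

    ``stages`` holds one stage token per sample (sampling dates, phenological
    bins, or S1–S9 labels); missing tokens (None/NaN) are pooled under
    ``unstaged``.
    """
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    if len(stages) != len(preds) or len(preds) != len(labels):
        raise ValueError("preds, labels and stages must have the same length")
    tokens = ["unstaged" if s is None or (isinstance(s, float) and np.isnan(s))
              else str(s) for s in stages]
    df = pd.DataFrame({"stage": tokens, "correct": preds == labels})
    rows = [
        {"stage": stage, "accuracy": float(g["correct"].mean()),
         "n_images": int(len(g))}
        for stage, g in df.groupby("stage", sort=False)
    ]
    rows.sort(key=lambda r: (r["stage"] == "unstaged",
                             date_sort_key(r["stage"])))
    return pd.DataFrame(rows, columns=["stage", "accuracy", "n_images"])


def confusion_partition(preds, labels, group_of: dict) -> tuple[int, int]:
    """Split misclassifications into within-group and across-group counts.

    ``group_of`` maps every class index (or name) to a group label, e.g. rice
    accession -> subspecies.  The two counts sum to the total error count.
    """
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    if preds.shape != labels.shape:
        raise ValueError("preds and labels must have the same length")
    classes = set(preds.tolist()) | set(labels.tolist())
    missing = sorted(c for c in classes if c not in group_of)
    if missing:
        raise ValueError(f"classes without a group: {missing[:5]}")
    within = across = 0
    for p, t in zip(preds.tolist(), labels.tolist()):
        if p == t:
            continue
        if group_of[p] == group_of[t]:
            within += 1
        else:
            across += 1
    return within, across


def relative_improvement(baseline_pct: float, new_pct: float) -> float:
    """Relative change 100·(new − baseline)/baseline, rounded to 2 decimals."""
    if baseline_pct <= 0:
        raise ValueError("baseline must be positive")
    return round(100.0 * (new_pct - baseline_pct) / baseline_pct, 2)
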