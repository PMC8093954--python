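"""Confusion counts and the five derived assessment measures.

With a designated positive class (benign, by the source system's
convention — note most CADx literature designates malignant):

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    F1          = 2 TP / (2 TP + FP + FN)

A zero denominator yields ``None`` (a distinct undefined marker, never
silently 0 or 1); macro averaging over one-vs-rest tables skips undefined
values with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int
    positive_label: str = "benign"

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class Metrics:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None

    def as_dict(self) -> dict:
        return asdict(self)


def confusion_counts(y_true, y_pred, positive_label: str = "benign") -> ConfusionCounts:
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred differ in length")
    # a positive label absent from both vectors is legal: TP = FP = FN = 0
    pos_t = yt == positive_label
    pos_p = yp == positive_label
    return ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
        positive_label=positive_label,
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(cc: ConfusionCounts) -> Metrics:
    if cc.total == 0:
        raise ValueError("empty confusion table")
    return Metrics(
        accuracy=_ratio(cc.TP + cc.TN, cc.total),
        sensitivity=_ratio(cc.TP, cc.TP + cc.FN),
        specificity=_ratio(cc.TN, cc.TN + cc.FP),
        precision=_ratio(cc.TP, cc.TP + cc.FP),
        f1=_ratio(2 * cc.TP, 2 * cc.TP + cc.FP + cc.FN),
    )


def macro_metrics(y_true, y_pred, label_set: list[str] | None = None) -> Metrics:
    """Unweighted one-vs-rest average over the label set (multiclass)."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if label_set is None:
        label_set = sorted(set(yt))
    if len(label_set) < 2:
        raise ValueError("need at least 2 labels")
    extra = set(yp) - set(label_set) - set(yt)
    if extra:
        raise ValueError(f"predicted labels not in label_set: {sorted(extra)}")
    per_label = [compute_metrics(confusion_counts(yt, yp, lab)) for lab in label_set]

    def mean_defined(field: str) -> float | None:
        vals = [getattr(m, field) for m in per_label]
        defined = [v for v in vals if v is not None]
        if len(defined) < len(vals):
            warnings.warn(
                f"{field}: {len(vals) - len(defined)} undefined per-class value(s) "
                "excluded from the macro average",
                stacklevel=2,
            )
        return float(np.mean(defined)) if defined else None

    return Metrics(*(mean_defined(f) for f in ("accuracy", "sensitivity", "specificity", "precision", "f1")))


def metrics_report_row(stage: str, fs_id: str, classifier: str, m: Metrics) -> dict:
    return {"stage": stage, "fs_id": fs_id, "classifier": classifier, **m.as_dict()}


def save_metrics_csv(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def save_metrics_json(rows: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(rows, indent=2))
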