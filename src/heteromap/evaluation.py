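"""Pixel-level classification metrics and the per-cohort report.

The positive class is the highly cellular region (ADC below the cut-off).
Every tumor pixel counts equally.  Metrics with a zero denominator are
reported as missing (``None``), never as NaN propagating into averages:
cohort averages are taken over the defined entries only, with a note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ConfusionCounts", "ClassificationMetrics", "confusion", "metrics", "EvalReport"]

METRIC_NAMES = ("accuracy", "balanced_accuracy", "sensitivity", "specificity")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ClassificationMetrics:
    accuracy: float | None
    balanced_accuracy: float | None
    sensitivity: float | None
    specificity: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def confusion(pred, truth) -> ConfusionCounts:
    """Pixel confusion counts; positive = high cellularity (label 1)."""
    pred = np.asarray(pred).astype(int).ravel()
    truth = np.asarray(truth).astype(int).ravel()
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.size} predictions vs {truth.size} labels")
    if not np.isin(pred, (0, 1)).all() or not np.isin(truth, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (truth == 1))),
        fp=int(np.sum((pred == 1) & (truth == 0))),
        tn=int(np.sum((pred == 0) & (truth == 0))),
        fn=int(np.sum((pred == 0) & (truth == 1))),
    )


def metrics(c: ConfusionCounts) -> ClassificationMetrics:
    """Accuracy, balanced accuracy, sensitivity, specificity.

    accuracy = (TP+TN)/total, sensitivity (recall of the positive class) =
    TP/(TP+FN), specificity = TN/(TN+FP), balanced accuracy = mean of the
    two class recalls.  A zero-denominator entry is missing, and balanced
    accuracy is missing whenever either recall is.
    """
    if c.total == 0:
        raise ValueError("no evaluated pixels")
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    bal = (sens + spec) / 2.0 if sens is not None and spec is not None else None
    return ClassificationMetrics(
        accuracy=(c.tp + c.tn) / c.total,
        balanced_accuracy=bal,
        sensitivity=sens,
        specificity=spec,
    )


@dataclass
class EvalReport:
    """Per-case metric rows plus cohort averages, one column set per kind.

    ``frame`` has one row per case with columns ``{kind}_{metric}``;
    ``summary_frame()`` appends the average and standard-deviation rows
    (computed over the defined entries only).
    """

    frame: pd.DataFrame
    kinds: tuple[str, ...]
    notes: list[str] = field(default_factory=list)

    @classmethod
    def from_rows(cls, rows: list[dict], kinds: tuple[str, ...]) -> "EvalReport":
        frame = pd.DataFrame(rows).set_index("case_id")
        notes = []
        for col in frame.columns:
            n_missing = int(frame[col].isna().sum())
            if n_missing:
                cases = list(frame.index[frame[col].isna()])
                notes.append(
                    f"{col}: undefined for {cases}; excluded from the average"
                )
                logger.info("metric %s undefined for %s", col, cases)
        return cls(frame, kinds, notes)

    def averages(self) -> pd.Series:
        return self.frame.mean(skipna=True)

    def stds(self) -> pd.Series:
        return self.frame.std(skipna=True, ddof=1)

    def summary_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out.loc["Average"] = self.averages()
        out.loc["±Std. Dev."] = self.stds()
        return out

    def summary(self) -> str:
        with pd.option_context("display.float_format", "{:.3f}".format):
            text = self.summary_frame().to_string()
        if self.notes:
            text += "\n\nNotes:\n" + "\n".join(f"  - {n}" for n in self.notes)
        return text

    def to_csv(self, path) -> None:
        self.summary_frame().to_csv(path)
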