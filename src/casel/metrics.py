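"""Confusion-count bookkeeping and binary classification metrics.

The positive class is always "active".  Metrics follow the closed-form
definitions

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    MCC       = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A zero denominator yields an explicit ``None`` flag, never a silent zero:
external validation sets can lack one class entirely (e.g. no inactives for
hCA XII at large sampling sizes), and those cells must be visibly undefined.

Probability-score stratification assigns each consensus prediction to one of
the bins {0.6, 0.7, 0.8, 0.9, 1.0} by rounding its mean score (half up) to
one decimal; scores below 0.55 are clamped into the lowest bin.  Rounding —
rather than half-open intervals — makes the per-bin confusion counts add up
exactly to the overall counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

#: Probability bins used in stratified validation reports.
PROBABILITY_BINS: Tuple[float, ...] = (0.6, 0.7, 0.8, 0.9, 1.0)

OVERALL = "overall"


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with "active" as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fn + other.fn,
            self.fp + other.fp,
            self.tn + other.tn,
        )

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative confusion count: {name}")


@dataclass(frozen=True)
class MetricSet:
    """Accuracy, precision, recall in [0, 1]; MCC in [-1, 1].

    A field is ``None`` when its denominator is zero (undefined), which is
    distinct from a genuine zero value.
    """

    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    mcc: Optional[float]

    def rounded(self, ndigits: int = 2) -> "MetricSet":
        """Display rounding: half away from zero, raw values kept elsewhere."""
        return MetricSet(*(
            None if v is None else round_half_away(v, ndigits)
            for v in (self.accuracy, self.precision, self.recall, self.mcc)
        ))


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.285 -> 0.29, -0.285 -> -0.29)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Compute the four performance metrics from confusion counts.

    Raises ``ValueError`` on an empty table; individual undefined metrics
    (zero denominator) are flagged as ``None``.
    """
    tp, fn, fp, tn = counts.tp, counts.fn, counts.fp, counts.tn
    total = counts.total
    if total == 0:
        raise ValueError("cannot compute metrics on empty confusion counts")
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else None
    return MetricSet(accuracy, precision, recall, mcc)


def confusion_from_labels(
    true_labels: Sequence[int], predicted_labels: Sequence[int]
) -> ConfusionCounts:
    """Cross-tabulate binary label vectors (1 = active = positive)."""
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"label length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    if not set(np.unique(np.concatenate([y_true, y_pred]))) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)


def probability_bin(mean_score: float) -> float:
    """Assign a mean probability score in [0.5, 1] to its report bin.

    Round half up to one decimal, then clamp into {0.6, ..., 1.0}: scores
    below 0.55 join the lowest bin since the report columns start at 0.6.
    """
    if not 0.5 - 1e-9 <= mean_score <= 1.0 + 1e-9:
        raise ValueError(f"mean score {mean_score} outside [0.5, 1]")
    b = math.floor(mean_score * 10 + 0.5) / 10
    return float(min(max(b, PROBABILITY_BINS[0]), PROBABILITY_BINS[-1]))


def stratify_by_probability(
    final_labels: Sequence[int],
    mean_scores: Sequence[float],
    true_labels: Sequence[int],
) -> Dict[object, Tuple[ConfusionCounts, Optional[MetricSet]]]:
    """Per-probability-bin confusion counts and metrics, plus the overall row.

    Returns a mapping with keys ``PROBABILITY_BINS`` and ``"overall"``.  An
    empty bin carries zero counts and a ``None`` metric set.  Per-bin counts
    sum exactly to the overall counts.
    """
    final_labels = np.asarray(final_labels)
    true_labels = np.asarray(true_labels)
    scores = np.asarray(mean_scores, dtype=float)
    if not (len(final_labels) == len(true_labels) == len(scores)):
        raise ValueError("labels and scores must have equal lengths")
    bins = np.array([probability_bin(s) for s in scores])
    out: Dict[object, Tuple[ConfusionCounts, Optional[MetricSet]]] = {}
    for b in PROBABILITY_BINS:
        mask = bins == b
        counts = confusion_from_labels(true_labels[mask], final_labels[mask])
        out[b] = (counts, compute_metrics(counts) if counts.total else None)
    overall = confusion_from_labels(true_labels, final_labels)
    out[OVERALL] = (overall, compute_metrics(overall) if overall.total else None)
    return out


def stratified_report_frame(
    stratified: Mapping[object, Tuple[ConfusionCounts, Optional[MetricSet]]],
) -> pd.DataFrame:
    """Arrange stratified results as a report table.

    Rows TP/FN/FP/TN/accuracy/MCC/precision/recall, columns overall + bins;
    undefined metrics appear as NA.  Metric rows are display-rounded to 2 dp.
    """
    columns = [OVERALL] + [str(b) for b in PROBABILITY_BINS]
    rows = ["TP", "FN", "FP", "TN", "accuracy", "MCC", "precision", "recall"]
    data: Dict[str, list] = {}
    for key in [OVERALL, *PROBABILITY_BINS]:
        counts, metrics = stratified[key]
        m = metrics.rounded() if metrics is not None else MetricSet(None, None, None, None)
        data[str(key)] = [
            counts.tp, counts.fn, counts.fp, counts.tn,
            m.accuracy, m.mcc, m.precision, m.recall,
        ]
    return pd.DataFrame(data, index=rows)[columns]


def mean_sd(values: Iterable[float]) -> Tuple[float, float]:
    """Mean and population standard deviation of a sequence."""
    arr = np.asarray(list(values), dtype=float)
    return float(arr.mean()), float(arr.std())
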