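"""Sparse-slice-masked confusion counting and edge-corrected metrics.

Evaluation runs only over annotated voxels (label code nonzero, hence
only on labeled slices). The positive class is axon (code 2); background,
artifact and edge voxels are negatives. On top of the usual accuracy /
precision / recall / F1, two edge-corrected variants subtract EA — edge
voxels predicted positive — from the false positives:

    edge_precision = TP / (TP + FP - EA)
    edge_f1        = 2 · recall · edge_precision / (recall + edge_precision)

so a prediction spilling one voxel past an annotated axon boundary (an
artefact of annotator uncertainty, not of the model) is not penalised.
Any metric with a zero denominator is reported as NaN, never silently 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .labels import AXON, EDGE, UNLABELED


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel counts over annotated voxels; EA = edges predicted positive."""

    tp: int
    tn: int
    fp: int
    fn: int
    ea: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn", "ea"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.ea > self.fp:
            raise ValueError("EA cannot exceed FP (edges are negatives)")

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Six metrics as fractions in [0, 1]; NaN marks an undefined value."""

    accuracy: float
    precision: float
    edge_precision: float
    recall: float
    f1: float
    edge_f1: float

    def as_dict(self, percent: bool = False) -> dict[str, float]:
        scale = 100.0 if percent else 1.0
        return {
            k: (v * scale if math.isfinite(v) else v)
            for k, v in self.__dict__.items()
        }


def confusion_counts(pred: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN/EA comparing a boolean mask to a label volume.

    Only voxels with a nonzero label code are evaluated; altering
    predictions on unlabeled slices can never change any count.
    """
    pred = np.asarray(pred, dtype=bool)
    labels = np.asarray(labels)
    if pred.shape != labels.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape} vs labels {labels.shape}"
        )
    evaluated = labels != UNLABELED
    positive = labels == AXON
    p, t = pred[evaluated], positive[evaluated]
    tp = int(np.count_nonzero(p & t))
    tn = int(np.count_nonzero(~p & ~t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    ea = int(np.count_nonzero(pred & (labels == EDGE)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn, ea=ea)


def _ratio(num: float, den: float) -> float:
    return num / den if den != 0 else math.nan


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Evaluate the six metrics from confusion counts.

    With EA = 0 the edge-corrected metrics coincide with the plain ones;
    with EA > 0 they are never smaller.
    """
    c = counts
    accuracy = _ratio(c.tp + c.tn, c.n_evaluated)
    precision = _ratio(c.tp, c.tp + c.fp)
    edge_precision = _ratio(c.tp, c.tp + c.fp - c.ea)
    recall = _ratio(c.tp, c.tp + c.fn)
    f1 = _f_score(precision, recall)
    edge_f1 = _f_score(edge_precision, recall)
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        edge_precision=edge_precision,
        recall=recall,
        f1=f1,
        edge_f1=edge_f1,
    )


def _f_score(precision: float, recall: float) -> float:
    if not (math.isfinite(precision) and math.isfinite(recall)):
        return math.nan
    return _ratio(2.0 * precision * recall, precision + recall)


def evaluate(pred: np.ndarray, labels: np.ndarray) -> tuple[ConfusionCounts, MetricsReport]:
    """Convenience wrapper: counts plus metrics in one call."""
    counts = confusion_counts(pred, labels)
    return counts, compute_metrics(counts)


def write_report(
    path: str | Path, counts: ConfusionCounts, report: MetricsReport
) -> None:
    """Serialise counts and metrics as JSON (NaN encoded as null)."""
    payload = {
        "counts": {
            "TP": counts.tp,
            "TN": counts.tn,
            "FP": counts.fp,
            "FN": counts.fn,
            "EA": counts.ea,
        },
        "metrics": {
            k: (v if math.isfinite(v) else None)
            for k, v in report.as_dict().items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
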