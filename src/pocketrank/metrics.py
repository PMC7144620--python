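"""Binary-classification metrics for pocket scoring.

Covers the usual confusion-matrix suite (accuracy, TPR/sensitivity,
precision, specificity, MCC), rank-based ROC AUC, and the reconstruction
of integer confusion counts from published summary rates (TPR and
precision together with the class sizes), which lets reported metric rows
be checked for internal consistency.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


@dataclass
class MetricReport:
    accuracy: float
    tpr: float
    precision: float
    specificity: float
    mcc: float
    auc: float | None = None

    @property
    def sensitivity(self) -> float:
        """Alias of TPR."""
        return self.tpr


def confusion(labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5) -> ConfusionCounts:
    """Tally confusion counts, predicting positive at score ≥ threshold."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1 or labels.size < 1:
        raise ValueError("labels and scores must be equal-length 1-d, n >= 1")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be 0/1")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def metric_suite(counts: ConfusionCounts) -> MetricReport:
    """Accuracy, TPR, precision, specificity and MCC from counts.

    Ratios with a zero denominator are reported as NaN; MCC is defined as 0
    when any marginal total is zero (the limit convention).
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricReport(
        accuracy=_ratio(tp + tn, counts.n),
        tpr=_ratio(tp, tp + fn),
        precision=_ratio(tp, tp + fp),
        specificity=_ratio(tn, tn + fp),
        mcc=mcc,
    )


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based (Mann–Whitney) ROC AUC with ties counted one half."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC requires both classes present")
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def counts_from_rates(P: int, N: int, tpr: float, precision: float) -> ConfusionCounts:
    """Reconstruct integer confusion counts from class sizes and rates.

    TP = round(tpr·P); FP = round(TP·(1−precision)/precision); FN and TN
    by complement.  Rounding is to the nearest integer, ties away from
    zero.  Raises when the rates are mutually inconsistent (negative
    counts).
    """
    if not (0 < tpr <= 1 and 0 < precision <= 1):
        raise ValueError("tpr and precision must be in (0, 1]")
    if P <= 0 or N <= 0:
        raise ValueError("class sizes must be positive")
    tp = _round_half_away(tpr * P)
    fp = _round_half_away(tp * (1 - precision) / precision)
    fn = P - tp
    tn = N - fp
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("inconsistent rates: reconstruction yields negative counts")
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def full_report(labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5) -> MetricReport:
    """Threshold metrics plus AUC from raw labels and scores."""
    report = metric_suite(confusion(labels, scores, threshold=threshold))
    report.auc = auc(labels, scores)
    return report


def write_report_tsv(
    rows: dict[str, tuple[MetricReport, int, int]],
    path: str | os.PathLike,
) -> None:
    """Write metric rows (name → (report, pos_size, neg_size)) as TSV with
    the column order AUC, Accuracy, TPR, Precision, MCC, Pos_size, Neg_size."""
    import pandas as pd

    frame = pd.DataFrame(
        [
            {
                "Data set": name,
                "AUC": report.auc,
                "Accuracy": report.accuracy,
                "TPR": report.tpr,
                "Precision": report.precision,
                "MCC": report.mcc,
                "Pos_size": pos,
                "Neg_size": neg,
            }
            for name, (report, pos, neg) in rows.items()
        ]
    )
    frame.to_csv(os.fspath(path), sep="\t", index=False, float_format="%.4f")
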