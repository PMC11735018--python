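"""Performance metrics for trial-level metabolic-cost predictions.

Covers the full reporting suite used for the published model family:
per-partition MSE, Pearson R with its two-sided p-value, prediction
error histograms, accuracy under a +-20 % tolerance band, and
classification-style recall/precision/F1 after a median split of the
measured cost (trials above the median cost form the positive class --
the classes are not defined in the original report, so the median
split is a documented convention here, not an inference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ShapeError, UndefinedMetricError
from .narx import NarxModel, predict_trials
from .preprocess import DatasetSplit
from .synthetic import GaitTrial


@dataclass
class EvaluationReport:
    """All metrics of one trained model on one cohort split.

    ``partitions`` maps 'train'/'validation'/'test'/'all' to dicts with
    keys ``n``, ``mse`` ((W/kg)^2), ``r`` and ``p_value``; correlation
    entries are None for partitions of fewer than 3 trials (recorded in
    ``warnings``).  Classification metrics and the error histogram are
    computed over all trials.
    """

    partitions: dict[str, dict]
    accuracy_pct: float
    recall_pct: float
    precision_pct: float
    f1: float
    histogram: tuple[list[float], list[int]]
    tolerance: float = 0.20
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "partitions": self.partitions,
            "accuracy_pct": self.accuracy_pct,
            "recall_pct": self.recall_pct,
            "precision_pct": self.precision_pct,
            "f1": self.f1,
            "histogram": {
                "bin_edges": self.histogram[0],
                "counts": self.histogram[1],
            },
            "tolerance": self.tolerance,
            "warnings": self.warnings,
        }


def mse(pred: Sequence[float], target: Sequence[float]) -> float:
    """Mean squared prediction error, (W/kg)^2."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape or p.size < 1:
        raise ShapeError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float(np.mean((p - t) ** 2))


def pearson_r(pred: Sequence[float], target: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation and its two-sided p-value.

    The p-value is the exact t-transform ``t = r sqrt((n-2)/(1-r^2))``
    on n-2 degrees of freedom (as implemented by scipy).
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ShapeError(f"shape mismatch: {p.shape} vs {t.shape}")
    if p.size < 3:
        raise UndefinedMetricError("correlation needs at least 3 points")
    if np.ptp(p) == 0 or np.ptp(t) == 0:
        raise UndefinedMetricError("correlation undefined for zero-variance input")
    res = stats.pearsonr(p, t)
    return float(res.statistic), float(res.pvalue)


def tolerance_accuracy(
    pred: Sequence[float], target: Sequence[float], tol: float = 0.20
) -> float:
    """Percentage of trials with |pred - target| <= tol * |target|."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape or p.size < 1:
        raise ShapeError(f"shape mismatch: {p.shape} vs {t.shape}")
    if tol <= 0:
        raise UndefinedMetricError("tolerance must be > 0")
    if np.any(t == 0):
        raise UndefinedMetricError("tolerance accuracy undefined for zero targets")
    within = np.abs(p - t) <= tol * np.abs(t)
    return 100.0 * float(np.mean(within))


def class_metrics(
    pred: Sequence[float], target: Sequence[float]
) -> tuple[float, float, float]:
    """Median-split recall (%), precision (%) and F1 (fraction).

    Both predictions and targets are binarized about the *target*
    median; trials above it are the positive ("high cost") class.
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ShapeError(f"shape mismatch: {p.shape} vs {t.shape}")
    if p.size < 4:
        raise UndefinedMetricError("classification metrics need n >= 4")
    med = float(np.median(t))
    t_pos = t > med
    p_pos = p > med
    if t_pos.all() or not t_pos.any():
        raise UndefinedMetricError("targets fall in a single class")
    tp = int(np.sum(p_pos & t_pos))
    fp = int(np.sum(p_pos & ~t_pos))
    fn = int(np.sum(~p_pos & t_pos))
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return 100.0 * recall, 100.0 * precision, f1


def error_histogram(
    pred: Sequence[float], target: Sequence[float], n_bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of prediction errors ``e = target - pred``.

    Uniform bins span [min(e), max(e)]; the counts always sum to the
    number of trials.
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape or p.size < 1:
        raise ShapeError(f"shape mismatch: {p.shape} vs {t.shape}")
    if n_bins < 1:
        raise UndefinedMetricError("need at least one bin")
    e = t - p
    lo, hi = float(e.min()), float(e.max())
    if lo == hi:  # degenerate spread: one bin holds everything
        hi = lo + 1e-12
    counts, edges = np.histogram(e, bins=n_bins, range=(lo, hi))
    return edges, counts


def evaluate_model(
    model: NarxModel,
    split: DatasetSplit,
    trials: Sequence[GaitTrial],
    tol: float = 0.20,
    n_bins: int = 20,
) -> EvaluationReport:
    """Full metric suite for a trained model on a partitioned cohort."""
    by_id = {t.trial_id: t for t in trials}
    order = split.train_ids + split.validation_ids + split.test_ids
    preds = predict_trials(model, [by_id[i] for i in order])
    targets = np.array([by_id[i].met_cost for i in order])
    pred_of = dict(zip(order, preds))

    warnings: list[str] = []
    partitions: dict[str, dict] = {}
    groups = {
        "train": split.train_ids,
        "validation": split.validation_ids,
        "test": split.test_ids,
        "all": order,
    }
    for name, ids in groups.items():
        p = np.array([pred_of[i] for i in ids])
        t = np.array([by_id[i].met_cost for i in ids])
        entry: dict = {"n": len(ids), "mse": mse(p, t) if len(ids) else None}
        if len(ids) >= 3 and np.ptp(t) > 0:
            r, pv = pearson_r(p, t)
            entry["r"], entry["p_value"] = r, pv
        else:
            entry["r"] = entry["p_value"] = None
            warnings.append(f"correlation omitted for partition {name!r} (n={len(ids)})")
        partitions[name] = entry

    recall, precision, f1 = class_metrics(preds, targets)
    edges, counts = error_histogram(preds, targets, n_bins=n_bins)
    return EvaluationReport(
        partitions=partitions,
        accuracy_pct=tolerance_accuracy(preds, targets, tol=tol),
        recall_pct=recall,
        precision_pct=precision,
        f1=f1,
        histogram=(edges.tolist(), counts.tolist()),
        tolerance=tol,
        warnings=warnings,
    )
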