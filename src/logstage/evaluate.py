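"""Staging evaluation: accuracy/sensitivity/specificity, ROC/AUC, k-fold CV.

Metrics follow the standard confusion-matrix definitions,

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    balanced    = (sensitivity + specificity) / 2,

computed one-vs-rest per stage at the image level.  A metric with a zero
denominator is reported as NaN (an explicit "undefined" marker, never a
silent 0); balanced accuracy averages over the defined parts.  ROC curves
sweep the unique score thresholds with trapezoidal AUC, which equals the
normalized Mann-Whitney U statistic (tie pairs counted half).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .imaging_io import DatasetManifest

__all__ = [
    "BinaryMetrics", "MetricsReport", "binary_metrics", "stage_metrics",
    "roc_curve", "kfold_split",
]

STAGES = (1, 2, 3, 4)


@dataclass(frozen=True)
class BinaryMetrics:
    accuracy: float
    sensitivity: float  # NaN when no positives in truth
    specificity: float  # NaN when no negatives in truth
    balanced_accuracy: float

    def defined(self) -> dict[str, float]:
        return {k: v for k, v in self.__dict__.items() if not math.isnan(v)}


def binary_metrics(tp: int, tn: int, fp: int, fn: int) -> BinaryMetrics:
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("all counts are zero")
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    parts = [v for v in (sensitivity, specificity) if not math.isnan(v)]
    balanced = float(np.mean(parts)) if parts else float("nan")
    return BinaryMetrics(accuracy, sensitivity, specificity, balanced)


@dataclass
class MetricsReport:
    """Per-stage one-vs-rest metrics plus confusion matrix and macro means."""

    per_stage: dict[int, dict[str, float]]
    confusion: np.ndarray  # 4x4 counts, rows = truth stage, cols = predicted
    macro: dict[str, float]
    roc: dict[int, list[tuple[float, float]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_stage": {f"T{s}": m for s, m in self.per_stage.items()},
            "confusion": self.confusion.astype(int).tolist(),
            "macro": self.macro,
            "roc": {f"T{s}": pts for s, pts in self.roc.items()},
        }


def _as_predictions(predicted: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    """Accept either hard stages (N,) or probability rows (N, 4)."""
    arr = np.asarray(predicted)
    if arr.ndim == 2:
        if arr.shape[1] != 4:
            raise ValueError(f"probability rows must have 4 columns, got {arr.shape}")
        return arr.argmax(axis=1) + 1, arr
    return arr.astype(int), None


def stage_metrics(truth, predicted) -> MetricsReport:
    """One-vs-rest metrics per stage; AUC/ROC when probabilities are given."""
    truth = np.asarray(truth, dtype=int)
    pred, probs = _as_predictions(predicted)
    if truth.shape != pred.shape:
        raise ValueError(f"length mismatch: {truth.shape} vs {pred.shape}")
    if not np.all(np.isin(truth, STAGES)):
        raise ValueError("truth stages must be in {1,2,3,4}")

    confusion = np.zeros((4, 4))
    for t, p in zip(truth, pred):
        confusion[t - 1, p - 1] += 1

    per_stage: dict[int, dict[str, float]] = {}
    roc_pts: dict[int, list[tuple[float, float]]] = {}
    for s in STAGES:
        pos_t, pos_p = truth == s, pred == s
        bm = binary_metrics(
            tp=int(np.sum(pos_t & pos_p)), tn=int(np.sum(~pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)), fn=int(np.sum(pos_t & ~pos_p)),
        )
        entry = dict(bm.__dict__)
        if probs is not None and 0 < pos_t.sum() < len(truth):
            pts, auc = roc_curve(pos_t.astype(int), probs[:, s - 1])
            entry["auc"] = auc
            roc_pts[s] = pts
        per_stage[s] = entry

    keys = set().union(*(m.keys() for m in per_stage.values()))
    macro = {}
    for key in sorted(keys):
        vals = [m[key] for m in per_stage.values() if key in m and not math.isnan(m[key])]
        macro[key] = float(np.mean(vals)) if vals else float("nan")
    return MetricsReport(per_stage=per_stage, confusion=confusion, macro=macro, roc=roc_pts)


def roc_curve(truth, scores) -> tuple[list[tuple[float, float]], float]:
    """ROC by sweeping unique score thresholds; returns (points, AUC).

    Points run from (0,0) to (1,1), non-decreasing in both coordinates;
    tied scores enter as a single diagonal segment, so the trapezoidal AUC
    matches the tie-averaged Mann-Whitney statistic.
    """
    truth = np.asarray(truth).astype(int)
    scores = np.asarray(scores, dtype=float)
    if truth.shape != scores.shape:
        raise ValueError("truth and scores must have equal length")
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present in truth")
    pts = [(0.0, 0.0)]
    for thr in np.unique(scores)[::-1]:
        pred = scores >= thr
        tpr = float(np.sum(pred & (truth == 1)) / n_pos)
        fpr = float(np.sum(pred & (truth == 0)) / n_neg)
        pts.append((fpr, tpr))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    auc = float(np.trapezoid(ys, xs))
    return pts, auc


def kfold_split(
    manifest: DatasetManifest,
    k: int = 10,
    seed: int = 0,
    group_by_patient: bool = True,
) -> list[tuple[list[str], list[str]]]:
    """Seeded k-fold partition of manifest paths into (train, test) lists.

    With ``group_by_patient`` all images of a patient land on the same side
    of every fold (patients are shuffled and dealt greedily to the smallest
    fold), so generalization is measured across patients, not slices.
    """
    n = len(manifest)
    if group_by_patient:
        groups: dict[str, list[str]] = {}
        for r in manifest.records:
            groups.setdefault(r.patient_id, []).append(r.path)
        units = sorted(groups)
        if k > len(units):
            raise ValueError(f"k={k} exceeds number of patients {len(units)}")
        rng = np.random.default_rng(seed)
        order = [units[i] for i in rng.permutation(len(units))]
        # deal largest-first to the currently smallest fold for balance
        order.sort(key=lambda u: -len(groups[u]))
        folds: list[list[str]] = [[] for _ in range(k)]
        for u in order:
            folds[min(range(k), key=lambda i: len(folds[i]))].extend(groups[u])
    else:
        if k > n:
            raise ValueError(f"k={k} exceeds number of items {n}")
        rng = np.random.default_rng(seed)
        paths = [manifest.records[i].path for i in rng.permutation(n)]
        folds = [list(f) for f in np.array_split(paths, k)]

    all_paths = {r.path for r in manifest.records}
    out = []
    for i in range(k):
        test = sorted(folds[i])
        train = sorted(all_paths - set(test))
        out.append((train, test))
    return out
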