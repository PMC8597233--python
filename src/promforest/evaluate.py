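"""Evaluation of promoter predictions against ground-truth coordinates.

Three assessment modes:

* **OVERLAP** — a scan window counts as a true positive only if it shares
  at least 10% of its length (>= 4 bp of a 40-nt window) with a truth
  promoter on the same contig and strand (the `intersect -s -f 0.1`
  semantics, re-implemented natively).

* **CLUSTER** — for each truth promoter, its k=5 nearest prediction
  windows (gap distance, overlap => 0, strand-blind) lying strictly
  within 100 nt are true positives; every other retained prediction is a
  false positive.  This credits predictions in the neighbourhood of a
  promoter without demanding exact coordinates.

* **BALANCED** — plain per-sequence classification of a labelled
  (typically 1:1) set, with MCC and accuracy at probability 0.5.

PR areas use step-wise (right-constant precision) integration; ROC areas
use the trapezoid rule.  A random classifier's expected AUPRC equals the
positive prevalence — on a whole genome with thousands of promoters and
~10^7 windows that baseline is of order 1e-4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .dataset import LabeledSequenceSet, deduplicate_intervals
from .genome_io import GenomicInterval
from .scanner import PredictionRecord

if TYPE_CHECKING:  # pragma: no cover
    from .model import TrainedModel

DEFAULT_MIN_OVERLAP_FRAC = 0.1
DEFAULT_CLUSTER_MAX_DIST = 100
DEFAULT_CLUSTER_K = 5


class MetricError(ValueError):
    """Metrics are undefined for the given inputs (e.g. one class only)."""


@dataclass
class GroundTruth:
    """Deduplicated actual-promoter intervals."""

    promoters: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.promoters = deduplicate_intervals(self.promoters)

    def __len__(self) -> int:
        return len(self.promoters)


@dataclass
class EvalResult:
    mode: str  # OVERLAP | CLUSTER | BALANCED
    pr_points: list[tuple[float, float]]  # (recall, precision)
    roc_points: list[tuple[float, float]]  # (fpr, tpr)
    auprc: float
    auroc: float
    n_pos: int
    n_total: int


@dataclass
class BalancedReport:
    result: EvalResult
    mcc: float
    accuracy: float


def random_baseline_auprc(n_pos: int, n_total: int) -> float:
    """Expected AUPRC of a random classifier = positive prevalence."""
    if n_total <= 0 or n_pos < 0 or n_pos > n_total:
        raise ValueError("need 0 <= n_pos <= n_total with n_total > 0")
    return n_pos / n_total


# --- overlap labelling ------------------------------------------------------

def label_by_overlap(
    windows: Sequence[GenomicInterval],
    truth: GroundTruth,
    min_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
) -> np.ndarray:
    """1 where a window shares >= ceil(min_frac * window.length) bp with a
    same-strand, same-contig truth interval; else 0."""
    if not (0.0 < min_frac <= 1.0):
        raise ValueError("min_frac must be in (0, 1]")
    truth_by_group: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for key in {(t.contig, t.strand) for t in truth.promoters}:
        group = [t for t in truth.promoters if (t.contig, t.strand) == key]
        truth_by_group[key] = (
            np.array([t.start for t in group]),
            np.array([t.end for t in group]),
        )
    labels = np.zeros(len(windows), dtype=np.int64)
    # group window indices so each group is labelled with one broadcast
    win_groups: dict[tuple[str, str], list[int]] = {}
    for i, w in enumerate(windows):
        win_groups.setdefault((w.contig, w.strand), []).append(i)
    for key, idxs in win_groups.items():
        if key not in truth_by_group:
            continue
        t_start, t_end = truth_by_group[key]
        w_start = np.array([windows[i].start for i in idxs])
        w_end = np.array([windows[i].end for i in idxs])
        need = np.ceil(min_frac * (w_end - w_start)).astype(np.int64)
        for lo in range(0, len(idxs), 8192):
            sl = slice(lo, lo + 8192)
            ov = np.minimum(w_end[sl, None], t_end[None, :]) - np.maximum(
                w_start[sl, None], t_start[None, :]
            )
            hit = (ov.max(axis=1) >= need[sl]) if ov.size else np.zeros(0, bool)
            labels[np.asarray(idxs)[sl][hit]] = 1
    return labels


# --- cluster labelling ------------------------------------------------------

def _interval_gap(a_start, a_end, b_start, b_end):
    """Base-pair gap between half-open intervals; overlap or adjacency => 0."""
    return np.maximum(np.maximum(b_start - a_end, a_start - b_end), 0)


def _cluster_flags(
    pred_ivs: Sequence[GenomicInterval],
    truth: GroundTruth,
    max_dist: int,
    k: int,
) -> tuple[np.ndarray, int]:
    """TP flag per prediction plus the number of truth intervals matched.

    For each truth interval, the k nearest predictions (gap distance,
    ties by leftmost start) strictly within max_dist are TPs; a
    prediction marked by any truth is a TP once.  Strand-blind.
    """
    n = len(pred_ivs)
    tp = np.zeros(n, dtype=bool)
    by_contig: dict[str, list[int]] = {}
    for i, iv in enumerate(pred_ivs):
        by_contig.setdefault(iv.contig, []).append(i)
    arrays = {}
    for contig, idxs in by_contig.items():
        order = sorted(idxs, key=lambda i: pred_ivs[i].start)
        starts = np.array([pred_ivs[i].start for i in order])
        ends = np.array([pred_ivs[i].end for i in order])
        arrays[contig] = (np.asarray(order), starts, ends)
    max_len = max((iv.length for iv in pred_ivs), default=0)
    matched = 0
    for t in truth.promoters:
        if t.contig not in arrays:
            continue
        order, starts, ends = arrays[t.contig]
        lo = np.searchsorted(starts, t.start - max_dist - max_len, side="left")
        hi = np.searchsorted(starts, t.end + max_dist, side="right")
        if hi <= lo:
            continue
        gaps = _interval_gap(starts[lo:hi], ends[lo:hi], t.start, t.end)
        near = np.flatnonzero(gaps < max_dist)
        if near.size == 0:
            continue
        # k nearest with ties broken by leftmost start (starts are sorted,
        # so a stable sort on gap preserves left-to-right order)
        chosen = near[np.argsort(gaps[near], kind="stable")][:k]
        tp[order[lo:hi][chosen]] = True
        matched += 1
    return tp, matched


def label_by_cluster(
    predictions: Sequence[PredictionRecord],
    truth: GroundTruth,
    max_dist: int = DEFAULT_CLUSTER_MAX_DIST,
    k: int = DEFAULT_CLUSTER_K,
) -> np.ndarray:
    """Boolean TP flag per prediction under the cluster criterion."""
    if max_dist < 0 or k < 1:
        raise ValueError("need max_dist >= 0 and k >= 1")
    flags, _ = _cluster_flags([p.window for p in predictions], truth, max_dist, k)
    return flags


# --- PR / ROC ---------------------------------------------------------------

def pr_roc(labels: Sequence[int], scores: Sequence[float], mode: str = "BALANCED") -> EvalResult:
    """PR and ROC curves with step-wise AUPRC and trapezoidal AUROC."""
    y = np.asarray(labels, dtype=np.int64)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have the same length")
    if len(np.unique(y)) < 2:
        raise MetricError("both classes must be present to compute PR/ROC")
    precision, recall, _ = precision_recall_curve(y, s)
    fpr, tpr, _ = roc_curve(y, s)
    return EvalResult(
        mode=mode,
        pr_points=list(zip(recall.tolist(), precision.tolist())),
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        auprc=float(average_precision_score(y, s)),
        auroc=float(roc_auc_score(y, s)),
        n_pos=int(y.sum()),
        n_total=int(y.size),
    )


# --- genome-wide assessment -------------------------------------------------

def evaluate_genome_wide(
    predictions: Sequence[PredictionRecord],
    truth: GroundTruth,
    mode: str = "OVERLAP",
    min_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
    max_dist: int = DEFAULT_CLUSTER_MAX_DIST,
    k: int = DEFAULT_CLUSTER_K,
    n_thresholds: int = 200,
) -> EvalResult:
    """Score a genome scan against truth promoters.

    OVERLAP labels every window once and sweeps all score thresholds.
    CLUSTER re-runs the k-nearest matching at each threshold of a
    ``n_thresholds``-quantile score grid; recall = matched truths /
    |truth|, and the ROC false-positive denominator is (all windows -
    |truth|).
    """
    mode = mode.upper()
    if len(truth) == 0:
        raise MetricError("ground truth is empty")
    if not predictions:
        raise MetricError("no predictions to evaluate")
    scores = np.array([p.probability for p in predictions])
    if mode == "OVERLAP":
        labels = label_by_overlap([p.window for p in predictions], truth, min_frac)
        return pr_roc(labels, scores, mode="OVERLAP")
    if mode != "CLUSTER":
        raise ValueError(f"unknown mode {mode!r}; expected OVERLAP or CLUSTER")

    qs = np.unique(np.quantile(scores, np.linspace(0.0, 1.0, n_thresholds)))
    thresholds = qs[::-1]  # descending: recall grows monotonically
    pred_ivs = [p.window for p in predictions]
    n_truth = len(truth)
    neg_denom = max(len(predictions) - n_truth, 1)

    pr_points: list[tuple[float, float]] = []
    roc_points: list[tuple[float, float]] = [(0.0, 0.0)]
    auprc = 0.0
    prev_recall = 0.0
    for tau in thresholds:
        keep = np.flatnonzero(scores >= tau)
        flags, matched = _cluster_flags(
            [pred_ivs[i] for i in keep], truth, max_dist, k
        )
        tp = int(flags.sum())
        fp = int(keep.size - tp)
        precision = tp / keep.size if keep.size else 1.0
        recall = matched / n_truth
        pr_points.append((recall, precision))
        roc_points.append((fp / neg_denom, recall))
        auprc += (recall - prev_recall) * precision
        prev_recall = recall

    roc = np.array(sorted(roc_points))
    auroc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
    return EvalResult(
        mode="CLUSTER",
        pr_points=pr_points,
        roc_points=[tuple(p) for p in roc_points],
        auprc=float(auprc),
        auroc=auroc,
        n_pos=n_truth,
        n_total=len(predictions),
    )


# --- balanced-set assessment ------------------------------------------------

def matthews_corrcoef_safe(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """MCC with the 0/0 -> 0 convention for degenerate confusion tables."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def evaluate_balanced(model: "TrainedModel", ds: LabeledSequenceSet) -> BalancedReport:
    """Per-sequence classification metrics on a labelled set.

    PR/ROC over the predicted probabilities plus MCC and accuracy at the
    0.5 probability threshold.
    """
    from .model import predict_proba  # local import: avoids a cycle

    y = ds.labels
    probs = predict_proba(model, ds.sequences)
    result = pr_roc(y, probs, mode="BALANCED")
    y_hat = (probs >= 0.5).astype(np.int64)
    return BalancedReport(
        result=result,
        mcc=matthews_corrcoef_safe(y, y_hat),
        accuracy=float(np.mean(y_hat == y)),
    )
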