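"""Scoring of predicted against true network topologies.

Evaluation treats topology comparison as binary classification over the
N(N-1)/2 unordered node pairs (the diagonal is excluded: self-regulation
is never inferred).  Besides recall, precision and the Matthews
correlation coefficient

    MCC = (TP*TN - FP*FN) /
          sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

the module builds threshold-sweep curves: the classical precision-recall
curve and the MCC-recall (MR) curve, whose area is a threshold-free
performance summary with 0 at chance level and 1 for a perfect scorer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .inference import CorrelationMatrix, StrengthMode, interaction_strength
from .topology import AdjacencyMatrix

logger = logging.getLogger(__name__)


class ConfusionCounts(NamedTuple):
    """Pair-level confusion counts; TP+FP+TN+FN == N(N-1)/2."""

    tp: int
    fp: int
    tn: int
    fn: int


def confusion(true_adj: AdjacencyMatrix, pred_adj: AdjacencyMatrix) -> ConfusionCounts:
    """Count TP/FP/TN/FN over unordered node pairs (diagonal excluded)."""
    if true_adj.n_nodes != pred_adj.n_nodes:
        raise ValueError(
            f"size mismatch: truth has {true_adj.n_nodes} nodes, "
            f"prediction has {pred_adj.n_nodes}"
        )
    iu = np.triu_indices(true_adj.n_nodes, k=1)
    t = true_adj.entries[iu].astype(bool)
    p = pred_adj.entries[iu].astype(bool)
    return ConfusionCounts(
        tp=int((t & p).sum()),
        fp=int((~t & p).sum()),
        tn=int((~t & ~p).sum()),
        fn=int((t & ~p).sum()),
    )


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); 0 when there are no true links."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); 0 when nothing is predicted."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else 0.0


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


@dataclass
class EvalCurve:
    """Threshold sweep of (recall, precision, MCC) with recall-integrated AUCs."""

    thresholds: np.ndarray
    recalls: np.ndarray
    precisions: np.ndarray
    mccs: np.ndarray
    auc_pr: float
    auc_mr: float


def _auc_over_recall(recalls: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal area of ``values`` against recall on [0, 1].

    Points are sorted by recall, duplicate-recall values averaged, and
    the curve anchored at recall 0 and 1 by carrying the nearest
    computed value.
    """
    order = np.argsort(recalls)
    r = recalls[order]
    v = values[order]
    uniq_r: list[float] = []
    uniq_v: list[float] = []
    i = 0
    while i < len(r):
        j = i
        while j < len(r) and r[j] == r[i]:
            j += 1
        uniq_r.append(float(r[i]))
        uniq_v.append(float(v[i:j].mean()))
        i = j
    if uniq_r[0] > 0.0:
        uniq_r.insert(0, 0.0)
        uniq_v.insert(0, uniq_v[0])
    if uniq_r[-1] < 1.0:
        uniq_r.append(1.0)
        uniq_v.append(uniq_v[-1])
    return float(np.trapezoid(uniq_v, uniq_r))


def curve(
    true_adj: AdjacencyMatrix,
    scores: CorrelationMatrix,
    n_thresholds: int = 100,
    mode: StrengthMode = "max",
) -> EvalCurve:
    """Sweep the binarization threshold and record (recall, precision, MCC).

    Thresholds are evenly spaced from 0 up to (excluding) the maximum
    observed pair strength; at each, the score matrix is binarized
    (strict inequality) and scored against the truth.  The maximum
    itself is excluded because a strict cut there predicts the empty
    network for every scorer, which would pin each curve to the
    uninformative point (recall 0, MCC 0); a perfect scorer thus
    integrates to area 1.  AUCs integrate over recall by the
    trapezoidal rule.  An all-zero score matrix yields a degenerate
    single-point curve with both AUCs 0.
    """
    if n_thresholds < 2:
        raise ValueError("n_thresholds must be >= 2")
    if true_adj.n_nodes != scores.n_genes:
        raise ValueError("truth and scores must have the same size")
    s = interaction_strength(scores, mode=mode)
    iu = np.triu_indices(true_adj.n_nodes, k=1)
    strengths = s[iu]
    truths = true_adj.entries[iu].astype(bool)
    s_max = float(strengths.max(initial=0.0))
    if s_max == 0.0:
        logger.warning("all-zero score matrix: degenerate single-point curve")
        c = _counts_at(strengths, truths, 0.0)
        return EvalCurve(
            thresholds=np.array([0.0]),
            recalls=np.array([recall(c)]),
            precisions=np.array([precision(c)]),
            mccs=np.array([mcc(c)]),
            auc_pr=0.0,
            auc_mr=0.0,
        )
    ts = np.linspace(0.0, s_max, n_thresholds, endpoint=False)
    rec = np.empty(n_thresholds)
    prec = np.empty(n_thresholds)
    mc = np.empty(n_thresholds)
    for k, t in enumerate(ts):
        c = _counts_at(strengths, truths, t)
        rec[k] = recall(c)
        prec[k] = precision(c)
        mc[k] = mcc(c)
    return EvalCurve(
        thresholds=ts,
        recalls=rec,
        precisions=prec,
        mccs=mc,
        auc_pr=_auc_over_recall(rec, prec),
        auc_mr=_auc_over_recall(rec, mc),
    )


def _counts_at(strengths: np.ndarray, truths: np.ndarray, t: float) -> ConfusionCounts:
    pred = strengths > t
    return ConfusionCounts(
        tp=int((truths & pred).sum()),
        fp=int((~truths & pred).sum()),
        tn=int((~truths & ~pred).sum()),
        fn=int((truths & ~pred).sum()),
    )


def grid_search_threshold(
    true_adj: AdjacencyMatrix,
    scores: CorrelationMatrix,
    grid: Sequence[float] | None = None,
    mode: StrengthMode = "max",
) -> tuple[float, float]:
    """Pick the binarization threshold maximising MCC against a truth.

    Evaluates every grid value (default 0.00 to 1.00 in steps of 0.01)
    and returns ``(best_threshold, best_mcc)``; ties break toward the
    smallest threshold.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
    grid = sorted(float(t) for t in grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    s = interaction_strength(scores, mode=mode)
    iu = np.triu_indices(true_adj.n_nodes, k=1)
    strengths = s[iu]
    truths = true_adj.entries[iu].astype(bool)
    best_t, best_m = grid[0], -2.0
    for t in grid:
        m = mcc(_counts_at(strengths, truths, t))
        if m > best_m:
            best_t, best_m = t, m
    return best_t, best_m
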