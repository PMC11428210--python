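"""Tolerance-window scoring of predicted vs. true state sequences.

Segmentation quality is judged frame-wise, one state against the rest, but S1
and S2 predictions are credited within a tolerance window (100 ms for S1,
80 ms for S2): a predicted S1/S2 interval whose onset lies within the window
of a true interval of the same state counts as correct even if shifted.
Matching operates on interval onsets (nearest true interval), never on
isolated frames, so a prediction shifted past the window scores both a miss
(FN) and a false alarm (FP).

Metrics per state: Acc = (TP+TN)/N, Se = TP/(TP+FN), F1 = 2*Se*P/(Se+P).
Precision has two modes: ``conventional`` P = TP/(TP+FP) (the default, and the
way F1 is normally formed) and ``printed`` P = TN/(TN+FP), the literal formula
in the source metric suite (which is specificity under standard nomenclature).
Macro metrics are unweighted means over the four states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import STATE_NAMES
from .state_decoding import StateSequence, runs

logger = logging.getLogger(__name__)

DEFAULT_TOL_MS = {"S1": 100.0, "S2": 80.0}


@dataclass
class ConfusionCounts:
    """Per-state one-vs-rest counts plus the raw 4x4 frame confusion matrix."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    matrix: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))

    def __post_init__(self):
        for arr in (self.tp, self.fp, self.tn, self.fn):
            if np.any(np.asarray(arr) < 0):
                raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            tn=self.tn + other.tn,
            fn=self.fn + other.fn,
            matrix=self.matrix + other.matrix,
        )


@dataclass
class MetricSet:
    """Acc/Se/P/F1 per state plus macro averages, all fractions in [0, 1]."""

    per_state: dict
    macro: dict

    def __getitem__(self, key):
        return self.macro[key]


def _intervals_of(labels: np.ndarray, state: int):
    return [(s, e) for s, e, lab in runs(labels) if lab == state]


def tolerance_match(
    pred: StateSequence,
    truth: StateSequence,
    tol_s1_ms: float = DEFAULT_TOL_MS["S1"],
    tol_s2_ms: float = DEFAULT_TOL_MS["S2"],
) -> ConfusionCounts:
    """One-vs-rest frame counts with onset-tolerance crediting for S1 and S2.

    For S1 (S2), a predicted interval is matched when its onset lies within
    ``tol_s1_ms`` (``tol_s2_ms``) of the onset of some true interval of the
    same state; matched predicted frames count as TP and matched true
    intervals contribute no FN. Unmatched predicted intervals are FP frames,
    unmatched true intervals FN frames. Systole and diastole are scored by
    plain frame agreement. Sequences of unequal length are truncated to the
    shorter with a warning.
    """
    if pred.frame_rate != truth.frame_rate:
        raise ValueError(
            f"frame rates differ: {pred.frame_rate} vs {truth.frame_rate}"
        )
    p, t = pred.labels, truth.labels
    if len(p) != len(t):
        logger.warning("length mismatch (%d vs %d); truncating", len(p), len(t))
        n = min(len(p), len(t))
        p, t = p[:n], t[:n]
    n = len(p)
    fr = pred.frame_rate
    tol_frames = {
        0: tol_s1_ms / 1000.0 * fr,
        2: tol_s2_ms / 1000.0 * fr,
    }

    tp = np.zeros(4)
    fp = np.zeros(4)
    fn = np.zeros(4)
    for state in range(4):
        pred_mask = p == state
        true_mask = t == state
        if state in (1, 3):  # systole / diastole: plain frame-wise counting
            tp[state] = np.sum(pred_mask & true_mask)
            fp[state] = np.sum(pred_mask & ~true_mask)
            fn[state] = np.sum(~pred_mask & true_mask)
            continue
        tol = tol_frames[state]
        pred_ivs = _intervals_of(p, state)
        true_ivs = _intervals_of(t, state)
        true_onsets = np.array([s for s, _ in true_ivs], dtype=float)
        pred_onsets = np.array([s for s, _ in pred_ivs], dtype=float)
        for s, e in pred_ivs:
            matched = len(true_onsets) > 0 and np.min(np.abs(true_onsets - s)) <= tol
            if matched:
                tp[state] += e - s
            else:
                fp[state] += e - s
        for s, e in true_ivs:
            matched = len(pred_onsets) > 0 and np.min(np.abs(pred_onsets - s)) <= tol
            if not matched:
                fn[state] += e - s
    tn = n - tp - fp - fn
    tn = np.maximum(tn, 0.0)

    matrix = np.zeros((4, 4))
    np.add.at(matrix, (t, p), 1.0)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, matrix=matrix)


def frame_counts(pred: StateSequence, truth: StateSequence) -> ConfusionCounts:
    """Plain frame-wise one-vs-rest counts (no tolerance credit for any state).

    This is the strict frame agreement metric; S1/S2 boundary shifts inside
    the tolerance windows still count as errors here.
    """
    if pred.frame_rate != truth.frame_rate:
        raise ValueError("frame rates differ")
    if len(pred) != len(truth):
        raise ValueError("sequences must have equal length")
    p, t = pred.labels, truth.labels
    matrix = np.zeros((4, 4))
    np.add.at(matrix, (t, p), 1.0)
    tp = np.diag(matrix).astype(float)
    fp = matrix.sum(axis=0) - tp
    fn = matrix.sum(axis=1) - tp
    tn = len(p) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, matrix=matrix)


def _safe_div(num, den):
    if den <= 0:
        logger.warning("zero denominator in metric; defining value as 0")
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts, precision_mode: str = "conventional") -> MetricSet:
    """Acc/Se/P/F1 per state and macro-averaged from one-vs-rest counts."""
    if precision_mode not in ("conventional", "printed"):
        raise ValueError("precision_mode must be 'conventional' or 'printed'")
    per_state = {}
    for i, name in enumerate(STATE_NAMES):
        tp, fp, tn, fn = counts.tp[i], counts.fp[i], counts.tn[i], counts.fn[i]
        acc = _safe_div(tp + tn, tp + fp + tn + fn)
        se = _safe_div(tp, tp + fn)
        if precision_mode == "printed":
            p = _safe_div(tn, tn + fp)
        else:
            p = _safe_div(tp, tp + fp)
        f1 = _safe_div(2.0 * se * p, se + p) if (se + p) > 0 else 0.0
        per_state[name] = {"Acc": acc, "Se": se, "P": p, "F1": f1}
    macro = {
        key: float(np.mean([per_state[name][key] for name in STATE_NAMES]))
        for key in ("Acc", "Se", "P", "F1")
    }
    return MetricSet(per_state=per_state, macro=macro)


def confusion_matrix(pred: StateSequence, truth: StateSequence) -> np.ndarray:
    """Row-normalized 4x4 frame confusion matrix (rows = truth, cols = prediction).

    Rows for states absent from the truth are left as zeros.
    """
    if len(pred) != len(truth):
        raise ValueError("sequences must have equal length")
    matrix = np.zeros((4, 4))
    np.add.at(matrix, (truth.labels, pred.labels), 1.0)
    sums = matrix.sum(axis=1, keepdims=True)
    out = np.divide(matrix, sums, out=np.zeros_like(matrix), where=sums > 0)
    return out


def evaluate_records(
    pairs,
    tol_s1_ms: float = DEFAULT_TOL_MS["S1"],
    tol_s2_ms: float = DEFAULT_TOL_MS["S2"],
    precision_mode: str = "conventional",
):
    """Pool tolerance-window counts over (pred, truth) record pairs, then score.

    Counts are pooled across records (micro across records) and metrics are
    macro-averaged across the four states, so aggregation is independent of
    record order.
    """
    total = None
    for pred, truth in pairs:
        c = tolerance_match(pred, truth, tol_s1_ms, tol_s2_ms)
        total = c if total is None else total + c
    if total is None:
        raise ValueError("no record pairs supplied")
    return compute_metrics(total, precision_mode), total
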