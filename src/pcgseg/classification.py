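"""Random-forest multi-classification of cycle fragments and the cycle-count sweep.

A fragment of N cardiac cycles is summarized by its 78-dim MFCC statistics
vector, reduced by PCA and classified as normal / ASD / VSD by a 100-tree
random forest. ``cross_validate_cycles`` re-runs the whole chain for each
cycle count with six-fold cross-validation, splitting folds at the RECORDING
level so overlapping fragments of one recording can never appear on both
sides of a fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features_mfcc import MelFilterbank, fragment_feature_vector, pca_fit_transform
from .io_preprocess import Signal
from .state_decoding import fragment_by_cycles
from .synthetic_pcg import CLASSES

MIN_FRAGMENT_FRAMES = 2  # a fragment must span at least two analysis frames


@dataclass(frozen=True)
class ClassifiedRecord:
    """One fragment's classification outcome within a CV run."""

    fragment_id: str
    true_class: str
    pred_class: str
    n_cycles: int
    fold: int

    def __post_init__(self):
        if self.true_class not in CLASSES or self.pred_class not in CLASSES:
            raise ValueError("classes must come from the fixed label set")
        if self.fold < 1:
            raise ValueError("fold indices are 1-based")


@dataclass
class SweepResult:
    """Per-cycle-count metrics table mirroring the cycle-sweep experiment."""

    table: pd.DataFrame  # columns: cycle, Acc, Se, F1, F1_ASD, F1_VSD, F1_normal

    def f1_at(self, n_cycles: int) -> float:
        row = self.table[self.table["cycle"] == n_cycles]
        if row.empty:
            raise KeyError(f"no sweep row for n_cycles={n_cycles}")
        return float(row["F1"].iloc[0])


def train_rf(X: np.ndarray, y, n_trees: int = 100, seed: int = 0) -> RandomForestClassifier:
    """Fit the 100-tree random forest (deterministic given the seed)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    model.fit(np.asarray(X, dtype=float), y)
    return model


def evaluate_multiclass(records) -> dict:
    """Macro Se/P/F1 + overall and macro (balanced) accuracy over fragments.

    Macro accuracy is the unweighted mean of per-class recall; with exactly
    balanced class counts it coincides with overall accuracy identically.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to evaluate")
    y_true = np.array([r.true_class for r in records])
    y_pred = np.array([r.pred_class for r in records])
    present = [c for c in CLASSES if np.any(y_true == c)]
    per_class = {}
    for cls in present:
        tp = np.sum((y_true == cls) & (y_pred == cls))
        fp = np.sum((y_true != cls) & (y_pred == cls))
        fn = np.sum((y_true == cls) & (y_pred != cls))
        se = tp / (tp + fn) if tp + fn else 0.0
        p = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * se * p / (se + p) if se + p else 0.0
        per_class[cls] = {"Se": se, "P": p, "F1": f1}
    overall_acc = float(np.mean(y_true == y_pred))
    macro = {
        key: float(np.mean([per_class[c][key] for c in present]))
        for key in ("Se", "P", "F1")
    }
    macro["Acc"] = float(np.mean([per_class[c]["Se"] for c in present]))
    return {
        "overall_accuracy": overall_acc,
        "macro": macro,
        "per_class": per_class,
    }


def _record_fragments(record, n_cycles: int):
    """Ground-truth-label fragments of one simulated record."""
    from .state_decoding import StateSequence, extract_cycles

    sig: Signal = record.signal
    # cycles from the exact interval labels: S1 onset to next S1 onset
    s1_starts = [s for s, _, st in record.labels if st == "S1"]
    cycles = [(s1_starts[i], s1_starts[i + 1]) for i in range(len(s1_starts) - 1)]
    return fragment_by_cycles(sig, cycles, n_cycles, events=record.labels)


def build_fragment_table(records, n_cycles: int, bank: MelFilterbank | None = None):
    """Feature matrix + metadata for all ``n_cycles``-cycle fragments.

    Returns ``(X, y, groups, ids)`` where ``groups`` ties each fragment to its
    source recording for leakage-safe fold assignment.
    """
    X, y, groups, ids = [], [], [], []
    for rec in records:
        rate = rec.signal.rate
        if bank is None:
            bank = MelFilterbank(rate=rate)
        for j, frag in enumerate(_record_fragments(rec, n_cycles)):
            if len(frag.samples) < int(0.04 * rate):
                continue
            X.append(fragment_feature_vector(frag.samples, rate, bank=bank))
            y.append(rec.pcg_class)
            groups.append(rec.signal.source_id)
            ids.append(f"{rec.signal.source_id}:f{j}")
    if not X:
        raise ValueError(f"no fragments of {n_cycles} cycles could be cut")
    return np.vstack(X), np.array(y), np.array(groups), ids


def _recording_folds(group_names, k: int, rng: np.random.Generator):
    """Shuffle recordings into k folds of near-equal size (difference <= 1)."""
    unique = sorted(set(group_names))
    if len(unique) < k:
        raise ValueError(f"need >= {k} recordings for {k}-fold CV, got {len(unique)}")
    order = list(rng.permutation(unique))
    folds = {name: (i % k) + 1 for i, name in enumerate(order)}
    return folds


def cross_validate_cycles(
    records,
    cycle_range=range(1, 10),
    k: int = 6,
    seed: int = 0,
    n_trees: int = 100,
    retained_variance: float = 0.95,
) -> SweepResult:
    """Six-fold CV of the fragment classifier for each cardiac-cycle count.

    For every ``n_cycles`` the fragments are rebuilt, features re-extracted
    and PCA + random forest refitted per fold (train folds only); predictions
    are pooled over folds before scoring. Fold assignment is at recording
    level.
    """
    records = list(records)
    rng = np.random.default_rng(seed)
    fold_of = _recording_folds([r.signal.source_id for r in records], k, rng)
    rows = []
    all_outcomes = {}
    for n_cycles in cycle_range:
        X, y, groups, ids = build_fragment_table(records, n_cycles)
        fold_ids = np.array([fold_of[g] for g in groups])
        outcomes = []
        for fold in range(1, k + 1):
            test = fold_ids == fold
            train = ~test
            if not np.any(test):
                continue
            if len(np.unique(y[train])) < 2:
                raise ValueError("a training fold collapsed to a single class")
            Xtr, Xte, _ = pca_fit_transform(X[train], X[test], retained_variance)
            rf = train_rf(Xtr, y[train], n_trees=n_trees, seed=seed + fold)
            preds = rf.predict(Xte)
            for frag_id, yt, yp in zip(
                np.array(ids)[test], y[test], preds
            ):
                outcomes.append(
                    ClassifiedRecord(
                        fragment_id=frag_id,
                        true_class=yt,
                        pred_class=yp,
                        n_cycles=n_cycles,
                        fold=fold,
                    )
                )
        metrics = evaluate_multiclass(outcomes)
        all_outcomes[n_cycles] = outcomes
        rows.append(
            {
                "cycle": n_cycles,
                "Acc": metrics["overall_accuracy"],
                "Se": metrics["macro"]["Se"],
                "F1": metrics["macro"]["F1"],
                "F1_ASD": metrics["per_class"].get("ASD", {}).get("F1", np.nan),
                "F1_VSD": metrics["per_class"].get("VSD", {}).get("F1", np.nan),
                "F1_normal": metrics["per_class"].get("normal", {}).get("F1", np.nan),
            }
        )
    result = SweepResult(table=pd.DataFrame(rows))
    result.outcomes = all_outcomes
    return result
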