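"""Self-contained benchmark runs used by the acceptance checks.

Both benchmarks regenerate their data, train from scratch and measure the
result; nothing is cached. Problem sizes are scaled to a single desktop CPU:
the segmentation benchmark trains a reduced TBLSTM (16 channels, 32 LSTM
units per direction, 30 epochs) on 120 five-second records at 15 dB SNR and
scores 30 held-out records with strict frame-wise F1; the classification
benchmark sweeps fragments of 1-6 cardiac cycles over 60 ten-second
recordings (20 per class) under six-fold recording-level cross-validation.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.stats import spearmanr

from .classification import cross_validate_cycles
from .envelopes import build_feature_matrix
from .seg_evaluation import compute_metrics, frame_counts
from .state_decoding import StateSequence
from .synthetic_pcg import default_profiles, simulate_dataset
from .tblstm_model import ModelConfig, train_segmenter


def _profiles(snr_db):
    return {
        name: replace(p, noise_snr_db=snr_db)
        for name, p in default_profiles().items()
    }


def _frame_pairs(records, frame_rate=50.0):
    pairs = []
    for rec in records:
        feats = build_feature_matrix(rec.signal, frame_rate=frame_rate)
        labels = rec.labels.to_frames(feats.n_frames, frame_rate)
        pairs.append((feats, labels))
    return pairs


def segmentation_benchmark(
    seed: int,
    n_train_per_class: int = 40,
    n_test_per_class: int = 10,
    snr_db: float = 15.0,
    channels: int = 16,
    lstm_hidden: int = 32,
    epochs: int = 30,
) -> dict:
    """Train the reduced segmenter and score held-out records.

    Returns strict frame-wise (no tolerance credit) macro F1 plus per-state
    S1/S2 F1 and overall frame accuracy on the held-out set.
    """
    profiles = _profiles(snr_db)
    train_recs, _ = simulate_dataset(
        n_train_per_class, profiles=profiles, seed=int(seed)
    )
    test_recs, _ = simulate_dataset(
        n_test_per_class, profiles=profiles, seed=int(seed) + 900_001
    )
    cfg = ModelConfig(
        channels=channels, lstm_hidden=lstm_hidden, epochs=epochs, seed=int(seed)
    )
    model, _ = train_segmenter(_frame_pairs(train_recs), cfg)

    counts = None
    correct = total = 0
    for feats, labels in _frame_pairs(test_recs):
        pred = StateSequence(model.posterior(feats).argmax(), 50.0)
        truth = StateSequence(labels, 50.0)
        c = frame_counts(pred, truth)
        counts = c if counts is None else counts + c
        correct += int(np.sum(pred.labels == truth.labels))
        total += len(truth)
    metrics = compute_metrics(counts)
    return {
        "macro_f1": metrics.macro["F1"],
        "f1_s1": metrics.per_state["S1"]["F1"],
        "f1_s2": metrics.per_state["S2"]["F1"],
        "frame_accuracy": correct / total,
    }


def cycle_sweep_benchmark(
    seed: int,
    n_per_class: int = 20,
    duration_s: float = 10.0,
    max_cycles: int = 6,
    k: int = 6,
    snr_db: float = 15.0,
) -> dict:
    """Fragment-classification sweep over 1..max_cycles cardiac cycles.

    Returns the macro-F1 curve, its endpoints and the Spearman rank
    correlation between cycle count and macro F1.
    """
    records, _ = simulate_dataset(
        n_per_class, profiles=_profiles(snr_db), seed=int(seed), duration_s=duration_s
    )
    sweep = cross_validate_cycles(
        records, cycle_range=range(1, max_cycles + 1), k=k, seed=int(seed)
    )
    f1 = sweep.table["F1"].to_numpy()
    rho = float(spearmanr(sweep.table["cycle"], sweep.table["F1"]).statistic)
    return {
        "f1_curve": [float(v) for v in f1],
        "f1_at_1": float(f1[0]),
        "f1_at_max": float(f1[-1]),
        "spearman_rho": rho,
        "table": sweep.table,
    }
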