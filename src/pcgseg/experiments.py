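"""End-to-end orchestration of the two experiments.

``run_segmentation_experiment`` performs k-fold cross-validation of the
TBLSTM segmenter on a labelled dataset (real or simulated) and reports
tolerance-window Acc/Se/P/F1 per fold plus the pooled confusion matrix.
``run_classification_experiment`` runs the cardiac-cycle-count sweep:
fragments of 1..N cycles, MFCC features, PCA + random forest under six-fold
recording-level cross-validation, emitting the sweep table and an
F1-versus-cycles plot.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .classification import cross_validate_cycles
from .config import RunConfig
from .envelopes import build_feature_matrix
from .io_preprocess import STATE_NAMES
from .seg_evaluation import compute_metrics, tolerance_match
from .state_decoding import StateSequence
from .synthetic_pcg import default_profiles, simulate_dataset
from .tblstm_model import ModelConfig, train_segmenter
from dataclasses import replace as dc_replace

logger = logging.getLogger(__name__)


def _model_config_from(config: RunConfig, seed: int) -> ModelConfig:
    seg = config.segmenter
    return ModelConfig(
        dilations=tuple(seg.dilations),
        kernel_size=seg.kernel_size,
        channels=seg.channels,
        lstm_hidden=seg.lstm_hidden,
        bidirectional=seg.bidirectional,
        dropout_rate=seg.dropout_rate,
        lr=seg.lr,
        batch_size=seg.batch_size,
        epochs=seg.epochs,
        frame_rate=seg.frame_rate,
        fusion=seg.fusion,
        seed=seed,
    )


def _dataset_with_snr(config: RunConfig, duration_s: float | None = None):
    profiles = default_profiles()
    profiles = {
        name: dc_replace(p, noise_snr_db=config.data.noise_snr_db)
        for name, p in profiles.items()
    }
    return simulate_dataset(
        config.data.n_per_class,
        profiles=profiles,
        seed=config.seed,
        duration_s=config.data.duration_s if duration_s is None else duration_s,
    )


def prepare_frame_dataset(records, frame_rate: float = 50.0):
    """(features, frame-labels) training pairs from labelled records."""
    pairs = []
    for rec in records:
        feats = build_feature_matrix(rec.signal, frame_rate=frame_rate)
        labels = rec.labels.to_frames(feats.n_frames, frame_rate)
        pairs.append((feats, labels))
    return pairs


def _fold_assignment(record_ids, k: int, rng: np.random.Generator):
    order = list(rng.permutation(sorted(record_ids)))
    return {rid: (i % k) + 1 for i, rid in enumerate(order)}


def run_segmentation_experiment(
    config: RunConfig, records=None, out_dir=None, folds: int = 6
):
    """k-fold CV of the segmenter; returns (report DataFrame, confusion matrix).

    The report holds one row per fold plus a mean row, each with macro and
    S1/S2 tolerance-window metrics. When ``records`` is None a synthetic
    dataset is generated per ``config.data``.
    """
    if records is None:
        records, _ = _dataset_with_snr(config)
    rng = np.random.default_rng(config.seed)
    fold_of = _fold_assignment([r.signal.source_id for r in records], folds, rng)
    frame_rate = config.segmenter.frame_rate
    pairs = prepare_frame_dataset(records, frame_rate)

    rows = []
    pooled_matrix = np.zeros((4, 4))
    for fold in range(1, folds + 1):
        train_idx = [i for i, r in enumerate(records) if fold_of[r.signal.source_id] != fold]
        test_idx = [i for i, r in enumerate(records) if fold_of[r.signal.source_id] == fold]
        model_cfg = _model_config_from(config, seed=config.seed * 1000 + fold)
        model, _ = train_segmenter([pairs[i] for i in train_idx], model_cfg)
        counts = None
        for i in test_idx:
            feats, labels = pairs[i]
            post = model.posterior(feats)
            pred = StateSequence(post.argmax(), frame_rate)
            truth = StateSequence(labels, frame_rate)
            c = tolerance_match(
                pred, truth, config.evaluation.tol_s1_ms, config.evaluation.tol_s2_ms
            )
            counts = c if counts is None else counts + c
        metrics = compute_metrics(counts, config.evaluation.precision_mode)
        pooled_matrix += counts.matrix
        rows.append(
            {
                "fold": fold,
                "Acc": metrics.macro["Acc"],
                "P": metrics.macro["P"],
                "Se": metrics.macro["Se"],
                "F1_S1": metrics.per_state["S1"]["F1"],
                "F1_S2": metrics.per_state["S2"]["F1"],
                "F1": metrics.macro["F1"],
            }
        )
    report = pd.DataFrame(rows)
    mean_row = report.drop(columns="fold").mean().to_dict()
    mean_row["fold"] = "mean"
    report = pd.concat([report, pd.DataFrame([mean_row])], ignore_index=True)

    row_sums = pooled_matrix.sum(axis=1, keepdims=True)
    norm_matrix = np.divide(
        pooled_matrix, row_sums, out=np.zeros_like(pooled_matrix), where=row_sums > 0
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "segmentation_report.csv", index=False)
        pd.DataFrame(norm_matrix, index=STATE_NAMES, columns=STATE_NAMES).to_csv(
            out / "confusion_matrix.csv"
        )
        config.to_yaml(out / "resolved_config.yaml")
        (out / "config_hash.txt").write_text(config.content_hash() + "\n")
    return report, norm_matrix


def run_classification_experiment(config: RunConfig, records=None, out_dir=None):
    """Cycle-count sweep; returns the sweep table (one row per cycle count).

    Defaults to fragmentation on ground-truth labels (isolating classifier
    behaviour); a trained segmenter's predictions can be substituted by
    setting ``classifier.use_ground_truth_labels`` to false, which runs the
    full cascade (that switch is logged and recorded in the resolved config).
    """
    if records is None:
        # classification recordings are longer than the 5-s segmentation
        # samples so that fragments up to cycle_max cycles exist at 70-120 bpm
        records, _ = _dataset_with_snr(
            config, duration_s=config.data.classification_duration_s
        )
    cls_cfg = config.classifier
    if not cls_cfg.use_ground_truth_labels:
        logger.info("fragmenting on PREDICTED labels (full cascade)")
        records = _resegment_records(config, records)
    else:
        logger.info("fragmenting on ground-truth labels")
    sweep = cross_validate_cycles(
        records,
        cycle_range=range(cls_cfg.cycle_min, cls_cfg.cycle_max + 1),
        k=cls_cfg.folds,
        seed=config.seed,
        n_trees=cls_cfg.n_trees,
        retained_variance=cls_cfg.retained_variance,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sweep.table.to_csv(out / "cycle_sweep.csv", index=False)
        config.to_yaml(out / "resolved_config.yaml")
        (out / "config_hash.txt").write_text(config.content_hash() + "\n")
        _plot_sweep(sweep.table, out / "f1_vs_cycles.png")
    return sweep


def _resegment_records(config: RunConfig, records):
    """Replace ground-truth labels by TBLSTM-predicted interval labels."""
    from dataclasses import replace

    from .io_preprocess import IntervalLabels
    from .state_decoding import decode, states_to_intervals

    frame_rate = config.segmenter.frame_rate
    pairs = prepare_frame_dataset(records, frame_rate)
    model_cfg = _model_config_from(config, seed=config.seed)
    model, _ = train_segmenter(pairs, model_cfg)
    out = []
    for rec, (feats, _) in zip(records, pairs):
        states = decode(model.posterior(feats), enforce_cyclic=True)
        intervals = states_to_intervals(states)
        try:
            labels = IntervalLabels(tuple(intervals))
        except ValueError:
            logger.warning(
                "predicted labels for %s violate the cyclic order; record skipped",
                rec.signal.source_id,
            )
            continue
        out.append(replace(rec, labels=labels))
    return out


def _plot_sweep(table: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for col, label in (("F1", "overall"), ("F1_ASD", "ASD"), ("F1_VSD", "VSD")):
        ax.plot(table["cycle"], table[col], marker="o", label=label)
    ax.set_xlabel("cardiac cycles per fragment")
    ax.set_ylabel("F1 score")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
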