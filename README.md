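# pcgseg

Segmentation and multi-classification of pediatric heart-sound recordings
(phonocardiograms, PCG). The package is aimed at biomedical-signal
researchers who need a complete, reproducible reference pipeline for
congenital heart disease (CHD) screening studies: it locates the four
cardiac states — first heart sound (S1), systole, second heart sound (S2),
diastole — in a recording, cuts the signal into fragments of N cardiac
cycles, and classifies each fragment as **normal**, **ASD** (atrial septal
defect) or **VSD** (ventricular septal defect).

## What is inside

* **Preprocessing** — second-order Butterworth band-pass 25–400 Hz applied
  zero-phase, down-sampling to 2 kHz, maximum normalization.
* **Envelope features** — Hilbert, homomorphic, wavelet (level-3 db6
  detail) and power-spectral-density envelopes, standardized on a common
  50 frames/s axis.
* **TBLSTM segmenter** — a multi-scale temporal convolutional network
  (five residual blocks of dilated causal convolutions, dilation rates
  2, 4, 8, 16, 16, max-pooling between blocks, per-scale upsampling and
  fusion) followed by a bidirectional LSTM, dropout and a softmax
  frame classifier. y<sub>t</sub> = softmax(W h<sub>t</sub> + b) with
  h<sub>t</sub> = [→h<sub>t</sub>; ←h<sub>t</sub>] over the fused
  multi-scale features. Implemented in numpy with hand-written,
  finite-difference-verified backpropagation; trained with Adam
  (lr 10⁻³), cross-entropy, batch 32, 90 epochs.
* **Decoding & fragmentation** — minimum-duration cleanup, optional cyclic
  projection, S1-onset-to-S1-onset cycle extraction, overlapping N-cycle
  fragments (stride one cycle).
* **Evaluation** — tolerance-window scoring (±100 ms for S1, ±80 ms for
  S2), per-state and macro Acc/Se/P/F1, normalized confusion matrices.
* **Classification** — MFCC + Δ + ΔΔ (26 mel filters, 30–500 Hz, order 12
  → 39 dims/frame), fragment mean/std aggregation, PCA (95 % variance) and
  a 100-tree random forest, with a six-fold cross-validated sweep over
  cardiac-cycle counts.
* **Simulator** — labelled synthetic pediatric PCGs (normal/ASD/VSD, with
  respiratory S2-split behaviour, murmurs, transients, calibrated noise) so
  the entire pipeline is testable without clinical data.

## Worked example

```python
import numpy as np
from pcgseg import (
    default_profiles, simulate_dataset, build_feature_matrix,
    ModelConfig, train_segmenter, StateSequence,
    tolerance_match, compute_metrics,
)

# 30 labelled synthetic records (10 per class), 5 s at 2 kHz
records, manifest = simulate_dataset(n_per_class=10, seed=7)

pairs = []
for rec in records:
    feats = build_feature_matrix(rec.signal, frame_rate=50.0)
    pairs.append((feats, rec.labels.to_frames(feats.n_frames, 50.0)))

cfg = ModelConfig(channels=16, lstm_hidden=32, epochs=60, seed=7)
model, history = train_segmenter(pairs[:24], cfg)

counts = None
for feats, labels in pairs[24:]:
    pred = StateSequence(model.posterior(feats).argmax(), 50.0)
    c = tolerance_match(pred, StateSequence(labels, 50.0))
    counts = c if counts is None else counts + c
m = compute_metrics(counts)
print(f"loss {history[0]:.3f} -> {history[-1]:.3f}")
print(f"macro F1 {m.macro['F1']:.3f}  "
      f"S1 F1 {m.per_state['S1']['F1']:.3f}  S2 F1 {m.per_state['S2']['F1']:.3f}")
```

Output from this exact script:

```
loss 1.424 -> 0.161
macro F1 0.986  S1 F1 1.000  S2 F1 1.000
```

Read: over 60 epochs the training loss falls from 1.42 (≈ chance over four
states) to 0.16; on the six held-out records every S1 and S2 event lands
inside its tolerance window (per-state F1 = 1.0), and the macro F1 of 0.986
reflects the few frame-level boundary disagreements in systole and diastole,
which carry no tolerance credit.

The same pipeline is scriptable from the shell:

```bash
pcgseg simulate --n 20 --seed 7 --out data/
pcgseg preprocess data/normal_000.wav pre.wav
pcgseg train --data data/ --seed 7 --out model.npz
pcgseg segment pre.wav --model model.npz --out states.csv
pcgseg evaluate --pred states.csv --truth truth.csv
pcgseg sweep --cycles 1:6 --folds 6 --seed 7 --out sweep/
```

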