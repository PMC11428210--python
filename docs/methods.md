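# Methods

`pcgseg` implements a complete pediatric phonocardiogram (PCG) analysis
pipeline: signal conditioning, envelope feature extraction, a neural
frame-wise segmenter of the four cardiac states, tolerance-window evaluation,
cardiac-cycle fragmentation, and random-forest multi-classification of
normal vs. atrial septal defect (ASD) vs. ventricular septal defect (VSD).
This note records the models, the tunable parameters that matter, the design
choices made where the design was genuinely open, and what the synthetic data
do and do not establish.

## Signal model and preprocessing

A recording is a mono waveform x(n) at an arbitrary rate. The working
representation is obtained by a second-order Butterworth band-pass
(25–400 Hz), down-sampling to 2 kHz, and maximum normalization
(x / max|x|). Two choices here are deliberate rather than inherited:

* **Zero-phase filtering.** The band-pass is applied forward–backward
  (`sosfiltfilt`). Segmentation is scored with ±100 ms (S1) / ±80 ms (S2)
  tolerance windows, so any filter group delay would bias event timings by a
  meaningful fraction of the budget; zero-phase filtering removes it at the
  cost of doubling the effective order. A click-train test verifies zero
  cross-correlation lag through the chain.
* **Filter at native rate, then resample.** Anti-aliased polyphase
  resampling follows the filter; the order is configurable.

The chain is *approximately* idempotent: a second pass re-attenuates
passband-edge energy and changes the waveform by ~1–2 % RMS on synthetic
records. The property test asserts idempotence at 5 % RMS; exact idempotence
is not achievable with a genuine Butterworth band-pass.

## Envelope features

Four non-negative envelopes summarize where acoustic energy lies in time:

| envelope | definition | free parameters |
|---|---|---|
| Hilbert | magnitude of the analytic signal (default) or literal \|H{x}\| | mode |
| homomorphic | exp(LPF(log \|analytic\|)) | low-pass cutoff 8 Hz, 1st order, zero-phase |
| wavelet | \|level-3 db6 detail\|, reconstructed to signal length | wavelet, level, raw-coefficient mode |
| PSD | mean power spectral density in 40–60 Hz, 0.05 s Hamming windows, 50 % overlap | band, window |

Open points resolved here: "absolute value of the Hilbert transformation" is
ambiguous between \|H{x}\| and the analytic magnitude; the analytic magnitude
is the default because it is the standard envelope (a `literal` mode keeps
the other reading). The homomorphic low-pass cutoff is unstated anywhere
authoritative; 8 Hz smooths within-sound oscillation (>70 Hz) while keeping
S1/S2 lobes (≥ 10 Hz apart in rate terms) separate. The wavelet detail is
reconstructed (inverse DWT of d3 alone) so all channels share one time axis;
the decimated coefficients are available. The PSD band default 40–60 Hz
captures dominant S1/S2 energy.

All four are linearly interpolated onto a common 50 frames/s axis (20 ms
frames; the tolerance windows span 4–5 frames, so this resolution does not
limit scoring) and standardized per channel over the record. Channels that
are constant up to numerical noise become all-zero rather than amplifying
round-off.

## The TBLSTM segmenter

Frame labels are S1 = 0, systole = 1, S2 = 2, diastole = 3.

**Multi-scale TCN.** Five residual blocks with dilation rates 2, 4, 8, 16, 16.
Each block is: dilated causal convolution → ReLU → causal convolution → ReLU,
plus an identity skip (1×1 convolution when widths change). Causal
convolutions left-pad by (K−1)·d so output frame n sees only inputs ≤ n;
the receptive field is (K−1)·d+1. After each block the sequence is
max-pooled (window 2, stride 2) and fed to the next block; every block's
pre-pool output is linearly interpolated back to the input frame count and
the five maps are concatenated channel-wise (a summation mode exists). For a
250-frame record the internal lengths are 250, 125, 62, 31, 15 pre-pool.
Inputs shorter than 32 frames are rejected (five poolings degenerate).

**Bi-LSTM head.** The fused representation feeds a bidirectional LSTM
(64 units per direction by default), dropout 0.25, and a dense + softmax
layer over the four states. The unidirectional variant ("TLSTM") is a
configuration flag.

**Free choices** (unstated in the source architecture, fixed here): kernel
size K = 3 for both convolutions; 32 channels per block (fused width 160);
LSTM width 64/direction; dropout 0.25; upsampling by linear interpolation
with channel concatenation rather than summation, which preserves per-scale
information. One ReLU after each convolution. Class weighting of the loss is
available but off by default.

**Training.** Adam (lr 0.001), mean per-frame cross-entropy, batch size 32,
90 epochs. The network is implemented directly in numpy with hand-written
backpropagation; every layer's gradient is validated against central finite
differences in the test suite, and all randomness (initialization, dropout,
shuffling) flows through one seeded generator, so a fixed seed reproduces a
run exactly on a fixed BLAS.

## State decoding and fragmentation

Greedy argmax labels are cleaned by absorbing runs shorter than a per-state
minimum duration into the longer neighbouring run (S1 60 ms, systole 80 ms,
S2 50 ms, diastole 120 ms — chosen from physiological S1/S2 durations
consistent with the tolerance windows). An optional projection forces the
cyclic order S1 → systole → S2 → diastole. Decoding is idempotent.

A cardiac cycle spans S1 onset to the next S1 onset; incomplete edge cycles
are dropped. Fragments of N cycles are cut with stride one cycle, so
consecutive fragments overlap by N−1 cycles — the maximal-overlap reading of
the sequential segmentation strategy; the stride is configurable.

## Tolerance-window evaluation

Scoring is one-vs-rest and frame-based, with event-level credit for S1 and
S2: a predicted S1 (S2) interval whose **onset** lies within 100 ms (80 ms)
of a true interval's onset is credited — its frames count as true positives
and the matched true interval contributes no false negatives. Unmatched
predicted intervals are false-positive frames; unmatched true intervals
false-negative frames. Matching onsets (not isolated frames) prevents a
prediction shifted past the window from being partially credited through
interval overlap. Systole and diastole are scored by plain frame agreement;
TN is defined per state as the remaining frames (a frame-level TN for a
4-state problem is otherwise ill-defined). Widening a window can only move
frames from FP/FN to TP, so sensitivity is monotone in the tolerance — a
property test asserts this.

Per state: Acc = (TP+TN)/N, Se = TP/(TP+FN), F1 = 2·Se·P/(Se+P). The
precision P has two modes: `conventional` TP/(TP+FP) (default — the form F1
normally composes with) and `printed` TN/(TN+FP), which reproduces the
literal formula of the source metric suite (that formula is specificity
under standard nomenclature; both are kept so either reading can be
reproduced). Macro metrics are unweighted means over the four states; counts
are pooled across records before computing metrics, making aggregation
order-independent.

For multi-class evaluation, *macro accuracy* is the unweighted mean of
per-class recall (balanced accuracy). With exactly balanced class counts it
equals overall accuracy identically — the package asserts the identity at
1e−12 — whereas a one-vs-rest (TP+TN)/N reading would not satisfy it.

## MFCC features and classification

Fragments are framed at 20 ms / 10 ms hop with Hamming windows, transformed
with a zero-padded 256-point FFT, pooled by 26 triangular mel filters between
30 and 500 Hz (triangles evaluated continuously at bin frequencies),
log-compressed (floor 1e−10) and decorrelated by an orthonormal DCT-II.
Coefficients c0..c12 (order 12, c0 retained; a drop-c0 option exists) plus
±2-frame regression deltas and delta-deltas give 39 dimensions per frame.

The FFT size deserves a note: at 2 kHz a 20 ms frame is 40 samples and the
next power of two (64) gives 31.25 Hz bins — wider than the ~15–40 Hz mel
filters in this band, leaving several filters without any bin and therefore
pinned at the log floor. The default is therefore a zero-padded 256-point
FFT (7.8 Hz bins), which keeps every filter populated; `n_fft` is a
parameter.

A fragment becomes a fixed-length vector via per-dimension mean and standard
deviation over frames (78 dims) — the bridge from frame features to a
fragment-level classifier, which no authoritative source specifies.
Classification uses PCA retaining 95 % variance followed by z-scoring, both
fitted on training rows only (per fold — leakage-safe, and a possible source
of divergence from results obtained with global fitting), then a 100-tree
random forest (other forest hyper-parameters at library defaults, recorded
via the resolved run config).

The cycle-count sweep re-runs the whole chain for each fragment length under
six-fold cross-validation with folds assigned at the **recording** level:
overlapping fragments of one recording never straddle a fold boundary.
Fragment-level splitting would leak heavily through the N−1-cycle overlaps;
this protocol choice may therefore score below a fragment-level protocol on
the same data.

## Synthetic phonocardiograms

No public pediatric CHD phonocardiogram corpus with state annotations is
available to this package, so every experiment runs on the `synthetic_pcg`
simulator, which emulates the statistical structure of short pediatric
auscultation recordings:

* 2 kHz records; 5 s for segmentation experiments. Classification
  recordings default to 10 s because fragments of up to nine cardiac cycles
  must exist inside one recording at 70–120 bpm — an 8–10 s minimum is
  implied by the cycle-sweep design itself.
* Cycles are S1 → systole → S2 → diastole with per-cycle heart-rate jitter
  (4 %); the S1-to-S2 span is ≈ 0.3 of the cycle at a resting 0.8 s cycle
  and compresses more slowly than diastole as the rate rises.
* S1 and S2 are Gaussian-enveloped band-limited bursts (S1: ~70–150 Hz,
  100 ms, amplitude 1; S2: ~90–200 Hz, 80 ms, amplitude 0.6) — S1 louder and
  longer than S2, as on a real phonocardiogram.
* **Respiration** (0.3–0.5 Hz) modulates the record beat by beat. A normal
  S2 split (20–50 ms) widens on inspiration and closes on expiration; the
  ASD split (30–70 ms) is *fixed* through the breath — the textbook
  distinction between physiological and ASD splitting. Right-sided murmurs
  wax with inspiration (Carvallo's sign): strongly for the
  tricuspid-regurgitation murmur that accompanies 70 % of ASD and 30 % of
  VSD records, mildly (depth 0.3) for the VSD murmur.
* VSD adds a harsh holosystolic band-noise murmur (100–300 Hz, relative
  amplitude 0.15–0.6) filling the S1–S2 interval; ASD adds an accentuated
  S2 (amplitude 0.7–1.1). A diastolic flow murmur type exists for
  large-shunt configurations.
* Sparse broadband transients (0.1/s, 50–120 ms, amplitude 0.2–0.5) mimic
  movement and contact noise; white noise is added at a calibrated SNR
  (default 15 dB).
* Interval labels tile each record exactly, so ground truth is
  sample-accurate by construction.

Beat-to-beat variability is what makes the cycle-count experiment
meaningful: with it, a single cycle is genuinely ambiguous (a normal heart
mid-inspiration shows a split S2; a soft murmur may be inaudible at
expiration) while multi-cycle fragments average over the breath — the
mechanism by which longer fragments help. Without such variability the sweep
is flat.

What the simulator does **not** model: realistic auscultation acoustics
(chest-wall transfer, stethoscope coloration), S3/S4 sounds, arrhythmia,
crying, or inter-patient acoustic diversity beyond the parameter draws.
Passing tests on synthetic data therefore demonstrate that the pipeline's
machinery is correct and that its statistical design (fold protocol,
aggregation, tolerance scoring) behaves as intended — not that clinical
performance on real pediatric recordings would match the synthetic numbers.

## Problem sizes and numerical choices

The self-contained benchmarks train a reduced segmenter (16 channels,
32 LSTM units/direction, 30 epochs) on 120 records and evaluate 30 held-out
records with strict frame-wise F1 (no tolerance credit — with the tolerance
windows the reduced model saturates near F1 = 1 and per-state comparisons
become uninformative); the classification benchmark uses 60 ten-second
recordings (20 per class) and sweeps 1–6 cycles under six-fold CV. These
sizes keep a full run on one desktop CPU core in a few minutes while leaving
the observed effects (S1 easier than S2; F1 rising with cycle count) well
clear of noise.

Numerics: float64 throughout the network; softmax via max-subtraction;
cross-entropy floored at 1e−12; log-mel floored at 1e−10; all-zero signals
pass through normalization unchanged with a warning; degenerate metric
denominators yield 0 with a warning. Ties in max-pooling resolve to the
earlier frame; interpolation is endpoint-aligned.

## Known limitations

* No Viterbi/HSMM duration decoding — minimum-duration absorption plus
  optional cyclic projection only.
* The numpy network trains small models briskly but is not meant for large
  configurations or GPUs.
* Tolerance credit keys on interval onsets; an extremely fragmented
  prediction could in principle earn credit from many small intervals near a
  true onset (mitigated by the minimum-duration decoder).
* Simulator realism as above; absolute synthetic metrics should not be read
  as clinical performance.
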