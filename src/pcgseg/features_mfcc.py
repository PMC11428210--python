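"""MFCC + delta + delta-delta features, fragment aggregation and PCA.

Fragments are cut into 20 ms Hamming frames with 10 ms hop; each frame's power
spectrum is pooled by a 26-filter triangular mel bank spanning 30-500 Hz,
log-compressed and decorrelated with an orthonormal DCT-II. Coefficients
c0..c12 (order 12, c0 retained) plus first- and second-order regression
deltas give 39 dimensions per frame. A fragment becomes a fixed-length vector
by per-dimension mean and standard deviation over its frames (78 dims), then
PCA (fitted on training rows only) and z-scoring with training statistics
prepare the classifier input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .io_preprocess import Signal

logger = logging.getLogger(__name__)

LOG_FLOOR = 1e-10

MEL_BAND = (30.0, 500.0)  # cepstral analysis band, Hz


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


@dataclass(frozen=True)
class MelFilterbank:
    """26 triangular filters on the mel scale between 30 and 500 Hz.

    Triangle weights are evaluated continuously at the FFT bin frequencies
    (no rounding of edges to bins). ``n_fft`` defaults to 256: at 2 kHz this
    gives 7.8 Hz bin spacing, fine enough that every ~15-40 Hz-wide filter
    covers at least one bin.
    """

    rate: float
    n_fft: int = 256
    n_filters: int = 26
    f_low: float = MEL_BAND[0]
    f_high: float = MEL_BAND[1]

    def __post_init__(self):
        if self.f_high > self.rate / 2:
            raise ValueError("f_high above Nyquist")
        if self.f_low >= self.f_high:
            raise ValueError("need f_low < f_high")

    @property
    def center_freqs_hz(self) -> np.ndarray:
        mels = np.linspace(hz_to_mel(self.f_low), hz_to_mel(self.f_high), self.n_filters + 2)
        return mel_to_hz(mels)

    def weights(self) -> np.ndarray:
        """(n_filters, n_fft//2 + 1) non-negative triangle weights."""
        bins_hz = np.arange(self.n_fft // 2 + 1) * self.rate / self.n_fft
        edges = self.center_freqs_hz  # n_filters + 2 edge/center points
        W = np.zeros((self.n_filters, len(bins_hz)))
        for m in range(self.n_filters):
            lo, ctr, hi = edges[m], edges[m + 1], edges[m + 2]
            up = (bins_hz - lo) / (ctr - lo)
            down = (hi - bins_hz) / (hi - ctr)
            W[m] = np.clip(np.minimum(up, down), 0.0, None)
        return W


def frame_signal(signal: Signal, frame_ms: float = 20.0, hop_ms: float = 10.0) -> np.ndarray:
    """Hamming-windowed frames, shape (n_frames, frame_len).

    Frame count is floor((N - W) / hop) + 1; a too-short signal yields an
    empty (0, frame_len) array with a warning.
    """
    x = signal.samples
    W = int(round(frame_ms / 1000.0 * signal.rate))
    hop = int(round(hop_ms / 1000.0 * signal.rate))
    if W < 1 or hop < 1:
        raise ValueError("frame/hop too short for this sample rate")
    if len(x) < W:
        logger.warning("signal shorter than one frame (%d < %d samples)", len(x), W)
        return np.zeros((0, W))
    n = (len(x) - W) // hop + 1
    idx = np.arange(W)[None, :] + hop * np.arange(n)[:, None]
    return x[idx] * np.hamming(W)[None, :]


def mfcc_frames(
    frames: np.ndarray,
    bank: MelFilterbank,
    n_coeffs: int = 13,
    drop_c0: bool = False,
) -> np.ndarray:
    """Cepstral coefficients c0..c12 per frame (order 12 -> 13 columns).

    Pipeline per frame: zero-padded FFT power spectrum -> mel filterbank
    energies -> log (floored at a small epsilon so silent frames stay finite)
    -> orthonormal DCT-II -> first ``n_coeffs`` coefficients. ``drop_c0``
    discards the energy coefficient and keeps c1..c13 instead.
    """
    if frames.ndim != 2:
        raise ValueError("frames must be 2-D")
    spectrum = rfft(frames, n=bank.n_fft, axis=1)
    power = np.abs(spectrum) ** 2
    energies = power @ bank.weights().T
    log_e = np.log(np.maximum(energies, LOG_FLOOR))
    ceps = dct(log_e, type=2, norm="ortho", axis=1)
    if drop_c0:
        return ceps[:, 1 : n_coeffs + 1]
    return ceps[:, :n_coeffs]


def delta_features(mfcc: np.ndarray, width: int = 2) -> np.ndarray:
    """[MFCC, delta, delta-delta] concatenation (13 -> 39 columns).

    Deltas use the standard regression formula over a +/-``width`` window
    with edge replication; delta-delta is the delta of the delta. A
    single-frame input gets zero deltas.
    """
    if mfcc.ndim != 2:
        raise ValueError("mfcc must be 2-D")

    def _delta(feat):
        if feat.shape[0] < 2:
            return np.zeros_like(feat)
        padded = np.pad(feat, ((width, width), (0, 0)), mode="edge")
        num = np.zeros_like(feat)
        for n in range(1, width + 1):
            num += n * (padded[width + n : padded.shape[0] - width + n]
                        - padded[width - n : padded.shape[0] - width - n])
        return num / (2.0 * sum(n * n for n in range(1, width + 1)))

    d1 = _delta(mfcc)
    d2 = _delta(d1)
    return np.concatenate([mfcc, d1, d2], axis=1)


def aggregate_fragment(feat: np.ndarray) -> np.ndarray:
    """Per-dimension mean and standard deviation over frames (39 -> 78 dims)."""
    if feat.ndim != 2 or feat.shape[0] < 1:
        raise ValueError("need at least one frame")
    return np.concatenate([feat.mean(axis=0), feat.std(axis=0)])


def fragment_feature_vector(
    samples: np.ndarray,
    rate: float,
    bank: MelFilterbank | None = None,
    n_coeffs: int = 13,
    drop_c0: bool = False,
) -> np.ndarray:
    """End-to-end 78-dim feature vector for one fragment waveform."""
    sig = Signal(samples=samples, rate=rate, source_id="fragment")
    if bank is None:
        bank = MelFilterbank(rate=rate)
    frames = frame_signal(sig)
    if frames.shape[0] == 0:
        raise ValueError("fragment shorter than one analysis frame")
    feats = delta_features(mfcc_frames(frames, bank, n_coeffs=n_coeffs, drop_c0=drop_c0))
    return aggregate_fragment(feats)


@dataclass
class FeatureProjection:
    """Train-set-fitted standardize -> PCA -> z-score transform."""

    pre_scaler: StandardScaler
    pca: PCA
    post_scaler: StandardScaler

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.post_scaler.transform(self.pca.transform(self.pre_scaler.transform(X)))


def pca_fit_transform(train_X: np.ndarray, test_X: np.ndarray | None, retained_variance: float = 0.95):
    """Fit PCA on training rows only; project both sets; z-score with train stats.

    ``retained_variance`` in (0, 1) keeps the smallest number of components
    explaining that variance fraction; 1.0 keeps min(rows-1, dims). Test rows
    never influence the projection (leakage-safe).
    """
    train_X = np.asarray(train_X, dtype=float)
    if not 0.0 < retained_variance <= 1.0:
        raise ValueError("retained_variance must be in (0, 1]")
    if train_X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    pre = StandardScaler().fit(train_X)
    Z = pre.transform(train_X)
    if retained_variance >= 1.0:
        n_comp = min(train_X.shape[0] - 1, train_X.shape[1])
    else:
        n_comp = retained_variance
    pca = PCA(n_components=n_comp, svd_solver="full").fit(Z)
    train_P = pca.transform(Z)
    post = StandardScaler().fit(train_P)
    proj = FeatureProjection(pre_scaler=pre, pca=pca, post_scaler=post)
    train_out = post.transform(train_P)
    test_out = proj.transform(np.asarray(test_X, dtype=float)) if test_X is not None else None
    return train_out, test_out, proj
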