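"""The four segmentation envelopes and the frame-aligned feature matrix.

Each envelope is a slowly varying, non-negative curve that tracks where the
acoustic energy of the heart sound lies in time:

* **Hilbert envelope** — magnitude of the analytic signal (default), or the
  literal ``|H{x}|`` of the Hilbert transform itself in ``literal`` mode.
* **Homomorphic envelope** — exp of a zero-phase low-passed log-magnitude,
  which smooths within-sound oscillation while keeping S1/S2 lobes separate.
* **Wavelet envelope** — absolute value of the level-3 Daubechies-6 detail
  component (band roughly rate/16–rate/8, i.e. 125–250 Hz at 2 kHz), where
  most S1/S2 energy falls.
* **PSD envelope** — mean power spectral density in a narrow low band,
  computed on 0.05 s Hamming windows with 50% overlap.

``build_feature_matrix`` resamples all four to a common frame rate and
standardizes each channel, producing the segmenter's input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .io_preprocess import Signal

EPS = 1e-10

CHANNEL_NAMES = ("hilbert", "homomorphic", "wavelet", "psd")


@dataclass(frozen=True)
class EnvelopeSet:
    hilbert: np.ndarray
    homomorphic: np.ndarray
    wavelet: np.ndarray
    psd: np.ndarray
    frame_rate: float


@dataclass(frozen=True)
class FrameFeatureMatrix:
    """Frames x channels matrix feeding the segmenter."""

    values: np.ndarray
    frame_rate: float
    channel_names: tuple = CHANNEL_NAMES

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("feature matrix must be 2-D (frames x channels)")
        if np.any(~np.isfinite(values)):
            raise ValueError("feature matrix contains NaN/inf")
        object.__setattr__(self, "values", values)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def hilbert_envelope(signal: Signal, mode: str = "analytic") -> np.ndarray:
    """Hilbert envelope of the waveform.

    ``analytic`` (default) returns ``|x + i H{x}|``; ``literal`` returns
    ``|H{x}|`` alone. For a cosine the literal mode gives ``|sin|``.
    """
    x = signal.samples
    if len(x) < 2:
        raise ValueError("signal too short for Hilbert transform")
    analytic = sps.hilbert(x)
    if mode == "analytic":
        return np.abs(analytic)
    if mode == "literal":
        return np.abs(analytic.imag)
    raise ValueError(f"unknown hilbert mode {mode!r}")


def homomorphic_envelope(signal: Signal, lp_cutoff: float = 8.0, order: int = 1) -> np.ndarray:
    """exp( LPF( log |analytic signal| ) ) with a zero-phase Butterworth low-pass."""
    if lp_cutoff >= signal.rate / 2:
        raise ValueError("lp_cutoff must be below Nyquist")
    mag = np.abs(sps.hilbert(signal.samples))
    log_mag = np.log(mag + EPS)
    sos = sps.butter(order, lp_cutoff, btype="low", fs=signal.rate, output="sos")
    smoothed = sps.sosfiltfilt(sos, log_mag)
    return np.exp(smoothed)


def wavelet_envelope(
    signal: Signal, wavelet: str = "db6", level: int = 3, reconstruct: bool = True
) -> np.ndarray:
    """Absolute value of the level-3 db6 detail component.

    With ``reconstruct=True`` (default) the detail coefficients are inverted
    back to signal length so the envelope shares the waveform's time axis;
    ``reconstruct=False`` returns the raw decimated coefficients (length
    ~ N / 2**level).
    """
    x = signal.samples
    wav = pywt.Wavelet(wavelet)
    min_len = pywt.Wavelet(wavelet).dec_len * 2**level
    if len(x) < min_len:
        raise ValueError(f"signal too short for level-{level} {wavelet} analysis")
    coeffs = pywt.wavedec(x, wav, level=level)
    # coeffs = [a_L, d_L, ..., d_1]; level-3 detail is coeffs[1] when level == 3
    detail = coeffs[1]
    if not reconstruct:
        return np.abs(detail)
    kept = [np.zeros_like(c) for c in coeffs]
    kept[1] = detail
    recon = pywt.waverec(kept, wav)
    return np.abs(recon[: len(x)])


def psd_envelope(
    signal: Signal,
    win_s: float = 0.05,
    overlap: float = 0.5,
    band: tuple = (40.0, 60.0),
) -> np.ndarray:
    """Mean power spectral density in ``band`` per Hamming window.

    Windows of ``win_s`` seconds with fractional ``overlap``; one value per
    window, so this envelope lives on a coarser time axis than the others
    (resampled later by :func:`build_feature_matrix`).
    """
    x = signal.samples
    nperseg = int(round(win_s * signal.rate))
    if nperseg < 8:
        raise ValueError("window too short (< 8 samples)")
    lo, hi = band
    if not (0 <= lo < hi <= signal.rate / 2):
        raise ValueError(f"band {band} outside (0, Nyquist)")
    hop = max(1, int(round(nperseg * (1.0 - overlap))))
    if len(x) < nperseg:
        return np.zeros(0)
    f, t, spec = sps.stft(
        x,
        fs=signal.rate,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg - hop,
        boundary=None,
        padded=False,
    )
    power = np.abs(spec) ** 2
    in_band = (f >= lo) & (f <= hi)
    if not np.any(in_band):
        raise ValueError(f"band {band} contains no FFT bins at rate {signal.rate}")
    return power[in_band].mean(axis=0)


def compute_envelopes(signal: Signal, hilbert_mode: str = "analytic") -> EnvelopeSet:
    """All four envelopes on their native time axes (PSD is per-window)."""
    return EnvelopeSet(
        hilbert=hilbert_envelope(signal, mode=hilbert_mode),
        homomorphic=homomorphic_envelope(signal),
        wavelet=wavelet_envelope(signal),
        psd=psd_envelope(signal),
        frame_rate=signal.rate,
    )


def _resample_to_frames(env: np.ndarray, native_rate: float, duration: float, n_frames: int) -> np.ndarray:
    """Linear interpolation of an envelope onto frame centers."""
    if len(env) == 0:
        return np.zeros(n_frames)
    t_native = (np.arange(len(env)) + 0.5) * (duration / len(env))
    t_frames = (np.arange(n_frames) + 0.5) * (duration / n_frames)
    return np.interp(t_frames, t_native, env)


def build_feature_matrix(
    signal: Signal, frame_rate: float = 50.0, hilbert_mode: str = "analytic"
) -> FrameFeatureMatrix:
    """Stack the four envelopes into a standardized frames x 4 matrix.

    Each envelope is linearly interpolated onto ``ceil(duration * frame_rate)``
    frame centers and standardized to zero mean, unit variance over the record
    (constant channels become all-zero rather than NaN).
    """
    env = compute_envelopes(signal, hilbert_mode=hilbert_mode)
    duration = signal.duration
    n_frames = int(np.ceil(duration * frame_rate))
    cols = []
    for name in CHANNEL_NAMES:
        series = getattr(env, name)
        col = _resample_to_frames(series, signal.rate, duration, n_frames)
        mu, sd = col.mean(), col.std()
        # channels that are constant up to numerical noise become all-zero
        scale = max(np.max(np.abs(col)), 1e-300)
        if sd <= 1e-8 * scale:
            cols.append(np.zeros_like(col))
        else:
            cols.append((col - mu) / sd)
    values = np.column_stack(cols)
    return FrameFeatureMatrix(values=values, frame_rate=frame_rate)
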