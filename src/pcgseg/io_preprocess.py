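"""Audio and label I/O plus the standardized phonocardiogram pre-processing chain.

Heart sound recordings arrive at arbitrary sample rates and amplitudes. Before
segmentation every record is put through the same chain: a second-order
Butterworth band-pass (25–400 Hz, applied forward-backward so event timings are
not shifted), down-sampling to 2 kHz, and maximum normalization. The chain is
idempotent on its own output up to numerical noise, which keeps repeated runs of
the pipeline comparable.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

logger = logging.getLogger(__name__)

#: Frame-label convention used throughout: S1=0, systole=1, S2=2, diastole=3.
STATE_NAMES = ("S1", "systole", "S2", "diastole")
STATE_TO_INT = {name: i for i, name in enumerate(STATE_NAMES)}

DEFAULT_BAND = (25.0, 400.0)  # software analysis band, Hz
DEFAULT_RATE = 2000.0  # working sample rate, Hz


class FormatError(ValueError):
    """Raised for unreadable or structurally invalid input files."""


@dataclass(frozen=True)
class Signal:
    """A sampled mono waveform.

    Parameters
    ----------
    samples : ndarray
        Dimensionless float amplitudes.
    rate : float
        Sampling rate in samples/second; must be positive.
    source_id : str
        Provenance tag (file stem, simulator seed, ...).
    """

    samples: np.ndarray
    rate: float
    source_id: str = ""

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if samples.ndim != 1:
            raise ValueError("Signal holds a mono waveform (1-D array)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Signal samples must be finite")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self.samples) / self.rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class IntervalLabels:
    """Ground-truth state intervals ``(start_s, end_s, state)``, state in STATE_NAMES.

    Intervals are kept sorted and non-overlapping; validation enforces the
    cardiac-cycle state order S1 -> systole -> S2 -> diastole (cyclically).
    """

    intervals: tuple = field(default_factory=tuple)

    def __post_init__(self):
        ivs = tuple(
            (float(s), float(e), str(state)) for s, e, state in self.intervals
        )
        prev_end = -np.inf
        prev_state = None
        for s, e, state in ivs:
            if state not in STATE_TO_INT:
                raise ValueError(f"unknown state {state!r}")
            if e <= s:
                raise ValueError(f"interval ({s}, {e}) has end <= start")
            if s < prev_end - 1e-12:
                raise ValueError("intervals overlap or are unsorted")
            if prev_state is not None:
                expected = (STATE_TO_INT[prev_state] + 1) % 4
                if STATE_TO_INT[state] != expected:
                    raise ValueError(
                        f"state order violated: {prev_state} -> {state}"
                    )
            prev_end, prev_state = e, state
        object.__setattr__(self, "intervals", ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def to_frames(self, n_frames: int, frame_rate: float) -> np.ndarray:
        """Rasterize to per-frame integer labels (frame centers decide)."""
        t = (np.arange(n_frames) + 0.5) / frame_rate
        labels = np.full(n_frames, 3, dtype=int)  # pad gaps with diastole
        for s, e, state in self.intervals:
            labels[(t >= s) & (t < e)] = STATE_TO_INT[state]
        return labels


def load_wav(path) -> Signal:
    """Read a WAV file (16-bit PCM or float) as a float-amplitude :class:`Signal`.

    Multi-channel files contribute only channel 0 (with a logged warning).
    Integer PCM is rescaled so full scale maps to amplitude 1.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / non-WAV payloads
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise FormatError(f"empty WAV file: {path}")
    if data.ndim > 1:
        logger.warning("%s has %d channels; using channel 0", path, data.shape[1])
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(float) / scale
    else:
        data = data.astype(float)
    return Signal(samples=data, rate=float(rate), source_id=path.stem)


def save_wav(path, signal: Signal, dtype: str = "float32") -> None:
    """Write a :class:`Signal` to WAV (``float32`` or 16-bit PCM ``int16``)."""
    path = Path(path)
    if dtype == "int16":
        clipped = np.clip(signal.samples, -1.0, 1.0 - 2.0**-15)
        data = np.round(clipped * 32768.0).astype(np.int16)
    elif dtype == "float32":
        data = signal.samples.astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    wavfile.write(path, int(round(signal.rate)), data)


def bandpass(
    signal: Signal,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 2,
) -> Signal:
    """Second-order Butterworth band-pass, applied zero-phase.

    Forward-backward filtering (``filtfilt``) has no group delay, so S1/S2
    timings survive filtering exactly; the effective magnitude response is the
    squared Butterworth response (effective order doubles).
    """
    nyq = signal.rate / 2.0
    if not (0.0 < low < high):
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=signal.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, signal.samples)
    return replace(signal, samples=filtered)


def resample(signal: Signal, target_rate: float = DEFAULT_RATE) -> Signal:
    """Anti-aliased polyphase resampling to ``target_rate``."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == signal.rate:
        return signal
    from fractions import Fraction

    frac = Fraction(target_rate / signal.rate).limit_denominator(10_000)
    out = sps.resample_poly(signal.samples, frac.numerator, frac.denominator)
    return replace(signal, samples=out, rate=float(target_rate))


def normalize_max(signal: Signal) -> Signal:
    """Divide by the peak absolute amplitude; all-zero input passes through."""
    peak = np.max(np.abs(signal.samples)) if len(signal) else 0.0
    if peak == 0.0:
        logger.warning("normalize_max: all-zero signal %s left unchanged", signal.source_id)
        return signal
    return replace(signal, samples=signal.samples / peak)


def preprocess(
    signal: Signal,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 2,
    target_rate: float = DEFAULT_RATE,
    filter_first: bool = True,
) -> Signal:
    """Full chain: band-pass -> resample -> maximum normalization.

    ``filter_first=False`` resamples before filtering (then the band must fit
    under the target Nyquist).
    """
    if filter_first:
        out = bandpass(signal, low, high, order)
        out = resample(out, target_rate)
    else:
        out = resample(signal, target_rate)
        out = bandpass(out, low, high, order)
    return normalize_max(out)


def load_labels(path) -> IntervalLabels:
    """Read interval labels from a CSV with header ``start_s,end_s,state``."""
    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or {"start_s", "end_s", "state"} - set(
            reader.fieldnames
        ):
            raise FormatError(f"{path}: expected header start_s,end_s,state")
        for rec in reader:
            rows.append((float(rec["start_s"]), float(rec["end_s"]), rec["state"]))
    return IntervalLabels(tuple(rows))


def save_labels(path, labels: IntervalLabels) -> None:
    """Write interval labels as ``start_s,end_s,state`` CSV."""
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["start_s", "end_s", "state"])
        for s, e, state in labels:
            writer.writerow([f"{s:.6f}", f"{e:.6f}", state])
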