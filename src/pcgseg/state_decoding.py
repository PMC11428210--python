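"""From frame posteriors to clean state sequences, cardiac cycles and fragments.

Raw argmax label tracks contain physiologically impossible blips (a one-frame
S2 inside diastole, say). ``decode`` removes runs shorter than a per-state
minimum duration by absorbing them into the longer neighbouring run, and can
optionally project the track onto the cyclic order S1 -> systole -> S2 ->
diastole. Cycles are S1-onset-to-next-S1-onset intervals; fragments are
sliding windows of N consecutive cycles with stride one cycle, so adjacent
fragments overlap by N-1 cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_preprocess import IntervalLabels, Signal, STATE_NAMES
from .tblstm_model import FramePosterior

logger = logging.getLogger(__name__)

#: Minimum credible state durations, ms. Derived from pediatric S1/S2 spans
#: (the S1/S2 evaluation tolerances are 100/80 ms; systole and diastole are
#: longer still). Runs shorter than these are treated as decoder noise.
DEFAULT_MIN_DUR_MS = {"S1": 60.0, "systole": 80.0, "S2": 50.0, "diastole": 120.0}

CYCLE_ORDER = (0, 1, 2, 3)  # S1, systole, S2, diastole


@dataclass(frozen=True)
class StateSequence:
    """Per-frame labels in {0: S1, 1: systole, 2: S2, 3: diastole}."""

    labels: np.ndarray
    frame_rate: float

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        if labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if len(labels) and (labels.min() < 0 or labels.max() > 3):
            raise ValueError("labels must lie in {0,1,2,3}")
        object.__setattr__(self, "labels", labels)

    def __len__(self):
        return len(self.labels)


@dataclass(frozen=True)
class CycleFragment:
    """A waveform slice spanning an integer number of cardiac cycles."""

    samples: np.ndarray
    rate: float
    start_s: float
    end_s: float
    n_cycles: int
    events: IntervalLabels

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


def runs(labels: np.ndarray):
    """Yield (start, end, label) for maximal constant runs; end is exclusive."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    return [(int(s), int(e), int(labels[s])) for s, e in zip(starts, ends)]


def _remove_short_runs(labels: np.ndarray, min_frames: dict) -> np.ndarray:
    """Iteratively absorb too-short runs into the longer neighbouring run."""
    labels = labels.copy()
    while True:
        rr = runs(labels)
        if len(rr) <= 1:
            return labels
        # pick the shortest offending run (ties: earliest)
        offenders = [
            (e - s, i)
            for i, (s, e, lab) in enumerate(rr)
            if (e - s) < min_frames[lab]
        ]
        if not offenders:
            return labels
        _, i = min(offenders)
        s, e, _ = rr[i]
        left_len = rr[i - 1][1] - rr[i - 1][0] if i > 0 else -1
        right_len = rr[i + 1][1] - rr[i + 1][0] if i < len(rr) - 1 else -1
        absorber = rr[i - 1][2] if left_len >= right_len else rr[i + 1][2]
        labels[s:e] = absorber


def _project_cyclic(labels: np.ndarray) -> np.ndarray:
    """Force the run sequence onto S1 -> systole -> S2 -> diastole order.

    Runs that break the cyclic order are relabeled to the expected successor
    of the previous run.
    """
    rr = runs(labels)
    if not rr:
        return labels
    out = labels.copy()
    prev = rr[0][2]
    for s, e, lab in rr[1:]:
        expected = (prev + 1) % 4
        if lab != expected:
            lab = expected
            out[s:e] = lab
        prev = lab
    return out


def decode(
    posterior: FramePosterior,
    min_dur_ms: dict | None = None,
    enforce_cyclic: bool = False,
) -> StateSequence:
    """Greedy argmax decoding with minimum-duration cleanup.

    Runs shorter than their state's minimum duration (defaults: S1 60 ms,
    systole 80 ms, S2 50 ms, diastole 120 ms) are absorbed into the longer
    neighbour; ``enforce_cyclic`` additionally projects the result onto the
    cyclic state order. Decoding is idempotent.
    """
    table = dict(DEFAULT_MIN_DUR_MS)
    if min_dur_ms:
        table.update(min_dur_ms)
    fr = posterior.frame_rate
    min_frames = {
        i: int(np.ceil(table[name] * fr / 1000.0)) for i, name in enumerate(STATE_NAMES)
    }
    labels = posterior.argmax()
    labels = _remove_short_runs(labels, min_frames)
    if enforce_cyclic:
        # projection merges or relabels whole runs and never shortens one,
        # so it cannot reintroduce sub-minimum runs
        labels = _project_cyclic(labels)
    return StateSequence(labels=labels, frame_rate=fr)


def extract_cycles(states: StateSequence) -> list:
    """Complete cardiac cycles as (start_s, end_s) spans, S1 onset to next S1 onset.

    Incomplete leading/trailing partial cycles are dropped; fewer than two S1
    onsets yields an empty list.
    """
    onsets = [s for s, e, lab in runs(states.labels) if lab == 0]
    if len(onsets) < 2:
        return []
    times = [s / states.frame_rate for s in onsets]
    return [(times[i], times[i + 1]) for i in range(len(times) - 1)]


def states_to_intervals(states: StateSequence) -> list:
    """Per-run (start_s, end_s, state_name) triples (no validity enforcement)."""
    fr = states.frame_rate
    return [
        (s / fr, e / fr, STATE_NAMES[lab]) for s, e, lab in runs(states.labels)
    ]


def fragment_by_cycles(
    signal: Signal,
    cycles: list,
    n_cycles: int,
    events: IntervalLabels | None = None,
    stride: int = 1,
) -> list:
    """Cut overlapping fragments of ``n_cycles`` consecutive cardiac cycles.

    Fragment j spans cycles j..j+n_cycles-1; with the default stride of one
    cycle consecutive fragments overlap by n_cycles-1 cycles. Returns an empty
    list (with a warning) when fewer than ``n_cycles`` cycles are available.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if len(cycles) < n_cycles:
        logger.warning(
            "only %d cycles available; cannot cut %d-cycle fragments",
            len(cycles),
            n_cycles,
        )
        return []
    fragments = []
    for j in range(0, len(cycles) - n_cycles + 1, stride):
        start_s = cycles[j][0]
        end_s = cycles[j + n_cycles - 1][1]
        i0 = int(round(start_s * signal.rate))
        i1 = int(round(end_s * signal.rate))
        sub_events = ()
        if events is not None:
            sub_events = tuple(
                (max(s, start_s) - start_s, min(e, end_s) - start_s, state)
                for s, e, state in events
                if e > start_s + 1e-9 and s < end_s - 1e-9
            )
        fragments.append(
            CycleFragment(
                samples=signal.samples[i0:i1],
                rate=signal.rate,
                start_s=start_s,
                end_s=end_s,
                n_cycles=n_cycles,
                events=IntervalLabels(sub_events),
            )
        )
    return fragments
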