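"""Synthetic pediatric phonocardiogram generator with exact ground truth.

Records are built cycle by cycle at 2 kHz: S1 and S2 are Gaussian-enveloped
band-limited bursts (S1 louder and longer than S2, ~70-150 Hz vs ~90-200 Hz),
systole and diastole durations follow a physiological rule (systole close to
0.3 of the cycle at resting rates and compressing less than diastole as the
rate rises), and per-cycle heart-rate jitter breaks strict periodicity. The
pathology profiles mirror textbook auscultation findings:

* **normal** — clean S1/S2, no murmur;
* **ASD** (atrial septal defect) — fixed split and often accentuated S2, with
  a frequent soft tricuspid-regurgitation systolic murmur;
* **VSD** (ventricular septal defect) — harsh holosystolic band-noise murmur
  filling the S1-S2 interval.

Gaussian white noise is added at a calibrated SNR. Interval labels tile the
record exactly, so every pipeline stage can be scored against sample-accurate
truth. The simulator emulates the statistical structure of short pediatric
auscultation recordings (4-7 cycles per 5 s); it makes no attempt at
clinically realistic acoustics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_preprocess import IntervalLabels, Signal, save_labels, save_wav

CLASSES = ("normal", "ASD", "VSD")


@dataclass(frozen=True)
class BurstSpec:
    """A heart-sound burst: Gaussian-windowed tone + narrowband noise."""

    freq_hz: tuple = (70.0, 150.0)  # carrier drawn per record
    duration_ms: float = 100.0
    amplitude: tuple = (0.9, 1.1)  # drawn per record, jittered per cycle
    split_ms: tuple = (0.0, 0.0)  # > 0 separates the burst into two lobes


@dataclass(frozen=True)
class MurmurSpec:
    kind: str = "none"  # none | holosystolic | diastolic_flow
    band_hz: tuple = (100.0, 300.0)
    amplitude: tuple = (0.0, 0.0)  # drawn per record, jittered per cycle


@dataclass(frozen=True)
class SimProfile:
    """Class-conditional generation parameters for one diagnosis.

    Respiration (0.3-0.5 Hz in children) modulates the record cycle by cycle:
    a *respiratory* S2 split widens on inspiration and closes on expiration
    (the normal pattern), whereas a *fixed* split keeps its width through the
    breath (the ASD hallmark); right-sided murmurs wax with inspiration
    (``murmur_resp_depth``). Occasional broadband transient artifacts
    (movement, contact noise) corrupt individual cycles.
    """

    name: str = "normal"
    heart_rate_bpm: tuple = (70.0, 120.0)
    hr_jitter: float = 0.04  # per-cycle fractional jitter of the cycle length
    s1: BurstSpec = field(default_factory=lambda: BurstSpec((70.0, 150.0), 100.0, (0.9, 1.1)))
    s2: BurstSpec = field(default_factory=lambda: BurstSpec((90.0, 200.0), 80.0, (0.5, 0.7)))
    split_respiratory: bool = True  # split tracks the breath (normal) or stays fixed (ASD)
    murmur: MurmurSpec = field(default_factory=MurmurSpec)
    murmur_resp_depth: float = 0.3  # fractional respiratory modulation of murmur level
    tr_murmur_prob: float = 0.0  # chance of an added tricuspid-regurgitation murmur
    tr_amplitude: tuple = (0.05, 0.25)
    resp_rate_hz: tuple = (0.3, 0.5)  # 18-30 breaths/min
    transient_rate_hz: float = 0.1  # expected broadband artifacts per second
    transient_amplitude: tuple = (0.2, 0.5)
    noise_snr_db: float | None = 15.0

    def __post_init__(self):
        if self.s1.duration_ms <= 0 or self.s2.duration_ms <= 0:
            raise ValueError("burst durations must be positive")


def default_profiles() -> dict:
    """The three study-condition profiles keyed by class name."""
    return {
        # healthy children commonly show an audible respiratory S2 split
        "normal": SimProfile(
            name="normal",
            s2=BurstSpec((90.0, 200.0), 80.0, (0.5, 0.7), split_ms=(20.0, 50.0)),
            split_respiratory=True,
        ),
        # ASD: fixed (non-respiratory) split, often accentuated S2, frequent
        # soft tricuspid-regurgitation murmur that waxes with inspiration
        "ASD": SimProfile(
            name="ASD",
            s2=BurstSpec((90.0, 200.0), 80.0, (0.7, 1.1), split_ms=(30.0, 70.0)),
            split_respiratory=False,
            murmur_resp_depth=0.6,
            tr_murmur_prob=0.7,
            tr_amplitude=(0.05, 0.25),
        ),
        # VSD: harsh holosystolic murmur, mildly respiration-dependent
        "VSD": SimProfile(
            name="VSD",
            murmur=MurmurSpec("holosystolic", (100.0, 300.0), (0.15, 0.6)),
            murmur_resp_depth=0.3,
            tr_murmur_prob=0.3,
            tr_amplitude=(0.05, 0.15),
        ),
    }


@dataclass(frozen=True)
class SimRecord:
    signal: Signal
    labels: IntervalLabels
    pcg_class: str
    seed: int


def _systole_fraction(cycle_s: float) -> float:
    """Fraction of the cycle between S1 end and S2 onset.

    Near 0.3 at a resting 75 bpm cycle (0.8 s) and growing as the cycle
    shortens, so diastole compresses faster than systole at high rates.
    """
    return float(np.clip(0.3 + 0.08 * (0.8 / cycle_s - 1.0), 0.25, 0.45))


def _gaussian_burst(t, center, dur_s, freq, phase, rng, noise_frac=0.3):
    """Unit-peak Gaussian-windowed tone with a dash of in-band noise."""
    sigma = dur_s / 6.0
    env = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    tone = np.cos(2.0 * np.pi * freq * (t - center) + phase)
    ripple = rng.standard_normal(len(t))
    b, a = sps.butter(2, [max(freq * 0.6, 20.0), min(freq * 1.6, 900.0)], btype="band", fs=1.0 / (t[1] - t[0]))
    ripple = sps.filtfilt(b, a, ripple)
    ripple /= max(np.max(np.abs(ripple)), 1e-12)
    return env * (tone + noise_frac * ripple)


def _band_noise(t, rate, band, rng):
    lo, hi = band
    x = rng.standard_normal(len(t))
    b, a = sps.butter(2, [lo, min(hi, rate / 2 * 0.95)], btype="band", fs=rate)
    x = sps.filtfilt(b, a, x)
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


def _tukey_window(n, alpha=0.4):
    return sps.windows.tukey(n, alpha) if n > 2 else np.ones(n)


def simulate_record(
    profile: SimProfile,
    duration_s: float = 5.0,
    rate: float = 2000.0,
    seed: int = 0,
) -> SimRecord:
    """Generate one labelled record; identical seeds give identical records."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    clean = np.zeros(n)

    # per-record draws
    hr = rng.uniform(*profile.heart_rate_bpm)
    s1_freq = rng.uniform(*profile.s1.freq_hz)
    s2_freq = rng.uniform(*profile.s2.freq_hz)
    s1_amp = rng.uniform(*profile.s1.amplitude)
    s2_amp = rng.uniform(*profile.s2.amplitude)
    split_s = rng.uniform(*profile.s2.split_ms) / 1000.0
    murmur_amp = rng.uniform(*profile.murmur.amplitude) if profile.murmur.kind != "none" else 0.0
    has_tr = rng.random() < profile.tr_murmur_prob
    tr_amp = rng.uniform(*profile.tr_amplitude) if has_tr else 0.0
    resp_rate = rng.uniform(*profile.resp_rate_hz)
    resp_phase = rng.uniform(0.0, 2.0 * np.pi)

    s1_dur = profile.s1.duration_ms / 1000.0
    s2_dur = profile.s2.duration_ms / 1000.0

    intervals = []
    start = 0.0
    while start < duration_s:
        cycle_s = (60.0 / hr) * (1.0 + profile.hr_jitter * rng.standard_normal())
        cycle_s = max(cycle_s, s1_dur + s2_dur + 0.1)
        sys_dur = _systole_fraction(cycle_s) * cycle_s
        dia_dur = cycle_s - s1_dur - sys_dur - s2_dur
        if dia_dur <= 0.02:
            raise ValueError(
                f"infeasible timing: S1+systole+S2 exceed the {cycle_s:.3f}s cycle"
            )
        amp_jit = 1.0 + 0.15 * rng.standard_normal(4)
        # inspiration > 0 > expiration at this cycle's onset
        resp = np.sin(2.0 * np.pi * resp_rate * start + resp_phase)

        s1_c = start + s1_dur / 2.0
        clean += s1_amp * abs(amp_jit[0]) * _gaussian_burst(
            t, s1_c, s1_dur, s1_freq, rng.uniform(0, 2 * np.pi), rng
        )
        s2_onset = start + s1_dur + sys_dur
        s2_c = s2_onset + s2_dur / 2.0
        if profile.split_respiratory:
            # physiological split: wide on inspiration, closed on expiration
            split_now = split_s * max(resp, 0.0)
        else:
            split_now = split_s  # fixed split regardless of the breath
        if split_now > 0.008:  # A2 and P2 components of a split second sound
            for offset, rel in ((-split_now / 2.0, 1.0), (split_now / 2.0, 0.8)):
                clean += s2_amp * rel * abs(amp_jit[1]) * _gaussian_burst(
                    t, s2_c + offset, s2_dur * 0.45, s2_freq, rng.uniform(0, 2 * np.pi), rng
                )
        else:
            clean += s2_amp * abs(amp_jit[1]) * _gaussian_burst(
                t, s2_c, s2_dur, s2_freq, rng.uniform(0, 2 * np.pi), rng
            )

        def _windowed_murmur(w_start, w_end, amp, band):
            i0, i1 = int(round(w_start * rate)), int(round(w_end * rate))
            i0, i1 = max(i0, 0), min(i1, n)
            if i1 - i0 < 32 or amp <= 0:  # clipped tail windows are skipped
                return
            noise = _band_noise(t[i0:i1], rate, band, rng)
            clean[i0:i1] += amp * _tukey_window(i1 - i0) * noise

        resp_gain = max(1.0 + profile.murmur_resp_depth * resp, 0.05)
        if profile.murmur.kind == "holosystolic":
            _windowed_murmur(
                start + s1_dur * 0.7,
                s2_onset + s2_dur * 0.3,
                murmur_amp * resp_gain * abs(amp_jit[2]),
                profile.murmur.band_hz,
            )
        elif profile.murmur.kind == "diastolic_flow":
            _windowed_murmur(
                s2_onset + s2_dur + 0.05,
                s2_onset + s2_dur + 0.05 + 0.5 * dia_dur,
                murmur_amp * resp_gain * abs(amp_jit[2]),
                profile.murmur.band_hz,
            )
        if has_tr:
            # right-sided murmur: louder on inspiration (Carvallo's sign)
            tr_gain = max(1.0 + 0.6 * resp, 0.05)
            _windowed_murmur(
                start + s1_dur,
                s2_onset,
                tr_amp * tr_gain * abs(amp_jit[3]),
                (150.0, 350.0),
            )

        for seg_start, seg_dur, state in (
            (start, s1_dur, "S1"),
            (start + s1_dur, sys_dur, "systole"),
            (s2_onset, s2_dur, "S2"),
            (s2_onset + s2_dur, dia_dur, "diastole"),
        ):
            s_clip = min(seg_start, duration_s)
            e_clip = min(seg_start + seg_dur, duration_s)
            if e_clip > s_clip:
                intervals.append((s_clip, e_clip, state))
        start += cycle_s

    # occasional broadband transient artifacts (movement / contact noise)
    n_transients = rng.poisson(profile.transient_rate_hz * duration_s)
    for _ in range(n_transients):
        dur = rng.uniform(0.05, 0.12)
        t0_art = rng.uniform(0.0, max(duration_s - dur, 0.0))
        i0 = int(round(t0_art * rate))
        i1 = min(int(round((t0_art + dur) * rate)), n)
        if i1 - i0 >= 32:
            amp = rng.uniform(*profile.transient_amplitude)
            clean[i0:i1] += amp * _tukey_window(i1 - i0, 0.6) * _band_noise(
                t[i0:i1], rate, (150.0, 600.0), rng
            )

    if profile.noise_snr_db is not None and np.isfinite(profile.noise_snr_db):
        p_signal = float(np.mean(clean**2))
        p_noise = p_signal / (10.0 ** (profile.noise_snr_db / 10.0))
        clean = clean + np.sqrt(p_noise) * rng.standard_normal(n)

    sig = Signal(samples=clean, rate=rate, source_id=f"sim_{profile.name}_{seed}")
    return SimRecord(
        signal=sig,
        labels=IntervalLabels(tuple(intervals)),
        pcg_class=profile.name,
        seed=seed,
    )


def simulate_dataset(
    n_per_class: int,
    profiles: dict | None = None,
    seed: int = 0,
    duration_s: float = 5.0,
    rate: float = 2000.0,
):
    """Balanced labelled dataset: ``n_per_class`` records for each class.

    Per-record seeds are spawned deterministically from the master seed.
    Returns ``(records, manifest)`` with a pandas manifest (record_id, class,
    seed, duration_s, n_cycles).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if profiles is None:
        profiles = default_profiles()
    master = np.random.default_rng(seed)
    records, rows = [], []
    for cls in sorted(profiles):
        profile = profiles[cls]
        for i in range(n_per_class):
            rec_seed = int(master.integers(0, 2**31 - 1))
            rec = simulate_record(profile, duration_s=duration_s, rate=rate, seed=rec_seed)
            rec_id = f"{cls}_{i:03d}"
            rec = replace(
                rec, signal=replace(rec.signal, source_id=rec_id)
            )
            records.append(rec)
            n_cycles = sum(1 for _, _, st in rec.labels if st == "S1")
            rows.append(
                {
                    "record_id": rec_id,
                    "class": cls,
                    "seed": rec_seed,
                    "duration_s": duration_s,
                    "n_cycles": n_cycles,
                }
            )
    manifest = pd.DataFrame(rows)
    return records, manifest


def write_dataset(records, manifest: pd.DataFrame, out_dir) -> None:
    """Write per-record WAV + label CSV and the dataset manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in records:
        stem = rec.signal.source_id
        save_wav(out / f"{stem}.wav", rec.signal)
        save_labels(out / f"{stem}_labels.csv", rec.labels)
    manifest.to_csv(out / "manifest.csv", index=False)
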