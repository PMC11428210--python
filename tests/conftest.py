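"""Shared fixtures: small synthetic records and deterministic profiles."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from pcgseg import synthetic_pcg
from pcgseg.io_preprocess import Signal


@pytest.fixture(scope="session")
def clean_profiles():
    """Noiseless versions of the three class profiles."""
    return {
        name: replace(p, noise_snr_db=None)
        for name, p in synthetic_pcg.default_profiles().items()
    }


@pytest.fixture(scope="session")
def fixed_rate_profile():
    """Noiseless normal profile with the heart rate pinned to 80 bpm."""
    base = synthetic_pcg.default_profiles()["normal"]
    return replace(base, heart_rate_bpm=(80.0, 80.0), hr_jitter=0.0, noise_snr_db=None)


@pytest.fixture(scope="session")
def normal_record(clean_profiles):
    return synthetic_pcg.simulate_record(clean_profiles["normal"], seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tone_2k():
    """One-second 100 Hz unit sinusoid at 2 kHz."""
    t = np.arange(2000) / 2000.0
    return Signal(samples=np.sin(2 * np.pi * 100.0 * t), rate=2000.0, source_id="tone")
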