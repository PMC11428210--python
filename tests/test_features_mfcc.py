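"""MFCC chain vs. a literal textbook implementation, deltas, aggregation, PCA."""

import numpy as np
import pytest

from pcgseg.features_mfcc import (
    LOG_FLOOR,
    MelFilterbank,
    aggregate_fragment,
    delta_features,
    frame_signal,
    fragment_feature_vector,
    hz_to_mel,
    mfcc_frames,
    pca_fit_transform,
)
from pcgseg.io_preprocess import Signal


@pytest.fixture(scope="module")
def bank():
    return MelFilterbank(rate=2000.0)


class TestFraming:
    def test_frame_count_5s_record(self):
        sig = Signal(np.zeros(10_000), 2000.0, "z")
        assert frame_signal(sig).shape == (499, 40)  # floor((10000-40)/20)+1

    def test_exactly_one_frame(self):
        sig = Signal(np.ones(40), 2000.0, "one")
        assert frame_signal(sig).shape[0] == 1

    def test_zero_signal_zero_frames_energy(self):
        sig = Signal(np.zeros(400), 2000.0, "z")
        assert np.all(frame_signal(sig) == 0.0)

    def test_too_short_warns_and_returns_empty(self, caplog):
        sig = Signal(np.zeros(10), 2000.0, "tiny")
        with caplog.at_level("WARNING"):
            frames = frame_signal(sig)
        assert frames.shape[0] == 0


class TestFilterbank:
    def test_filters_nonnegative_with_positive_rowsums(self, bank):
        W = bank.weights()
        assert W.shape[0] == 26
        assert np.all(W >= 0)
        assert np.all(W.sum(axis=1) > 0)  # no empty filter at n_fft=256

    def test_support_within_band(self, bank):
        W = bank.weights()
        bins_hz = np.arange(bank.n_fft // 2 + 1) * bank.rate / bank.n_fft
        active = np.any(W > 0, axis=0)
        assert bins_hz[active].min() >= 30.0 - bank.rate / bank.n_fft
        assert bins_hz[active].max() <= 500.0 + bank.rate / bank.n_fft

    def test_centers_monotone_on_mel_scale(self, bank):
        centers = bank.center_freqs_hz[1:-1]
        mels = hz_to_mel(centers)
        assert np.all(np.diff(mels) > 0)
        diffs = np.diff(hz_to_mel(bank.center_freqs_hz))
        np.testing.assert_allclose(diffs, diffs[0], rtol=1e-9)  # equal mel spacing

    def test_adjacent_filters_overlap(self, bank):
        W = bank.weights()
        for m in range(25):
            assert np.any((W[m] > 0) & (W[m + 1] > 0))


def literal_mfcc(frames, bank, n_coeffs=13):
    """Independent loop implementation: DFT, triangles, log, textbook DCT-II."""
    n_fft = bank.n_fft
    n_bins = n_fft // 2 + 1
    bins_hz = np.arange(n_bins) * bank.rate / n_fft
    edges = bank.center_freqs_hz
    out = np.zeros((frames.shape[0], n_coeffs))
    M = bank.n_filters
    for t in range(frames.shape[0]):
        padded = np.zeros(n_fft)
        padded[: frames.shape[1]] = frames[t]
        power = np.zeros(n_bins)
        for j in range(n_bins):
            re = sum(padded[n] * np.cos(2 * np.pi * j * n / n_fft) for n in range(n_fft))
            im = -sum(padded[n] * np.sin(2 * np.pi * j * n / n_fft) for n in range(n_fft))
            power[j] = re * re + im * im
        loge = np.zeros(M)
        for m in range(M):
            lo, ctr, hi = edges[m], edges[m + 1], edges[m + 2]
            e = 0.0
            for j in range(n_bins):
                f = bins_hz[j]
                w = min((f - lo) / (ctr - lo), (hi - f) / (hi - ctr))
                e += max(w, 0.0) * power[j]
            loge[m] = np.log(max(e, LOG_FLOOR))
        for k in range(n_coeffs):
            c = sum(loge[m] * np.cos(np.pi * k * (2 * m + 1) / (2 * M)) for m in range(M))
            scale = np.sqrt(2.0 / M) if k else np.sqrt(1.0 / M)
            out[t, k] = scale * c
    return out


class TestMfcc:
    def test_thirteen_columns(self, bank, rng):
        frames = rng.standard_normal((5, 40))
        assert mfcc_frames(frames, bank).shape == (5, 13)

    def test_flat_log_spectrum_concentrates_in_c0(self, bank, monkeypatch):
        # constant filterbank energies -> DCT of a constant: only c0 nonzero
        frames = np.zeros((1, 40))
        out = mfcc_frames(frames, bank)  # silent frame -> floored constant energies
        assert abs(out[0, 0]) > 0
        np.testing.assert_allclose(out[0, 1:], 0.0, atol=1e-9)

    def test_amplitude_doubling_shifts_only_c0(self, bank, rng):
        frames = rng.standard_normal((4, 40))
        a = mfcc_frames(frames, bank)
        b = mfcc_frames(2.0 * frames, bank)
        np.testing.assert_allclose(a[:, 1:], b[:, 1:], atol=1e-6)
        shift = b[:, 0] - a[:, 0]
        np.testing.assert_allclose(shift, shift[0], atol=1e-6)

    def test_matches_literal_loop_implementation(self, bank, rng):
        frames = rng.standard_normal((3, 40))
        fast = mfcc_frames(frames, bank)
        slow = literal_mfcc(frames, bank)
        np.testing.assert_allclose(fast, slow, atol=1e-6)

    def test_silent_frames_finite(self, bank):
        out = mfcc_frames(np.zeros((3, 40)), bank)
        assert np.all(np.isfinite(out))

    def test_drop_c0_mode(self, bank, rng):
        frames = rng.standard_normal((4, 40))
        kept = mfcc_frames(frames, bank, drop_c0=True)
        full = mfcc_frames(frames, bank, n_coeffs=14)
        np.testing.assert_allclose(kept, full[:, 1:14])


class TestDeltas:
    def test_constant_input_zero_deltas(self):
        mfcc = np.ones((10, 13))
        out = delta_features(mfcc)
        assert out.shape == (10, 39)
        np.testing.assert_allclose(out[:, 13:], 0.0)

    def test_width_39_for_any_13col_input(self, rng):
        assert delta_features(rng.standard_normal((7, 13))).shape[1] == 39

    def test_linear_ramp_constant_delta_zero_delta2(self):
        t = np.arange(20, dtype=float)[:, None]
        mfcc = np.tile(t, (1, 13)) * 0.5
        out = delta_features(mfcc)
        d1 = out[5:-5, 13:26]  # away from edge padding
        np.testing.assert_allclose(d1, 0.5, atol=1e-9)
        np.testing.assert_allclose(out[5:-5, 26:], 0.0, atol=1e-9)

    def test_single_frame_zero_deltas(self):
        out = delta_features(np.ones((1, 13)))
        np.testing.assert_allclose(out[:, 13:], 0.0)


class TestAggregate:
    def test_single_frame(self):
        frame = np.arange(39, dtype=float)[None, :]
        vec = aggregate_fragment(frame)
        np.testing.assert_allclose(vec[:39], frame[0])
        np.testing.assert_allclose(vec[39:], 0.0)

    def test_length_78(self, rng):
        assert len(aggregate_fragment(rng.standard_normal((20, 39)))) == 78

    def test_frame_order_invariance(self, rng):
        feat = rng.standard_normal((15, 39))
        perm = rng.permutation(15)
        np.testing.assert_allclose(
            aggregate_fragment(feat), aggregate_fragment(feat[perm]), atol=1e-12
        )


class TestPCA:
    def test_planar_data_keeps_two_components(self, rng):
        basis = rng.standard_normal((2, 10))
        coords = rng.standard_normal((50, 2))
        X = coords @ basis  # exactly 2-D subspace
        train, _, proj = pca_fit_transform(X, None, retained_variance=0.95)
        assert proj.pca.n_components_ == 2

    def test_full_variance_component_count(self, rng):
        X = rng.standard_normal((10, 20))
        _, _, proj = pca_fit_transform(X, None, retained_variance=1.0)
        assert proj.pca.n_components_ == 9  # min(rows-1, dims)

    def test_train_mean_maps_to_zero(self, rng):
        X = rng.standard_normal((30, 8))
        _, _, proj = pca_fit_transform(X, None)
        out = proj.transform(X.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_invalid_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_fit_transform(rng.standard_normal((10, 4)), None, retained_variance=0.0)

    def test_no_test_set_leakage(self, rng):
        X_train = rng.standard_normal((40, 12))
        X_test = rng.standard_normal((10, 12))
        _, out1, proj1 = pca_fit_transform(X_train, X_test)
        perm = rng.permutation(10)
        _, out2, proj2 = pca_fit_transform(X_train, X_test[perm])
        np.testing.assert_allclose(proj1.pca.components_, proj2.pca.components_)
        np.testing.assert_allclose(out1[perm], out2, atol=1e-12)


def test_fragment_feature_vector_end_to_end(normal_record):
    vec = fragment_feature_vector(
        normal_record.signal.samples[:2000], normal_record.signal.rate
    )
    assert vec.shape == (78,)
    assert np.all(np.isfinite(vec))
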