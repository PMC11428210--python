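"""Independent brute-force oracles used by the acceptance tests.

These are deliberately naive, loop-based transcriptions of the defining
formulas, kept separate from (and never importing) the implementations they
check.
"""

import numpy as np


def brute_force_causal(x, f):
    """y_n = sum_{k=1..K} f_k x_{n-K+k}, zero outside the sequence."""
    K, N = len(f), len(x)
    y = np.zeros(N)
    for n in range(N):
        for k in range(1, K + 1):
            idx = n - K + k
            if idx >= 0:
                y[n] += f[k - 1] * x[idx]
    return y


def brute_force_dilated(x, f, d):
    """y_n = sum_{k=1..K} f_k x_{n-(K-k)d}, zero outside the sequence."""
    K, N = len(f), len(x)
    y = np.zeros(N)
    for n in range(N):
        for k in range(1, K + 1):
            idx = n - (K - k) * d
            if idx >= 0:
                y[n] += f[k - 1] * x[idx]
    return y


def scalar_lstm(x_t, h_prev, c_prev, p):
    """Element-by-element gate equations with explicit [h, x] concatenation."""
    H = len(h_prev)
    hx = list(h_prev) + list(x_t)
    h_out, c_out = np.zeros(H), np.zeros(H)
    for j in range(H):
        zi = sum(p.W_i[j][m] * hx[m] for m in range(len(hx))) + p.b_i[j]
        zf = sum(p.W_f[j][m] * hx[m] for m in range(len(hx))) + p.b_f[j]
        zo = sum(p.W_o[j][m] * hx[m] for m in range(len(hx))) + p.b_o[j]
        zc = sum(p.W_C[j][m] * hx[m] for m in range(len(hx))) + p.b_C[j]
        i = 1.0 / (1.0 + np.exp(-zi))
        f = 1.0 / (1.0 + np.exp(-zf))
        o = 1.0 / (1.0 + np.exp(-zo))
        c = f * c_prev[j] + i * np.tanh(zc)
        c_out[j] = c
        h_out[j] = o * np.tanh(c)
    return h_out, c_out


def literal_mfcc_frame(frame, bank, n_coeffs=13, log_floor=1e-10):
    """One frame through DFT -> triangles -> log -> textbook orthonormal DCT-II."""
    n_fft = bank.n_fft
    n_bins = n_fft // 2 + 1
    bins_hz = np.arange(n_bins) * bank.rate / n_fft
    edges = bank.center_freqs_hz
    M = bank.n_filters
    padded = np.zeros(n_fft)
    padded[: len(frame)] = frame
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
        loge[m] = np.log(max(e, log_floor))
    out = np.zeros(n_coeffs)
    for k in range(n_coeffs):
        c = sum(loge[m] * np.cos(np.pi * k * (2 * m + 1) / (2 * M)) for m in range(M))
        out[k] = (np.sqrt(2.0 / M) if k else np.sqrt(1.0 / M)) * c
    return out


def bruteforce_metrics(counts, mode):
    """Acc/Se/P/F1 recomputed with plain scalar arithmetic per state."""
    names = ("S1", "systole", "S2", "diastole")
    out = {}
    for i, name in enumerate(names):
        tp, fp = float(counts.tp[i]), float(counts.fp[i])
        tn, fn = float(counts.tn[i]), float(counts.fn[i])
        total = tp + fp + tn + fn
        acc = (tp + tn) / total if total else 0.0
        se = tp / (tp + fn) if tp + fn else 0.0
        if mode == "printed":
            p = tn / (tn + fp) if tn + fp else 0.0
        else:
            p = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * se * p / (se + p) if se + p else 0.0
        out[name] = {"Acc": acc, "Se": se, "P": p, "F1": f1}
    return out
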