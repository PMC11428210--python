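"""Minimal numpy neural-network layers with hand-written backpropagation.

The segmentation network is small (a few hundred thousand parameters) and runs
on CPU, so the layers below implement exactly the pieces it needs — causal and
dilated causal 1-D convolution, ReLU, max-pooling, linear-interpolation
upsampling, LSTM / Bi-LSTM, dropout, a dense head, softmax cross-entropy and
Adam — each as a stateful object with ``forward`` caching whatever its
``backward`` needs. Shapes follow the (batch, time, channels) convention.

Every layer's gradient is exercised by finite-difference checks in the test
suite; randomness (init, dropout, shuffling) is funneled through explicit
``numpy.random.Generator`` instances.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=float)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self):
        self.grad.fill(0.0)


def _uniform_fan_in(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class CausalConv1d:
    """Causal (optionally dilated) 1-D convolution.

    Output frame ``n`` sees only input frames ``<= n``: the input is
    left-padded by ``(K-1)*d`` zeros, giving a receptive field of
    ``(K-1)*d + 1`` frames and output length equal to input length.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, dilation: int, rng):
        if kernel_size < 1 or dilation < 1:
            raise ValueError("kernel_size and dilation must be >= 1")
        self.K, self.d = kernel_size, dilation
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel_size
        self.W = Param(_uniform_fan_in(rng, (kernel_size, c_in, c_out), fan_in))
        self.b = Param(_uniform_fan_in(rng, (c_out,), fan_in))
        self._xp = None

    @property
    def receptive_field(self) -> int:
        return (self.K - 1) * self.d + 1

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        pad = (self.K - 1) * self.d
        xp = np.pad(x, ((0, 0), (pad, 0), (0, 0)))
        y = np.broadcast_to(self.b.data, (B, T, self.c_out)).copy()
        for k in range(self.K):
            y += xp[:, k * self.d : k * self.d + T, :] @ self.W.data[k]
        self._xp = xp
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        xp = self._xp
        B, T, _ = g.shape
        pad = (self.K - 1) * self.d
        self.b.grad += g.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        for k in range(self.K):
            sl = slice(k * self.d, k * self.d + T)
            self.W.grad[k] += np.einsum("btc,btd->cd", xp[:, sl, :], g)
            dxp[:, sl, :] += g @ self.W.data[k].T
        return dxp[:, pad:, :]


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool1d:
    """Max-pooling over time, window 2, stride 2 (odd tail frame dropped)."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x):
        B, T, C = x.shape
        T2 = T // 2
        if T2 == 0:
            raise ValueError("sequence too short to pool")
        pairs = x[:, : 2 * T2, :].reshape(B, T2, 2, C)
        take_second = pairs[:, :, 1, :] > pairs[:, :, 0, :]
        y = np.where(take_second, pairs[:, :, 1, :], pairs[:, :, 0, :])
        self._cache = (x.shape, take_second)
        return y

    def backward(self, g):
        (B, T, C), take_second = self._cache
        T2 = T // 2
        dpairs = np.zeros((B, T2, 2, C))
        dpairs[:, :, 1, :] = np.where(take_second, g, 0.0)
        dpairs[:, :, 0, :] = np.where(take_second, 0.0, g)
        dx = np.zeros((B, T, C))
        dx[:, : 2 * T2, :] = dpairs.reshape(B, 2 * T2, C)
        return dx


class Upsample1d:
    """Linear interpolation along time to a target length (endpoint-aligned)."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x, t_out: int):
        B, t_in, C = x.shape
        if t_in == 1:
            lo = np.zeros(t_out, dtype=int)
            hi = lo
            w = np.zeros(t_out)
        else:
            pos = np.linspace(0.0, t_in - 1.0, t_out)
            lo = np.floor(pos).astype(int)
            hi = np.minimum(lo + 1, t_in - 1)
            w = pos - lo
        y = x[:, lo, :] * (1.0 - w)[None, :, None] + x[:, hi, :] * w[None, :, None]
        self._cache = (x.shape, lo, hi, w)
        return y

    def backward(self, g):
        shape, lo, hi, w = self._cache
        dx = np.zeros(shape)
        np.add.at(dx, (slice(None), lo, slice(None)), g * (1.0 - w)[None, :, None])
        np.add.at(dx, (slice(None), hi, slice(None)), g * w[None, :, None])
        return dx


class Dropout:
    """Inverted dropout; active only when ``train=True`` in :meth:`forward`."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def params(self):
        return []

    def forward(self, x, train: bool, rng: np.random.Generator | None = None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Dense:
    def __init__(self, c_in: int, c_out: int, rng):
        self.W = Param(_uniform_fan_in(rng, (c_in, c_out), c_in))
        self.b = Param(_uniform_fan_in(rng, (c_out,), c_in))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, g):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        self.W.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return g @ self.W.data.T


def sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class LSTM:
    """Single-direction LSTM over (batch, time, channels).

    Gates are computed in one fused matmul per step; order along the last
    axis of the weight matrices is [input, forget, output, candidate].
    """

    def __init__(self, c_in: int, hidden: int, rng):
        self.c_in, self.H = c_in, hidden
        fan_in = c_in + hidden
        self.Wx = Param(_uniform_fan_in(rng, (c_in, 4 * hidden), fan_in))
        self.Wh = Param(_uniform_fan_in(rng, (hidden, 4 * hidden), fan_in))
        self.b = Param(_uniform_fan_in(rng, (4 * hidden,), fan_in))
        self._cache = None

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x):
        B, T, _ = x.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        steps = []
        for t in range(T):
            z = x[:, t, :] @ self.Wx.data + h @ self.Wh.data + self.b.data
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            o = sigmoid(z[:, 2 * H : 3 * H])
            g_ = np.tanh(z[:, 3 * H :])
            c_new = f * c + i * g_
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            steps.append((h, c, i, f, o, g_, tanh_c))
            h, c = h_new, c_new
            hs[:, t, :] = h
        self._cache = (x, steps)
        return hs

    def backward(self, grad_hs):
        x, steps = self._cache
        B, T, _ = x.shape
        H = self.H
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, o, g_, tanh_c = steps[t]
            dh = grad_hs[:, t, :] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di = dc * g_
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    do * o * (1.0 - o),
                    dg * (1.0 - g_**2),
                ],
                axis=1,
            )
            self.Wx.grad += x[:, t, :].T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.data.T
            dh_next = dz @ self.Wh.data.T
            dc_next = dc * f
        return dx


class BiLSTM:
    """Bidirectional LSTM: forward and time-reversed passes, concatenated.

    ``bidirectional=False`` degrades to a single forward LSTM (width H
    instead of 2H), which is the unidirectional "TLSTM" variant.
    """

    def __init__(self, c_in: int, hidden: int, rng, bidirectional: bool = True):
        self.bidirectional = bidirectional
        self.fwd = LSTM(c_in, hidden, rng)
        self.bwd = LSTM(c_in, hidden, rng) if bidirectional else None

    @property
    def out_width(self) -> int:
        return self.fwd.H * (2 if self.bidirectional else 1)

    def params(self):
        ps = self.fwd.params()
        if self.bwd is not None:
            ps = ps + self.bwd.params()
        return ps

    def forward(self, x):
        hf = self.fwd.forward(x)
        if not self.bidirectional:
            return hf
        hb = self.bwd.forward(x[:, ::-1, :])[:, ::-1, :]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, g):
        if not self.bidirectional:
            return self.fwd.backward(g)
        H = self.fwd.H
        dxf = self.fwd.backward(g[:, :, :H])
        dxb = self.bwd.backward(g[:, ::-1, H:][:, :, :])[:, ::-1, :]
        return dxf + dxb


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class SoftmaxCrossEntropy:
    """Mean per-frame cross-entropy with optional per-class weights."""

    def __init__(self, class_weights: np.ndarray | None = None):
        self.class_weights = class_weights
        self._cache = None

    def forward(self, logits: np.ndarray, labels: np.ndarray) -> float:
        p = softmax(logits)
        flat_p = p.reshape(-1, p.shape[-1])
        flat_y = labels.reshape(-1)
        w = (
            np.ones(len(flat_y))
            if self.class_weights is None
            else np.asarray(self.class_weights)[flat_y]
        )
        nll = -np.log(flat_p[np.arange(len(flat_y)), flat_y] + 1e-12)
        loss = float((w * nll).sum() / w.sum())
        self._cache = (p, labels, w)
        return loss

    def backward(self) -> np.ndarray:
        p, labels, w = self._cache
        grad = p.copy().reshape(-1, p.shape[-1])
        flat_y = labels.reshape(-1)
        grad[np.arange(len(flat_y)), flat_y] -= 1.0
        grad *= (w / w.sum())[:, None]
        return grad.reshape(p.shape)


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            mhat = m / (1.0 - self.b1**self.t)
            vhat = v / (1.0 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
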