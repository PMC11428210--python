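"""The TBLSTM heart-sound segmenter.

Architecture: a multi-scale temporal convolutional network (five residual
blocks with dilation rates 2, 4, 8, 16, 16, each followed by max-pooling with
window and stride 2), whose per-scale outputs are upsampled back to the input
frame count and fused; a bidirectional LSTM capturing rhythm across cardiac
cycles; dropout; and a dense + softmax head emitting per-frame posteriors over
the four cardiac states (S1=0, systole=1, S2=2, diastole=3).

Training uses Adam (lr 0.001), per-frame cross-entropy, batch size 32 and 90
epochs by default. A `bidirectional=False` configuration gives the
unidirectional "TLSTM" variant.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .envelopes import FrameFeatureMatrix, build_feature_matrix
from .io_preprocess import Signal

logger = logging.getLogger(__name__)

MIN_FRAMES = 32  # five pooling stages halve the sequence; shorter inputs degenerate


# ---------------------------------------------------------------------------
# Functional reference operations (1-D sequences, 1-D kernels)
# ---------------------------------------------------------------------------

def causal_conv(x, kernel) -> np.ndarray:
    """Causal convolution ``y_n = sum_{k=1..K} f_k x_{n-K+k}`` (left zero-padded).

    Output frame n depends only on input frames <= n; output length equals
    input length.
    """
    return dilated_causal_conv(x, kernel, dilation=1)


def dilated_causal_conv(x, kernel, dilation: int = 1) -> np.ndarray:
    """Dilated causal convolution ``y_n = sum_{k=1..K} f_k x_{n-(K-k)d}``.

    The receptive field is ``(K-1)*d + 1``; the input is left zero-padded by
    ``(K-1)*d`` so lengths are preserved.
    """
    x = np.asarray(x, dtype=float)
    f = np.asarray(kernel, dtype=float)
    K = len(f)
    if K < 1 or dilation < 1:
        raise ValueError("kernel length and dilation must be >= 1")
    T = len(x)
    pad = (K - 1) * dilation
    xp = np.concatenate([np.zeros(pad), x])
    y = np.zeros(T)
    for k in range(K):  # tap k (0-based) reads x_{n-(K-1-k)d}
        y += f[k] * xp[k * dilation : k * dilation + T]
    return y


@dataclass
class LSTMParams:
    """Weights of one LSTM unit acting on the concatenation [h_{t-1}, x_t].

    ``W_*`` have shape (hidden, hidden + input); ``b_*`` have shape (hidden,).
    """

    W_i: np.ndarray
    W_f: np.ndarray
    W_o: np.ndarray
    W_C: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_C: np.ndarray


def lstm_step(x_t, h_prev, c_prev, params: LSTMParams):
    """One LSTM update: gates by sigmoid, candidate by tanh.

    i = sigma(W_i [h,x] + b_i), f, o likewise; C~ = tanh(W_C [h,x] + b_C);
    C_t = f*C_{t-1} + i*C~; h_t = o * tanh(C_t)  (elementwise products).
    """
    hx = np.concatenate([np.asarray(h_prev, float), np.asarray(x_t, float)])
    i = nn.sigmoid(params.W_i @ hx + params.b_i)
    f = nn.sigmoid(params.W_f @ hx + params.b_f)
    o = nn.sigmoid(params.W_o @ hx + params.b_o)
    c_tilde = np.tanh(params.W_C @ hx + params.b_C)
    c_t = f * np.asarray(c_prev, float) + i * c_tilde
    h_t = o * np.tanh(c_t)
    return h_t, c_t


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Hyper-parameters of the TBLSTM segmenter.

    Defaults follow the published training recipe (dilations 2,4,8,16,16;
    Adam lr 0.001; batch 32; 90 epochs); kernel size, channel width, LSTM
    width and dropout rate are free choices documented in the methods note.
    """

    dilations: tuple = (2, 4, 8, 16, 16)
    kernel_size: int = 3
    channels: int = 32
    lstm_hidden: int = 64
    bidirectional: bool = True
    dropout_rate: float = 0.25
    n_classes: int = 4
    lr: float = 0.001
    batch_size: int = 32
    epochs: int = 90
    seed: int = 0
    n_input_channels: int = 4
    frame_rate: float = 50.0
    fusion: str = "concat"  # or "sum"
    class_weights: tuple | None = None

    def __post_init__(self):
        self.dilations = tuple(int(d) for d in self.dilations)
        if self.fusion not in ("concat", "sum"):
            raise ValueError("fusion must be 'concat' or 'sum'")


@dataclass
class FramePosterior:
    """Per-frame state probabilities (frames x 4; rows sum to 1)."""

    probs: np.ndarray
    frame_rate: float

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("probs must be 2-D")
        rowsum = self.probs.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > 1e-6) or np.any(self.probs < -1e-12):
            raise ValueError("rows must be probability distributions")

    def argmax(self) -> np.ndarray:
        return self.probs.argmax(axis=1)


class ResidualBlock:
    """Dilated causal conv -> ReLU -> causal conv -> ReLU, plus skip.

    The skip path is the identity when input and output channel counts match,
    otherwise a 1x1 convolution.
    """

    def __init__(self, c_in, c_out, kernel_size, dilation, rng):
        self.dconv = nn.CausalConv1d(c_in, c_out, kernel_size, dilation, rng)
        self.relu1 = nn.ReLU()
        self.conv = nn.CausalConv1d(c_out, c_out, kernel_size, 1, rng)
        self.relu2 = nn.ReLU()
        self.skip = None if c_in == c_out else nn.CausalConv1d(c_in, c_out, 1, 1, rng)

    def params(self):
        ps = self.dconv.params() + self.conv.params()
        if self.skip is not None:
            ps += self.skip.params()
        return ps

    def forward(self, x):
        h = self.relu2.forward(self.conv.forward(self.relu1.forward(self.dconv.forward(x))))
        s = x if self.skip is None else self.skip.forward(x)
        return h + s

    def backward(self, g):
        dx_main = self.dconv.backward(
            self.relu1.backward(self.conv.backward(self.relu2.backward(g)))
        )
        dx_skip = g if self.skip is None else self.skip.backward(g)
        return dx_main + dx_skip


class TBLSTM:
    """Multi-scale TCN + Bi-LSTM frame classifier. Build via :func:`build_model`."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        c = config.channels
        self.blocks = []
        c_in = config.n_input_channels
        for d in config.dilations:
            self.blocks.append(ResidualBlock(c_in, c, config.kernel_size, d, rng))
            c_in = c
        self.pools = [nn.MaxPool1d() for _ in config.dilations]
        self.upsamplers = [nn.Upsample1d() for _ in config.dilations]
        n_scales = len(config.dilations)
        fused_c = c * n_scales if config.fusion == "concat" else c
        self.bilstm = nn.BiLSTM(fused_c, config.lstm_hidden, rng, config.bidirectional)
        self.dropout = nn.Dropout(config.dropout_rate)
        self.head = nn.Dense(self.bilstm.out_width, config.n_classes, rng)
        self.trained = False

    def params(self):
        ps = []
        for b in self.blocks:
            ps += b.params()
        ps += self.bilstm.params()
        ps += self.head.params()
        return ps

    # -- multi-scale TCN ---------------------------------------------------
    def fuse(self, x: np.ndarray) -> np.ndarray:
        """Multi-scale fused representation of a (B, T, C_in) batch.

        Each residual block feeds a window-2/stride-2 max-pool whose output is
        the next block's input; every block's pre-pool output is upsampled
        back to T frames and the maps are concatenated (or summed) channel-wise.
        """
        B, T, _ = x.shape
        if T < MIN_FRAMES:
            raise ValueError(f"input has {T} frames; need >= {MIN_FRAMES}")
        maps = []
        h = x
        for block, pool, up in zip(self.blocks, self.pools, self.upsamplers):
            pre = block.forward(h)
            maps.append(up.forward(pre, T))
            h = pool.forward(pre)
        if self.config.fusion == "concat":
            return np.concatenate(maps, axis=2)
        return np.sum(maps, axis=0)

    def _fuse_backward(self, g: np.ndarray) -> np.ndarray:
        c = self.config.channels
        n = len(self.blocks)
        if self.config.fusion == "concat":
            gs = [g[:, :, i * c : (i + 1) * c] for i in range(n)]
        else:
            gs = [g] * n
        d_next = None  # gradient flowing into pool of current block from deeper blocks
        for i in range(n - 1, -1, -1):
            gpre = self.upsamplers[i].backward(gs[i])
            if d_next is not None:
                gpre = gpre + self.pools[i].backward(d_next)
            d_next = self.blocks[i].backward(gpre)
        return d_next

    # -- full network ------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        """Logits (B, T, n_classes) for a batch of feature matrices."""
        fused = self.fuse(x)
        h = self.bilstm.forward(fused)
        h = self.dropout.forward(h, train=train, rng=rng)
        return self.head.forward(h)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.head.backward(g)
        g = self.dropout.backward(g)
        g = self.bilstm.backward(g)
        return self._fuse_backward(g)

    def posterior(self, features: FrameFeatureMatrix) -> FramePosterior:
        """Inference on one record (dropout off, deterministic)."""
        logits = self.forward(features.values[None, :, :], train=False)
        return FramePosterior(nn.softmax(logits)[0], features.frame_rate)


def build_model(config: ModelConfig) -> TBLSTM:
    """Construct an untrained TBLSTM with seeded weight initialization."""
    rng = np.random.default_rng(config.seed)
    return TBLSTM(config, rng)


# ---------------------------------------------------------------------------
# Training / inference
# ---------------------------------------------------------------------------

def _as_xy(item):
    feats, labels = item
    x = feats.values if isinstance(feats, FrameFeatureMatrix) else np.asarray(feats, float)
    y = np.asarray(labels, dtype=int)
    if x.shape[0] != len(y):
        raise ValueError("feature frames and labels disagree in length")
    if y.min() < 0 or y.max() > 3:
        raise ValueError("labels must lie in {0,1,2,3}")
    return x, y


def train_segmenter(dataset, config: ModelConfig, model: TBLSTM | None = None):
    """Train a TBLSTM on (FrameFeatureMatrix, frame-labels) pairs.

    Minimizes mean per-frame cross-entropy with Adam for ``config.epochs``
    epochs. Records are bucketed by frame count so each mini-batch stacks into
    one array. Returns ``(model, history)`` where ``history`` is the per-epoch
    mean training loss; a NaN loss aborts with diagnostics.
    """
    pairs = [_as_xy(item) for item in dataset]
    if len(pairs) < 1:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = TBLSTM(config, rng)
    loss_fn = nn.SoftmaxCrossEntropy(
        None if config.class_weights is None else np.asarray(config.class_weights)
    )
    opt = nn.Adam(model.params(), lr=config.lr)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(pairs))
        # bucket by length so batches are rectangular
        buckets: dict[int, list[int]] = {}
        for idx in order:
            buckets.setdefault(pairs[idx][0].shape[0], []).append(idx)
        losses, weights = [], []
        for length in sorted(buckets):
            idxs = buckets[length]
            for start in range(0, len(idxs), config.batch_size):
                chunk = idxs[start : start + config.batch_size]
                xb = np.stack([pairs[i][0] for i in chunk])
                yb = np.stack([pairs[i][1] for i in chunk])
                logits = model.forward(xb, train=True, rng=rng)
                loss = loss_fn.forward(logits, yb)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch}: loss={loss}, "
                        f"batch of {len(chunk)} records x {length} frames"
                    )
                opt.zero_grad()
                model.backward(loss_fn.backward())
                opt.step()
                losses.append(loss)
                weights.append(len(chunk))
        epoch_loss = float(np.average(losses, weights=weights))
        history.append(epoch_loss)
        logger.info("epoch %d/%d loss %.4f", epoch + 1, config.epochs, epoch_loss)
    model.trained = True
    return model, history


def predict_states(model: TBLSTM, signal: Signal) -> FramePosterior:
    """Segment a preprocessed signal: envelopes -> TBLSTM -> frame posteriors."""
    if not model.trained:
        raise RuntimeError("model has not been trained (or loaded from a checkpoint)")
    feats = build_feature_matrix(signal, frame_rate=model.config.frame_rate)
    return model.posterior(feats)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: TBLSTM) -> None:
    """Persist weights + config as a .npz archive with an embedded JSON config."""
    path = Path(path)
    cfg = asdict(model.config)
    arrays = {f"p{i}": p.data for i, p in enumerate(model.params())}
    np.savez(path, config=json.dumps(cfg), trained=model.trained, **arrays)


def load_checkpoint(path) -> TBLSTM:
    with np.load(Path(path), allow_pickle=False) as blob:
        cfg_dict = json.loads(str(blob["config"]))
        if cfg_dict.get("class_weights") is not None:
            cfg_dict["class_weights"] = tuple(cfg_dict["class_weights"])
        cfg_dict["dilations"] = tuple(cfg_dict["dilations"])
        config = ModelConfig(**cfg_dict)
        model = build_model(config)
        for i, p in enumerate(model.params()):
            p.data[...] = blob[f"p{i}"]
        model.trained = bool(blob["trained"])
    return model
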