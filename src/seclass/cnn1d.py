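"""From-scratch 1-D convolutional network for expression profiles (SE1DCNN).

Architecture (seven layers): input of m1 selected genes → C1 (k1 valid
cross-correlations of length w1, ReLU) → M1 (non-overlapping max pool of
width p1) → C2 (k2 kernels of length w2 over all k1 channels, ReLU) → M2
(pool p2) → fully-connected layer of m6 ReLU units → output layer of m7 = C
sigmoid units. Layer lengths obey

    m2 = m1 − w1 + 1,  m3 = m2 / p1,  m4 = m3 − w2 + 1,  m5 = m4 / p2,

with p1 | m2 and p2 | m4 enforced at config validation. Training minimizes
the squared-error loss ½ Σ_c (t_c − y_c)² (mean over the batch, one-hot
targets) by the delta rule: the output sensitivity is
δ_out = f′(u) ∘ (y − t), hidden sensitivities propagate as
δ^i = (W^{i+1})ᵀ δ^{i+1} ∘ f′(u^i) with pooling deltas routed to the argmax
position of each window, and every weight steps by −η ∂J/∂W.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .sample_expansion import ExpandedSet

__all__ = [
    "CNNConfig",
    "CNNParams",
    "conv1d_valid",
    "relu",
    "maxpool1d",
    "dimension_chain",
    "init_params",
    "cnn_forward",
    "squared_error_loss",
    "cnn_backward",
    "fit_se1dcnn",
    "predict_se1dcnn",
]


@dataclass
class CNNConfig:
    """Network shape and training hyperparameters.

    k1, k2 — kernel counts of the convolution layers; w1, w2 — kernel
    lengths; p1, p2 — pool widths; m6 — fully-connected width; η, epochs,
    batch_size (None = full batch), seed as usual.
    """

    k1: int = 11
    k2: int = 5
    w1: int = 21
    w2: int = 21
    p1: int = 4
    p2: int = 4
    m6: int = 100
    learning_rate: float = 0.05
    epochs: int = 200
    batch_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "w1", "w2", "p1", "p2", "m6"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate < 0 or self.epochs < 0:
            raise ValueError("learning_rate and epochs must be ≥ 0")

    def validate(self, m1: int) -> tuple[int, int, int, int]:
        """Check the m1→m5 arithmetic; returns (m2, m3, m4, m5)."""
        return dimension_chain(m1, self.w1, self.p1, self.w2, self.p2)


def dimension_chain(m1: int, w1: int, p1: int, w2: int, p2: int) -> tuple[int, int, int, int]:
    """Layer lengths (m2, m3, m4, m5); raises if any stage is invalid."""
    m2 = m1 - w1 + 1
    if m2 < 1:
        raise ValueError(f"kernel w1={w1} longer than input m1={m1}")
    if m2 % p1 != 0:
        raise ValueError(f"pool p1={p1} does not divide m2={m2}")
    m3 = m2 // p1
    m4 = m3 - w2 + 1
    if m4 < 1:
        raise ValueError(f"kernel w2={w2} longer than pooled length m3={m3}")
    if m4 % p2 != 0:
        raise ValueError(f"pool p2={p2} does not divide m4={m4}")
    m5 = m4 // p2
    return m2, m3, m4, m5


def conv1d_valid(signal: np.ndarray, kernel: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """Valid cross-correlation: out_t = Σ_j kernel_j · signal_{t+j} + bias."""
    signal = np.asarray(signal, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.shape[0] > signal.shape[0]:
        raise ValueError("kernel longer than signal")
    windows = sliding_window_view(signal, kernel.shape[0])
    return windows @ kernel + bias


def relu(u: np.ndarray) -> np.ndarray:
    return np.maximum(u, 0.0)


def maxpool1d(signal: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping max pooling; returns (pooled, argmax-in-window).

    The retained argmax (first position on ties) routes gradients back to
    the winning input during backpropagation.
    """
    signal = np.asarray(signal, dtype=float)
    L = signal.shape[-1]
    if L % p != 0:
        raise ValueError(f"pool width {p} does not divide length {L}")
    windows = signal.reshape(*signal.shape[:-1], L // p, p)
    idx = windows.argmax(axis=-1)
    pooled = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
    return pooled, idx


@dataclass
class CNNParams:
    """All trainable tensors; shapes fixed by CNNConfig, m1 and C."""

    K1: np.ndarray      # (k1, w1)
    b1: np.ndarray      # (k1,)
    K2: np.ndarray      # (k2, k1, w2)
    b2: np.ndarray      # (k2,)
    W_fc: np.ndarray    # (m6, k2*m5)
    b_fc: np.ndarray    # (m6,)
    W_out: np.ndarray   # (C, m6)
    b_out: np.ndarray   # (C,)

    def tensors(self) -> dict[str, np.ndarray]:
        return {
            "K1": self.K1, "b1": self.b1, "K2": self.K2, "b2": self.b2,
            "W_fc": self.W_fc, "b_fc": self.b_fc,
            "W_out": self.W_out, "b_out": self.b_out,
        }


def _glorot(shape: tuple[int, ...], fan_in: int, fan_out: int, rng) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


def init_params(cfg: CNNConfig, m1: int, C: int, rng: np.random.Generator) -> CNNParams:
    m2, m3, m4, m5 = cfg.validate(m1)
    return CNNParams(
        K1=_glorot((cfg.k1, cfg.w1), cfg.w1, cfg.k1 * cfg.w1, rng),
        b1=np.zeros(cfg.k1),
        K2=_glorot((cfg.k2, cfg.k1, cfg.w2), cfg.k1 * cfg.w2, cfg.k2 * cfg.w2, rng),
        b2=np.zeros(cfg.k2),
        W_fc=_glorot((cfg.m6, cfg.k2 * m5), cfg.k2 * m5, cfg.m6, rng),
        b_fc=np.zeros(cfg.m6),
        W_out=_glorot((C, cfg.m6), cfg.m6, C, rng),
        b_out=np.zeros(C),
    )


def _sigmoid(u: np.ndarray) -> np.ndarray:
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out


def cnn_forward(params: CNNParams, X: np.ndarray, cfg: CNNConfig) -> tuple[np.ndarray, dict]:
    """Batched forward pass; returns (class scores (N, C), cache).

    The cache keeps pre-activations and pool argmaxes for the backward pass.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N, m1 = X.shape
    m2, m3, m4, m5 = cfg.validate(m1)

    win1 = sliding_window_view(X, cfg.w1, axis=1)            # (N, m2, w1)
    u1 = np.einsum("nmw,kw->nkm", win1, params.K1) + params.b1[None, :, None]
    x1 = relu(u1)                                            # (N, k1, m2)
    pool1, idx1 = maxpool1d(x1, cfg.p1)                      # (N, k1, m3)

    win2 = sliding_window_view(pool1, cfg.w2, axis=2)        # (N, k1, m4, w2)
    u2 = np.einsum("ncmw,kcw->nkm", win2, params.K2) + params.b2[None, :, None]
    x2 = relu(u2)                                            # (N, k2, m4)
    pool2, idx2 = maxpool1d(x2, cfg.p2)                      # (N, k2, m5)

    flat = pool2.reshape(N, -1)                              # (N, k2*m5)
    u_fc = flat @ params.W_fc.T + params.b_fc                # (N, m6)
    x_fc = relu(u_fc)
    u_out = x_fc @ params.W_out.T + params.b_out             # (N, C)
    y = _sigmoid(u_out)

    cache = {
        "X": X, "win1": win1, "u1": u1, "pool1": pool1, "idx1": idx1,
        "win2": win2, "u2": u2, "idx2": idx2, "pool2": pool2,
        "flat": flat, "u_fc": u_fc, "x_fc": x_fc, "u_out": u_out, "y": y,
        "dims": (m2, m3, m4, m5),
    }
    return y, cache


def squared_error_loss(t: np.ndarray, y: np.ndarray) -> float:
    """½ Σ_c (t_c − y_c)² for one sample, or the mean over a batch."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape:
        raise ValueError("target and output shapes differ")
    per = 0.5 * ((t - y) ** 2).sum(axis=-1)
    return float(per) if per.ndim == 0 else float(per.mean())


def _unpool(delta: np.ndarray, idx: np.ndarray, p: int) -> np.ndarray:
    """Route pooled deltas back to the argmax slots (zero elsewhere)."""
    routed = np.zeros(delta.shape + (p,))
    np.put_along_axis(routed, idx[..., None], delta[..., None], axis=-1)
    return routed.reshape(*delta.shape[:-1], delta.shape[-1] * p)


def cnn_backward(
    params: CNNParams, cache: dict, T: np.ndarray, cfg: CNNConfig
) -> dict[str, np.ndarray]:
    """Gradients of the mean squared-error loss for every tensor.

    Output sensitivity δ_out = f′(u_out) ∘ (y − t); hidden sensitivities
    follow the delta rule with ReLU masks and argmax-routed pooling deltas.
    """
    T = np.atleast_2d(np.asarray(T, dtype=float))
    y = cache["y"]
    N = y.shape[0]
    w2 = cfg.w2
    m4 = cache["dims"][2]

    d_uout = ((y - T) / N) * y * (1.0 - y)                   # (N, C)
    g_Wout = d_uout.T @ cache["x_fc"]
    g_bout = d_uout.sum(axis=0)

    d_xfc = d_uout @ params.W_out                            # (N, m6)
    d_ufc = d_xfc * (cache["u_fc"] > 0)
    g_Wfc = d_ufc.T @ cache["flat"]
    g_bfc = d_ufc.sum(axis=0)

    d_flat = d_ufc @ params.W_fc                             # (N, k2*m5)
    d_pool2 = d_flat.reshape(cache["pool2"].shape)           # (N, k2, m5)
    d_x2 = _unpool(d_pool2, cache["idx2"], cfg.p2)           # (N, k2, m4)
    d_u2 = d_x2 * (cache["u2"] > 0)

    g_K2 = np.einsum("nkm,ncmw->kcw", d_u2, cache["win2"])
    g_b2 = d_u2.sum(axis=(0, 2))

    d_pool1 = np.zeros_like(cache["pool1"])                  # (N, k1, m3)
    for w in range(w2):
        d_pool1[:, :, w : w + m4] += np.einsum("nkm,kc->ncm", d_u2, params.K2[:, :, w])

    d_x1 = _unpool(d_pool1, cache["idx1"], cfg.p1)           # (N, k1, m2)
    d_u1 = d_x1 * (cache["u1"] > 0)
    g_K1 = np.einsum("nkm,nmw->kw", d_u1, cache["win1"])
    g_b1 = d_u1.sum(axis=(0, 2))

    return {
        "K1": g_K1, "b1": g_b1, "K2": g_K2, "b2": g_b2,
        "W_fc": g_Wfc, "b_fc": g_bfc, "W_out": g_Wout, "b_out": g_bout,
    }


@dataclass
class CNN1DModel:
    params: CNNParams
    cfg: CNNConfig
    n_classes: int
    m1: int
    loss_history: list[float] = field(default_factory=list)


def fit_se1dcnn(train: ExpandedSet, cfg: CNNConfig, C: int) -> CNN1DModel:
    """Delta-rule gradient descent on the expanded training set.

    Deterministic under cfg.seed; aborts on non-finite loss. With an
    unexpanded training set this is the plain-1DCNN baseline.
    """
    if C < 2:
        raise ValueError("need at least 2 classes")
    X = np.asarray(train.values, dtype=float)
    y = np.asarray(train.labels, dtype=int)
    if X.shape[0] < 1:
        raise ValueError("empty training set")
    if y.min() < 1 or y.max() > C:
        raise ValueError("labels outside 1..C")
    m1 = X.shape[1]
    rng = np.random.default_rng(cfg.seed)
    params = init_params(cfg, m1, C, rng)
    T = np.eye(C)[y - 1]
    eta = cfg.learning_rate
    history: list[float] = []
    n = X.shape[0]
    for epoch in range(cfg.epochs):
        if cfg.batch_size is None or cfg.batch_size >= n:
            batches = [np.arange(n)]
        else:
            order = rng.permutation(n)
            batches = [order[s : s + cfg.batch_size] for s in range(0, n, cfg.batch_size)]
        for batch in batches:
            yb, cache = cnn_forward(params, X[batch], cfg)
            loss = squared_error_loss(T[batch], yb)
            if not np.isfinite(loss):
                raise FloatingPointError(f"loss non-finite at epoch {epoch}")
            grads = cnn_backward(params, cache, T[batch], cfg)
            for name, tensor in params.tensors().items():
                tensor -= eta * grads[name]
        yfull, _ = cnn_forward(params, X, cfg)
        history.append(squared_error_loss(T, yfull))
    return CNN1DModel(params=params, cfg=cfg, n_classes=C, m1=m1, loss_history=history)


def predict_se1dcnn(model: CNN1DModel, X_test: np.ndarray) -> np.ndarray:
    """Predicted labels 1..C (argmax scores; ties → lowest class)."""
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    if X_test.shape[1] != model.m1:
        raise ValueError(
            f"test samples have {X_test.shape[1]} genes, model expects {model.m1}"
        )
    y, _ = cnn_forward(model.params, X_test, model.cfg)
    return y.argmax(axis=1) + 1
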