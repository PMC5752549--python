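"""Stacked autoencoder classifier trained on sample-expanded data (SESAE).

Each autoencoder layer has tied weights: the encoder computes
y = sigmoid(W x + b_y) and the decoder z = sigmoid(Wᵀ y + b_z), so a single
matrix W is shared between both directions (halving the parameters). Layers
are pretrained greedily by full-batch gradient descent on the mean squared
reconstruction error ½‖x − z‖²; layer 2 is trained on layer-1 codes. The
decoders are then discarded, a classifier head is stacked on the top code
and the whole network is fine-tuned by backpropagation from the classifier
loss. The default head is softmax with cross-entropy; a sigmoid head with
squared error is available for symmetry with the convolutional model.

With sample expansion disabled (training on the raw rows only) the same fit
is the plain-SAE baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit as sigmoid

from .sample_expansion import ExpandedSet

__all__ = [
    "AEParams",
    "SAEConfig",
    "SESAEModel",
    "ae_encode",
    "ae_decode",
    "ae_cost_and_grads",
    "train_autoencoder",
    "classifier_cost_and_grads",
    "fit_sesae",
    "predict_sesae",
]


@dataclass
class AEParams:
    """Tied-weight autoencoder parameters: W (hidden × visible), biases b_y
    (hidden) and b_z (visible)."""

    W: np.ndarray
    b_y: np.ndarray
    b_z: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b_y = np.asarray(self.b_y, dtype=float)
        self.b_z = np.asarray(self.b_z, dtype=float)
        h, v = self.W.shape
        if self.b_y.shape != (h,) or self.b_z.shape != (v,):
            raise ValueError("bias shapes inconsistent with W")


@dataclass
class SAEConfig:
    """Hyperparameters of pretraining and fine-tuning.

    hidden_sizes
        Width of each stacked hidden layer, e.g. [50, 50].
    learning_rate
        Step size η for both phases.
    pretrain_epochs / finetune_epochs
        Full passes of gradient descent per phase.
    batch_size
        None = full batch (training sets here are small); else minibatch size.
    head
        "softmax" (cross-entropy) or "squared" (sigmoid outputs, ½‖t−y‖²).
    """

    hidden_sizes: list[int] = field(default_factory=lambda: [50, 50])
    learning_rate: float = 0.1
    pretrain_epochs: int = 100
    finetune_epochs: int = 200
    batch_size: int | None = None
    seed: int = 0
    head: str = "softmax"

    def __post_init__(self) -> None:
        if not self.hidden_sizes or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be ≥ 0")
        if self.pretrain_epochs < 0 or self.finetune_epochs < 0:
            raise ValueError("epoch counts must be ≥ 0")
        if self.head not in ("softmax", "squared"):
            raise ValueError("head must be 'softmax' or 'squared'")


def _init_weight(h: int, v: int, rng: np.random.Generator) -> np.ndarray:
    # sigmoid-layer range: uniform in ±4·sqrt(6/(fan_in+fan_out))
    bound = 4.0 * np.sqrt(6.0 / (h + v))
    return rng.uniform(-bound, bound, size=(h, v))


def ae_encode(p: AEParams, x: np.ndarray) -> np.ndarray:
    """y = sigmoid(W x + b_y); accepts a vector (v,) or batch (N, v)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return sigmoid(p.W @ x + p.b_y)
    return sigmoid(x @ p.W.T + p.b_y)


def ae_decode(p: AEParams, y: np.ndarray) -> np.ndarray:
    """z = sigmoid(Wᵀ y + b_z); accepts a vector (h,) or batch (N, h)."""
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        return sigmoid(p.W.T @ y + p.b_z)
    return sigmoid(y @ p.W + p.b_z)


def ae_cost_and_grads(p: AEParams, X: np.ndarray) -> tuple[float, dict[str, np.ndarray]]:
    """Mean squared reconstruction error over the batch and its gradients.

    cost = (1/N) Σ_n ½‖x_n − z_n‖². W receives contributions from both the
    encoder and the (transposed) decoder path.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N = X.shape[0]
    Y = sigmoid(X @ p.W.T + p.b_y)          # (N, h)
    Z = sigmoid(Y @ p.W + p.b_z)            # (N, v)
    diff = Z - X
    cost = 0.5 * float((diff**2).sum()) / N

    d_uz = (diff / N) * Z * (1.0 - Z)       # (N, v)
    g_bz = d_uz.sum(axis=0)
    gW_dec = Y.T @ d_uz                     # (h, v)
    d_Y = d_uz @ p.W.T                      # (N, h)
    d_uy = d_Y * Y * (1.0 - Y)
    g_by = d_uy.sum(axis=0)
    gW_enc = d_uy.T @ X                     # (h, v)
    return cost, {"W": gW_enc + gW_dec, "b_y": g_by, "b_z": g_bz}


def train_autoencoder(
    X: np.ndarray,
    hidden: int,
    cfg: SAEConfig,
    rng: np.random.Generator | None = None,
) -> tuple[AEParams, list[float]]:
    """Gradient-descent pretraining of one tied-weight autoencoder.

    Returns the fitted parameters and the per-epoch cost history (cost
    measured before each update, plus the final cost). Aborts on NaN loss.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("need at least one sample")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    v = X.shape[1]
    p = AEParams(W=_init_weight(hidden, v, rng), b_y=np.zeros(hidden), b_z=np.zeros(v))
    history: list[float] = []
    eta = cfg.learning_rate
    for epoch in range(cfg.pretrain_epochs):
        for batch in _batches(X.shape[0], cfg.batch_size, rng):
            cost, g = ae_cost_and_grads(p, X[batch])
            if not np.isfinite(cost):
                raise FloatingPointError(
                    f"autoencoder loss became non-finite at epoch {epoch}"
                )
            p.W -= eta * g["W"]
            p.b_y -= eta * g["b_y"]
            p.b_z -= eta * g["b_z"]
        history.append(ae_cost_and_grads(p, X)[0])
    return p, history


def _batches(n: int, batch_size: int | None, rng: np.random.Generator):
    if batch_size is None or batch_size >= n:
        yield np.arange(n)
        return
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


@dataclass
class SESAEModel:
    """Fitted stacked-autoencoder classifier."""

    encoders: list[AEParams]
    W_out: np.ndarray
    b_out: np.ndarray
    n_classes: int
    n_features: int
    head: str = "softmax"
    pretrain_history: list[list[float]] = field(default_factory=list)
    finetune_history: list[float] = field(default_factory=list)


def _forward_codes(encoders: list[AEParams], X: np.ndarray) -> list[np.ndarray]:
    """Activations of every hidden layer; codes[-1] feeds the head."""
    codes = []
    h = X
    for p in encoders:
        h = sigmoid(h @ p.W.T + p.b_y)
        codes.append(h)
    return codes


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def classifier_cost_and_grads(
    encoders: list[AEParams],
    W_out: np.ndarray,
    b_out: np.ndarray,
    X: np.ndarray,
    T: np.ndarray,
    head: str = "softmax",
) -> tuple[float, list[dict[str, np.ndarray]], np.ndarray, np.ndarray]:
    """Classifier loss (mean over batch) and gradients for fine-tuning.

    T is the one-hot target matrix (N, C). Returns
    (cost, per-encoder grads {W, b_y}, grad W_out, grad b_out).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N = X.shape[0]
    codes = _forward_codes(encoders, X)
    top = codes[-1]
    logits = top @ W_out.T + b_out
    if head == "softmax":
        P = _softmax(logits)
        eps = 1e-300
        cost = -float((T * np.log(P + eps)).sum()) / N
        d_logits = (P - T) / N
    elif head == "squared":
        Yh = sigmoid(logits)
        cost = 0.5 * float(((T - Yh) ** 2).sum()) / N
        d_logits = ((Yh - T) / N) * Yh * (1.0 - Yh)
    else:
        raise ValueError(f"unknown head {head!r}")

    g_Wout = d_logits.T @ top
    g_bout = d_logits.sum(axis=0)
    grads: list[dict[str, np.ndarray]] = [None] * len(encoders)  # type: ignore
    d_h = d_logits @ W_out
    for layer in range(len(encoders) - 1, -1, -1):
        h = codes[layer]
        below = X if layer == 0 else codes[layer - 1]
        d_u = d_h * h * (1.0 - h)
        grads[layer] = {"W": d_u.T @ below, "b_y": d_u.sum(axis=0)}
        if layer > 0:
            d_h = d_u @ encoders[layer].W
    return cost, grads, g_Wout, g_bout


def fit_sesae(train: ExpandedSet, cfg: SAEConfig, C: int) -> SESAEModel:
    """Greedy layerwise pretraining, then end-to-end fine-tuning.

    Layer k is pretrained on the codes of layer k−1; the decoders are then
    discarded and a size-C head is fine-tuned jointly with the encoders.
    Deterministic under cfg.seed.
    """
    if C < 2:
        raise ValueError("need at least 2 classes")
    X = np.asarray(train.values, dtype=float)
    if X.shape[0] < 1:
        raise ValueError("empty training set")
    y = np.asarray(train.labels, dtype=int)
    if y.min() < 1 or y.max() > C:
        raise ValueError("labels outside 1..C")
    rng = np.random.default_rng(cfg.seed)

    encoders: list[AEParams] = []
    pretrain_history: list[list[float]] = []
    inputs = X
    for hidden in cfg.hidden_sizes:
        p, hist = train_autoencoder(inputs, hidden, cfg, rng=rng)
        encoders.append(p)
        pretrain_history.append(hist)
        inputs = sigmoid(inputs @ p.W.T + p.b_y)

    top_width = cfg.hidden_sizes[-1]
    W_out = _init_weight(C, top_width, rng) / 4.0  # linear head: plain Glorot range
    b_out = np.zeros(C)
    T = np.eye(C)[y - 1]

    eta = cfg.learning_rate
    finetune_history: list[float] = []
    for epoch in range(cfg.finetune_epochs):
        for batch in _batches(X.shape[0], cfg.batch_size, rng):
            cost, grads, g_Wout, g_bout = classifier_cost_and_grads(
                encoders, W_out, b_out, X[batch], T[batch], cfg.head
            )
            if not np.isfinite(cost):
                raise FloatingPointError(f"classifier loss non-finite at epoch {epoch}")
            for p, g in zip(encoders, grads):
                p.W -= eta * g["W"]
                p.b_y -= eta * g["b_y"]
            W_out -= eta * g_Wout
            b_out -= eta * g_bout
        finetune_history.append(
            classifier_cost_and_grads(encoders, W_out, b_out, X, T, cfg.head)[0]
        )
    return SESAEModel(
        encoders=encoders,
        W_out=W_out,
        b_out=b_out,
        n_classes=C,
        n_features=X.shape[1],
        head=cfg.head,
        pretrain_history=pretrain_history,
        finetune_history=finetune_history,
    )


def predict_sesae(model: SESAEModel, X_test: np.ndarray) -> np.ndarray:
    """Predicted labels 1..C (argmax of the head; ties → lowest class)."""
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    if X_test.shape[1] != model.n_features:
        raise ValueError(
            f"test samples have {X_test.shape[1]} genes, model expects {model.n_features}"
        )
    top = _forward_codes(model.encoders, X_test)[-1]
    logits = top @ model.W_out.T + model.b_out
    return logits.argmax(axis=1) + 1
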