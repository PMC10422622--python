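"""Tied-weight stacked autoencoder with a structural loss for architecture
selection.

Each layer is a single tied autoencoder: ``h = act(x·Wᵀ + b)`` and
``x' = σ(h·W + c)`` with one weight matrix W (hidden × input) shared by
encoder and decoder.  Layers are pretrained greedily on the squared
reconstruction error E = Σ(x − x')², each on the hidden activations of the
one below, with earlier layers frozen.  A softmax head over the top hidden
layer is then attached and the whole network fine-tuned with mini-batch SGD
on the cross-entropy, optionally with inverted dropout on the hidden
activations.

Architecture selection uses the structural loss function

    SLF = ω₁(1 − ρ₁²) + (1 − ω₁)(1 − ρ₂²),    ω₁ = 0.5,

where ρ₁ and ρ₂ are the Pearson and Spearman correlations between the input
matrix and its reconstruction through the full stack.  SLF lies in [0, 1]:
0 for a perfectly (anti)correlated reconstruction, ~1 for an unrelated one.
Among candidate layer layouts the one with minimal SLF wins; ties go to
fewer total neurons, then fewer layers, then candidate order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit
from scipy.stats import spearmanr

SLF_WEIGHT = 0.5  # ω₁: Pearson vs Spearman weight in the structural loss

_SERIAL_VERSION = 1


def sigmoid(z):
    """Logistic function 1/(1+e^(−z)), numerically stable at large |z|."""
    return expit(z)


def _act(z, kind: str):
    if kind == "sigmoid":
        return expit(z)
    if kind == "relu":
        return np.maximum(z, 0.0)
    raise ValueError(f"unknown activation {kind!r}")


def _act_deriv_from_output(h, kind: str):
    if kind == "sigmoid":
        return h * (1.0 - h)
    if kind == "relu":
        return (h > 0).astype(float)
    raise ValueError(f"unknown activation {kind!r}")


@dataclass
class AutoencoderLayer:
    """One tied autoencoder layer: W (m×n), hidden bias b (m), decode bias c (n)."""

    W: np.ndarray
    b: np.ndarray
    c: np.ndarray
    activation: str = "sigmoid"
    training_errors: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        m, n = self.W.shape
        if self.b.shape != (m,) or self.c.shape != (n,):
            raise ValueError("inconsistent layer shapes")

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    @property
    def n_input(self) -> int:
        return self.W.shape[1]


@dataclass
class TrainConfig:
    """Mini-batch SGD settings (defaults: lr 0.01, batch 5, 50 epochs,
    dropout 0.5 during supervised fine-tuning only)."""

    learning_rate: float = 0.01
    epochs: int = 50
    batch_size: int = 5
    dropout: float = 0.5
    seed: int = 0
    hidden_activation: str = "sigmoid"
    finetune_scope: str = "all"  # "all" or "head"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


@dataclass
class SAEStack:
    """Pretrained layers plus an optional softmax head.

    ``feature_min``/``feature_range`` hold the per-feature min–max scaling
    fitted on the training split (sigmoid-range compatibility); they are
    reapplied automatically at prediction time.
    """

    layers: list
    beta: np.ndarray | None = None   # head weights (classes × top hidden)
    alpha: np.ndarray | None = None  # head bias (classes)
    classes: list | None = None
    feature_min: np.ndarray | None = None
    feature_range: np.ndarray | None = None

    def scale(self, X: np.ndarray) -> np.ndarray:
        if self.feature_min is None:
            return X
        return (X - self.feature_min) / self.feature_range


def encode(x: np.ndarray, layer: AutoencoderLayer) -> np.ndarray:
    """h = act(x·Wᵀ + b); accepts a single vector or a (N × n) batch."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != layer.n_input:
        raise ValueError(f"input width {x.shape[-1]} != layer input {layer.n_input}")
    return _act(x @ layer.W.T + layer.b, layer.activation)


def decode(h: np.ndarray, layer: AutoencoderLayer) -> np.ndarray:
    """x' = σ(h·W + c) — tied weights, sigmoid output in (0, 1)."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != layer.n_hidden:
        raise ValueError(f"hidden width {h.shape[-1]} != layer hidden {layer.n_hidden}")
    return expit(h @ layer.W + layer.c)


def reconstruction_error(X: np.ndarray, X_prime: np.ndarray) -> float:
    """Squared-error cost: sum over samples and components of (x − x')²."""
    X = np.asarray(X, dtype=float)
    X_prime = np.asarray(X_prime, dtype=float)
    if X.shape != X_prime.shape:
        raise ValueError("shape mismatch")
    return float(np.sum((X - X_prime) ** 2))


def ae_gradients(layer: AutoencoderLayer, X: np.ndarray):
    """Analytic gradients of the squared-error cost through the tied layer.

    Returns (loss, dW, db, dc).  The W gradient carries both the encoder
    and decoder contributions since the weights are shared.
    """
    X = np.asarray(X, dtype=float)
    H = encode(X, layer)
    Xp = decode(H, layer)
    loss = reconstruction_error(X, Xp)
    dXp = 2.0 * (Xp - X)
    dA2 = dXp * Xp * (1.0 - Xp)          # decoder pre-activation (sigmoid)
    dc = dA2.sum(axis=0)
    dW_dec = H.T @ dA2                    # (m × n)
    dH = dA2 @ layer.W.T
    dA1 = dH * _act_deriv_from_output(H, layer.activation)
    db = dA1.sum(axis=0)
    dW_enc = dA1.T @ X
    return loss, dW_enc + dW_dec, db, dc


def _init_layer(n_in: int, n_hidden: int, rng, activation: str) -> AutoencoderLayer:
    scale = np.sqrt(6.0 / (n_in + n_hidden))  # Glorot uniform
    W = rng.uniform(-scale, scale, size=(n_hidden, n_in))
    return AutoencoderLayer(W=W, b=np.zeros(n_hidden), c=np.zeros(n_in),
                            activation=activation)


def train_autoencoder(X: np.ndarray, hidden_size: int, config: TrainConfig,
                      rng=None) -> AutoencoderLayer:
    """Mini-batch SGD on the squared reconstruction error.

    Inputs are expected in [0, 1] (the sigmoid decoder range).  The per-epoch
    mean reconstruction error is recorded in ``layer.training_errors``.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite inputs")
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be a non-empty 2-D array")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    layer = _init_layer(X.shape[1], hidden_size, rng, config.hidden_activation)
    n = X.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = X[order[start: start + config.batch_size]]
            loss, dW, db, dc = ae_gradients(layer, batch)
            epoch_loss += loss
            layer.W -= config.learning_rate * dW
            layer.b -= config.learning_rate * db
            layer.c -= config.learning_rate * dc
        layer.training_errors.append(epoch_loss / n)
    return layer


def pretrain_stack(X: np.ndarray, hidden_sizes: list[int], config: TrainConfig,
                   rng=None) -> SAEStack:
    """Greedy layer-wise pretraining: layer i trains on the (frozen) hidden
    activations of layer i−1; layer 1 trains on X."""
    if not hidden_sizes:
        raise ValueError("hidden_sizes must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    layers = []
    H = np.asarray(X, dtype=float)
    for size in hidden_sizes:
        layer = train_autoencoder(H, size, config, rng=rng)
        layers.append(layer)
        H = encode(H, layer)
    return SAEStack(layers=layers)


def deep_representation(x: np.ndarray, stack: SAEStack) -> np.ndarray:
    """Chain of encodes through every layer; the identity for an empty stack."""
    h = np.asarray(x, dtype=float)
    for layer in stack.layers:
        h = encode(h, layer)
    return h


def reconstruct(X: np.ndarray, stack: SAEStack) -> np.ndarray:
    """Encode through all layers, then decode back down in reverse order."""
    h = deep_representation(X, stack)
    for layer in reversed(stack.layers):
        h = decode(h, layer)
    return h


def slf(Dx: np.ndarray, Dz: np.ndarray, weight: float = SLF_WEIGHT) -> float:
    """Structural loss ω₁(1 − ρ₁²) + (1 − ω₁)(1 − ρ₂²) between two matrices.

    ρ₁ is the Pearson and ρ₂ the Spearman correlation of the flattened
    entries (ties get average ranks).  A constant Dz makes both
    correlations undefined; they are treated as 0, giving SLF = 1.
    """
    Dx = np.asarray(Dx, dtype=float).ravel()
    Dz = np.asarray(Dz, dtype=float).ravel()
    if Dx.shape != Dz.shape:
        raise ValueError("shape mismatch")
    if Dx.size < 3:
        raise ValueError("need at least 3 entries")
    if np.ptp(Dx) == 0:
        raise ValueError("constant input matrix Dx")
    if np.ptp(Dz) == 0:
        rho1 = rho2 = 0.0
    else:
        rho1 = float(np.corrcoef(Dx, Dz)[0, 1])
        rho2 = float(spearmanr(Dx, Dz).statistic)
    return weight * (1.0 - rho1 ** 2) + (1.0 - weight) * (1.0 - rho2 ** 2)


def select_architecture(
    X: np.ndarray,
    candidate_size_lists: list[list[int]],
    config: TrainConfig,
    tie_tol: float = 1e-9,
) -> list[int]:
    """Pick the hidden-layer layout whose full-stack reconstruction has the
    lowest structural loss against X.

    X is min–max scaled per feature before pretraining (the same scaling the
    classifier applies).  Ties within ``tie_tol`` prefer fewer total
    neurons, then fewer layers, then earlier candidates.
    """
    if not candidate_size_lists:
        raise ValueError("candidate list must be non-empty")
    Xs = _minmax_scale(np.asarray(X, dtype=float))[0]
    scored = []
    for pos, sizes in enumerate(candidate_size_lists):
        stack = pretrain_stack(Xs, list(sizes), config)
        value = slf(Xs, reconstruct(Xs, stack))
        scored.append((value, sum(sizes), len(sizes), pos, list(sizes)))
    best_value = min(s[0] for s in scored)
    contenders = [s for s in scored if s[0] <= best_value + tie_tol]
    contenders.sort(key=lambda s: (s[1], s[2], s[3]))
    return contenders[0][4]


# ---------------------------------------------------------------------------
# supervised head

def _minmax_scale(X: np.ndarray, lo: np.ndarray | None = None,
                  rng_: np.ndarray | None = None):
    if lo is None:
        lo = X.min(axis=0)
        rng_ = X.max(axis=0) - lo
        rng_ = np.where(rng_ > 0, rng_, 1.0)
    return (X - lo) / rng_, lo, rng_


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_hidden(X: np.ndarray, stack: SAEStack, dropout: float, rng):
    """Encode through all layers; with dropout > 0, apply inverted dropout
    masks to every hidden activation (training only)."""
    hs, masks = [], []
    h = X
    for layer in stack.layers:
        h = encode(h, layer)
        if dropout > 0 and rng is not None:
            mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
            h = h * mask
            masks.append(mask)
        else:
            masks.append(None)
        hs.append(h)
    return hs, masks


def supervised_loss_and_gradients(stack: SAEStack, X: np.ndarray, y_idx: np.ndarray,
                                  dropout: float = 0.0, rng=None,
                                  scope: str = "all"):
    """Mean cross-entropy of the softmax head and its analytic gradients.

    Returns (loss, dbeta, dalpha, layer_grads) where layer_grads is a list
    of (dW, db) per layer (empty biases untouched — the decode biases c do
    not enter the supervised path).  ``scope="head"`` freezes the layers.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    hs, masks = _forward_hidden(X, stack, dropout, rng)
    top = hs[-1] if hs else X
    logits = top @ stack.beta.T + stack.alpha
    P = _softmax(logits)
    loss = float(-np.mean(np.log(P[np.arange(n), y_idx] + 1e-300)))

    Y = np.zeros_like(P)
    Y[np.arange(n), y_idx] = 1.0
    dlogits = (P - Y) / n
    dbeta = dlogits.T @ top
    dalpha = dlogits.sum(axis=0)
    layer_grads = []
    if scope == "all":
        dH = dlogits @ stack.beta
        for i in range(len(stack.layers) - 1, -1, -1):
            layer = stack.layers[i]
            if masks[i] is not None:
                dH = dH * masks[i]
            # the activation derivative needs the pre-dropout output
            below = hs[i - 1] if i > 0 else X
            raw = encode(below, layer)
            dA = dH * _act_deriv_from_output(raw, layer.activation)
            dW = dA.T @ below
            db = dA.sum(axis=0)
            layer_grads.append((dW, db))
            dH = dA @ layer.W
        layer_grads.reverse()
    return loss, dbeta, dalpha, layer_grads


def fit_classifier(
    X: np.ndarray,
    y,
    hidden_sizes: list[int],
    config: TrainConfig,
    classes: list | None = None,
) -> SAEStack:
    """Greedy pretraining followed by supervised fine-tuning.

    Features are min–max scaled to [0, 1] per column over the training set
    (stored on the stack and reused at prediction).  Fine-tuning runs
    mini-batch SGD on the softmax cross-entropy with inverted dropout on
    the hidden activations; ``config.finetune_scope`` chooses whether the
    pretrained layers are updated ("all", default) or frozen ("head").
    Per-epoch training cross-entropy lands in ``stack.finetune_losses``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if classes is None:
        classes = sorted(set(y.tolist()))
    class_to_idx = {c: i for i, c in enumerate(classes)}
    try:
        y_idx = np.array([class_to_idx[v] for v in y.tolist()])
    except KeyError as e:
        raise ValueError(f"label {e.args[0]!r} outside the class set {classes}") from e

    rng = np.random.default_rng(config.seed)
    Xs, lo, rng_scale = _minmax_scale(X)
    stack = pretrain_stack(Xs, hidden_sizes, config, rng=rng)
    stack.feature_min, stack.feature_range = lo, rng_scale
    stack.classes = list(classes)

    top_size = hidden_sizes[-1]
    scale = np.sqrt(6.0 / (top_size + len(classes)))
    stack.beta = rng.uniform(-scale, scale, size=(len(classes), top_size))
    stack.alpha = np.zeros(len(classes))

    n = Xs.shape[0]
    losses = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start: start + config.batch_size]
            loss, dbeta, dalpha, layer_grads = supervised_loss_and_gradients(
                stack, Xs[idx], y_idx[idx], dropout=config.dropout, rng=rng,
                scope=config.finetune_scope,
            )
            epoch_loss += loss
            n_batches += 1
            stack.beta -= config.learning_rate * dbeta
            stack.alpha -= config.learning_rate * dalpha
            for layer, (dW, db) in zip(stack.layers, layer_grads):
                layer.W -= config.learning_rate * dW
                layer.b -= config.learning_rate * db
        losses.append(epoch_loss / n_batches)
    stack.finetune_losses = losses
    return stack


def predict_proba(stack: SAEStack, X: np.ndarray) -> np.ndarray:
    """Softmax class probabilities; rows sum to 1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != stack.layers[0].n_input:
        raise ValueError("feature width does not match the stack")
    h = deep_representation(stack.scale(X), stack)
    return _softmax(h @ stack.beta.T + stack.alpha)


def predict(stack: SAEStack, X: np.ndarray) -> np.ndarray:
    """Argmax of the head softmax; ties resolve to the lowest class index."""
    proba = predict_proba(stack, X)
    idx = proba.argmax(axis=1)
    return np.array([stack.classes[i] for i in idx])


# ---------------------------------------------------------------------------
# serialization (JSON, versioned)

def save_stack(stack: SAEStack, path: str | Path) -> None:
    payload = {
        "format_version": _SERIAL_VERSION,
        "layers": [
            {"W": l.W.tolist(), "b": l.b.tolist(), "c": l.c.tolist(),
             "activation": l.activation}
            for l in stack.layers
        ],
        "beta": None if stack.beta is None else stack.beta.tolist(),
        "alpha": None if stack.alpha is None else stack.alpha.tolist(),
        "classes": stack.classes,
        "feature_min": None if stack.feature_min is None else stack.feature_min.tolist(),
        "feature_range": None if stack.feature_range is None else stack.feature_range.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_stack(path: str | Path) -> SAEStack:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _SERIAL_VERSION:
        raise ValueError("unsupported model archive version")
    layers = [
        AutoencoderLayer(W=np.array(l["W"]), b=np.array(l["b"]), c=np.array(l["c"]),
                         activation=l.get("activation", "sigmoid"))
        for l in payload["layers"]
    ]
    def arr(key):
        v = payload.get(key)
        return None if v is None else np.array(v)
    return SAEStack(layers=layers, beta=arr("beta"), alpha=arr("alpha"),
                    classes=payload.get("classes"),
                    feature_min=arr("feature_min"), feature_range=arr("feature_range"))
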