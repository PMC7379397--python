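"""Per-item 4-class deep network.

Each scale item is imputed by its own fully-connected network: one input
layer (the 12 attention indices plus every previously merged item), 15
hidden ReLU layers in three width bands — five layers at twice the input
width, five at the input width, five at half of it — and a 4-unit softmax
output, one unit per Likert score.  Dropout follows every hidden layer;
training uses cross-entropy with the Adam update rule and stops early when
held-out loss fails to improve for ``patience_epochs`` consecutive epochs.

Three batch regimes are supported: full-batch gradient descent, mini-batch
with batch size 8, and stochastic (batch size 1) — the regimes whose time /
accuracy trade-off the imputation framework sweeps over.

The implementation is plain numpy: the networks here are small (at most a
few hundred units per layer) and CPU-bound matmuls dominate, so a
framework adds nothing but a dependency.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split

__all__ = [
    "BatchMode",
    "HyperParams",
    "NetworkSpec",
    "TrainedItemModel",
    "build_network_spec",
    "train_item_model",
    "predict_item",
]

N_CLASSES = 4


class BatchMode(str, enum.Enum):
    FULL_BATCH = "full"
    MINI_BATCH_8 = "mini8"
    STOCHASTIC = "stochastic"


_BATCH_SIZES = {BatchMode.FULL_BATCH: None, BatchMode.MINI_BATCH_8: 8, BatchMode.STOCHASTIC: 1}


@dataclass
class HyperParams:
    """Training hyper-parameters for one item network.

    ``patience_epochs`` may be ``math.inf`` to disable early stopping (the
    run then always lasts ``max_epochs``).  Defaults follow the framework's
    middle sweep point: patience 10, dropout 25%, full batch.
    """

    patience_epochs: float = 10
    dropout_rate: float = 0.25
    batch_mode: BatchMode = BatchMode.FULL_BATCH
    max_epochs: int = 1000
    validation_fraction: float = 0.2
    learning_rate: float = 1e-3
    n_init_attempts: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not (self.patience_epochs >= 1):
            raise ValueError("patience_epochs must be >= 1")
        if self.n_init_attempts < 1:
            raise ValueError("n_init_attempts must be >= 1")
        if math.isfinite(self.patience_epochs) and self.max_epochs < self.patience_epochs:
            raise ValueError("max_epochs must be >= patience_epochs")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture: 15 hidden layers in the 2n / n / n//2 width pattern."""

    n_inputs: int
    hidden_widths: tuple[int, ...]
    n_outputs: int
    dropout_rate: float


def build_network_spec(n_inputs: int, dropout_rate: float = 0.25) -> NetworkSpec:
    """Widths are [2n]*5 + [n]*5 + [n//2]*5 (floor; clamped at 1)."""
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    n = n_inputs
    widths = (2 * n,) * 5 + (n,) * 5 + (max(n // 2, 1),) * 5
    return NetworkSpec(n_inputs=n, hidden_widths=widths, n_outputs=N_CLASSES, dropout_rate=dropout_rate)


@dataclass
class TrainedItemModel:
    """A trained item network plus its held-out imputation accuracy.

    ``validation_accuracy`` is computed on rows never used for weight
    updates; it is the quantity the greedy loop maximizes.  When the item
    is constant in the training data the model degenerates to that
    constant (``constant_class`` set, no weights).
    """

    spec: NetworkSpec
    weights: list = field(default_factory=list, repr=False)
    biases: list = field(default_factory=list, repr=False)
    scaler_mean: np.ndarray | None = None
    scaler_std: np.ndarray | None = None
    scale_cols: np.ndarray | None = None
    validation_accuracy: float = 0.0
    epochs_run: int = 0
    constant_class: int | None = None


# ---------------------------------------------------------------------------
# forward / backward


def _forward(weights, biases, x, dropout_rate=0.0, rng=None):
    """Returns (activations list, logits). Dropout only when rng given."""
    a = x
    acts = [a]
    for W, b in zip(weights[:-1], biases[:-1]):
        a = np.maximum(a @ W + b, 0.0)
        if rng is not None and dropout_rate > 0.0:
            keep = rng.random(a.shape) >= dropout_rate
            a = a * keep / (1.0 - dropout_rate)  # inverted dropout
        acts.append(a)
    logits = a @ weights[-1] + biases[-1]
    return acts, logits


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _cross_entropy(probs, y):
    return float(-np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)).mean())


def _backward(weights, acts, probs, y):
    """Gradients of mean cross-entropy wrt weights and biases."""
    gW = [np.empty_like(w) for w in weights]
    gb = [np.empty(w.shape[1]) for w in weights]
    _backward_into(weights, acts, probs, y, gW, gb)
    return gW, gb


def _backward_into(weights, acts, probs, y, gW, gb):
    """Backprop writing gradients into preallocated per-layer buffers."""
    n = len(y)
    delta = probs.copy()
    delta[np.arange(n), y] -= 1.0
    delta /= n
    for layer in range(len(weights) - 1, -1, -1):
        np.matmul(acts[layer].T, delta, out=gW[layer])
        gb[layer][:] = delta.sum(axis=0)
        if layer > 0:
            delta = (delta @ weights[layer].T) * (acts[layer] > 0)


def train_item_model(
    features: np.ndarray,
    targets: np.ndarray,
    hyperparams: HyperParams,
    scale_cols: Sequence[bool] | None = None,
) -> TrainedItemModel:
    """Train one item network and return it with its held-out accuracy.

    ``features`` must be complete (no NaN) with >= 8 rows.  Rows are split
    into train/validation by ``validation_fraction`` (stratified by target
    whenever every observed class has at least two rows); weights are
    updated per ``batch_mode``; training halts when validation loss has not
    improved for ``patience_epochs`` epochs, and the best-loss weights are
    restored.  ``scale_cols`` flags columns to standardize (statistics fit
    on the training rows only) — used for the continuous attention indices,
    while merged 0–3 item columns are fed raw.  Deterministic given
    ``hyperparams.seed``.
    """
    hyperparams.validate()
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets)
    if X.ndim != 2:
        raise ValueError("features must be 2-D")
    if np.isnan(X).any():
        raise ValueError("features contain missing entries")
    if len(X) != len(y):
        raise ValueError("features and targets disagree in length")
    if len(X) < 8:
        raise ValueError(f"insufficient data: {len(X)} rows (< 8)")
    y = y.astype(int)
    if not np.isin(y, np.arange(N_CLASSES)).all():
        raise ValueError("targets must be in {0,1,2,3}")

    spec = build_network_spec(X.shape[1], hyperparams.dropout_rate)
    col_mask = (
        np.zeros(X.shape[1], dtype=bool)
        if scale_cols is None
        else np.asarray(scale_cols, dtype=bool)
    )

    classes, counts = np.unique(y, return_counts=True)
    if len(classes) == 1:
        # constant item: nothing to learn, held-out accuracy is trivially 1
        return TrainedItemModel(
            spec=spec, scale_cols=col_mask, validation_accuracy=1.0,
            epochs_run=0, constant_class=int(classes[0]),
        )

    ss = np.random.SeedSequence(hyperparams.seed)
    split_seed = int(ss.generate_state(1)[0] >> 1)
    stratify = y if counts.min() >= 2 else None
    idx_train, idx_val = train_test_split(
        np.arange(len(y)),
        test_size=hyperparams.validation_fraction,
        random_state=split_seed % (2**32),
        stratify=stratify,
    )
    Xtr, ytr = X[idx_train], y[idx_train]
    Xva, yva = X[idx_val], y[idx_val]

    # standardize flagged columns on training statistics only
    mean = np.zeros(X.shape[1])
    std = np.ones(X.shape[1])
    if col_mask.any():
        mean[col_mask] = Xtr[:, col_mask].mean(axis=0)
        std[col_mask] = Xtr[:, col_mask].std(axis=0)
        std[std == 0] = 1.0
    Xtr = (Xtr - mean) / std
    Xva = (Xva - mean) / std

    # A 15-deep plain ReLU stack is sensitive to its initialization: some
    # draws land in poor optima (a dead bottleneck layer, or a collapsed
    # class boundary).  Training therefore collects ``n_init_attempts``
    # fits whose validation loss actually moved off its untrained value,
    # allowing up to two extra runs to replace stuck ones, and keeps the
    # best validation loss.  (For an unpredictable item a stuck run and a
    # converged run are near-indistinguishable and equally good, so the
    # retry cap merely bounds wasted work.)
    attempts = []
    n_live = 0
    attempt = 0
    max_attempts = hyperparams.n_init_attempts + 2
    while n_live < hyperparams.n_init_attempts and attempt < max_attempts:
        attempt_seed = np.random.SeedSequence([hyperparams.seed, attempt])
        outcome = _train_once(spec, Xtr, ytr, Xva, yva, hyperparams, attempt_seed)
        attempts.append(outcome)
        attempt += 1
        if outcome.first_loss - outcome.best_loss > 0.01 * outcome.first_loss:
            n_live += 1
    best = min(attempts, key=lambda o: o.best_loss)

    _, val_logits = _forward(best.weights, best.biases, Xva)
    val_acc = float((val_logits.argmax(axis=1) == yva).mean())

    return TrainedItemModel(
        spec=spec,
        weights=best.weights,
        biases=best.biases,
        scaler_mean=mean,
        scaler_std=std,
        scale_cols=col_mask,
        validation_accuracy=val_acc,
        epochs_run=best.epochs_run,
    )


@dataclass
class _TrainOutcome:
    weights: list
    biases: list
    best_loss: float
    first_loss: float
    epochs_run: int


def _flat_params(widths: list[int]) -> tuple[np.ndarray, list, list]:
    """One contiguous parameter buffer with per-layer weight/bias views.

    Keeping every parameter in a single array lets the Adam update run as
    a handful of whole-buffer vector operations instead of one Python loop
    over 32 small arrays per gradient step.
    """
    sizes = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        sizes.append(fan_in * fan_out)
        sizes.append(fan_out)
    theta = np.zeros(int(np.sum(sizes)))
    weights, biases, off = [], [], 0
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        weights.append(theta[off : off + fan_in * fan_out].reshape(fan_in, fan_out))
        off += fan_in * fan_out
        biases.append(theta[off : off + fan_out])
        off += fan_out
    return theta, weights, biases


def _train_once(spec, Xtr, ytr, Xva, yva, hyperparams: HyperParams, seed_seq) -> _TrainOutcome:
    """One full training run: Adam + dropout + patience, best weights kept."""
    init_seed, shuffle_seed = [int(s) for s in seed_seq.generate_state(2) >> 1]
    rng = np.random.default_rng(init_seed)
    widths = [spec.n_inputs, *spec.hidden_widths, spec.n_outputs]
    theta, weights, biases = _flat_params(widths)
    grad, gW, gb = _flat_params(widths)
    # Glorot-uniform init: with 15 ReLU layers and dropout noise, the larger
    # He gain tends to drive the narrow tail layers into permanent ReLU
    # death; the conservative Glorot scale keeps them trainable.
    for W in weights:
        fan_in, fan_out = W.shape
        W[:] = rng.uniform(-1.0, 1.0, W.shape) * np.sqrt(6.0 / (fan_in + fan_out))

    lr, b1, b2, eps = hyperparams.learning_rate, 0.9, 0.999, 1e-8
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    t = 0

    batch_size = _BATCH_SIZES[hyperparams.batch_mode] or len(Xtr)
    shuffle_rng = np.random.default_rng(shuffle_seed)
    _, init_logits = _forward(weights, biases, Xva)
    first_loss = _cross_entropy(_softmax(init_logits), yva)  # untrained baseline
    best_loss = np.inf
    best_theta = None
    stall = 0
    epochs_run = 0

    for epoch in range(hyperparams.max_epochs):
        epochs_run = epoch + 1
        order = (
            shuffle_rng.permutation(len(Xtr))
            if batch_size < len(Xtr)
            else np.arange(len(Xtr))
        )
        for start in range(0, len(order), batch_size):
            sel = order[start : start + batch_size]
            acts, logits = _forward(weights, biases, Xtr[sel], spec.dropout_rate, rng)
            probs = _softmax(logits)
            _backward_into(weights, acts, probs, ytr[sel], gW, gb)
            t += 1
            m *= b1
            m += (1 - b1) * grad
            v *= b2
            v += (1 - b2) * np.square(grad)
            step = (lr / (1 - b1**t)) * m / (np.sqrt(v / (1 - b2**t)) + eps)
            theta -= step

        _, val_logits = _forward(weights, biases, Xva)
        val_loss = _cross_entropy(_softmax(val_logits), yva)
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_theta = theta.copy()
            stall = 0
        else:
            stall += 1
            if stall >= hyperparams.patience_epochs:
                break

    if best_theta is not None:
        theta[:] = best_theta
    return _TrainOutcome(
        [w.copy() for w in weights], [b.copy() for b in biases],
        best_loss, first_loss, epochs_run,
    )


def predict_item(model: TrainedItemModel, features: np.ndarray) -> np.ndarray:
    """Predict Likert scores: argmax softmax class, ties toward lower score."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.spec.n_inputs:
        raise ValueError(
            f"feature matrix must have {model.spec.n_inputs} columns, got {X.shape}"
        )
    if np.isnan(X).any():
        raise ValueError("features contain missing entries")
    if model.constant_class is not None:
        return np.full(len(X), model.constant_class, dtype=int)
    X = (X - model.scaler_mean) / model.scaler_std
    _, logits = _forward(model.weights, model.biases, X)
    # np.argmax returns the first maximum, i.e. the lower score on ties
    return logits.argmax(axis=1).astype(int)
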