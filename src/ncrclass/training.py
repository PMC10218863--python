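"""Training protocol: Adam, batched cross-entropy, early stopping, ten-fold CV.

The protocol matches the published recipe: Adam at learning rate 0.001,
batch size 100, categorical cross-entropy (optionally weighted per class),
early stopping after five consecutive epochs without a new strict minimum of
the validation loss, and best-checkpoint restoration — the returned model is
the one with the overall lowest validation loss, not the last epoch's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from . import nn
from .models import ModelSpec, realize

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "EarlyStopping",
    "compute_class_weights",
    "train",
    "ten_fold_cv",
    "median_validation_curve",
]


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.001
    batch_size: int = 100
    patience: int = 5
    max_epochs: int = 500
    seed: int = 0
    class_weights: dict | None = None

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch losses/accuracy; ``best_epoch`` is 1-based."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = 0

    def __len__(self) -> int:
        return len(self.val_loss)


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without a strict new minimum.

    Ties do not count as improvement.  ``update`` returns True when training
    should stop after the epoch just reported.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.epochs_seen = 0
        self.stale = 0

    def update(self, val_loss: float) -> bool:
        self.epochs_seen += 1
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = self.epochs_seen
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


def compute_class_weights(labels) -> dict:
    """Inverse-frequency weights normalized to mean 1: w_c = N / (K * n_c)."""
    labels = list(labels)
    if not labels:
        raise ValueError("no labels given")
    classes, counts = np.unique(labels, return_counts=True)
    n, k = len(labels), len(classes)
    return {c: n / (k * cnt) for c, cnt in zip(classes, counts)}


def _take(X, idx):
    if isinstance(X, tuple):
        return tuple(_take(part, idx) for part in X)
    return X[idx]


def _n_samples(X) -> int:
    return X[0].shape[0] if isinstance(X, tuple) else X.shape[0]


def _check_onehot(y: np.ndarray, n_classes: int, what: str) -> None:
    if y.ndim != 2 or y.shape[1] != n_classes:
        raise ValueError(f"{what} labels must be one-hot with {n_classes} columns")
    rows = y.sum(axis=1)
    if not np.allclose(rows, 1.0):
        raise ValueError(f"{what} labels contain a row outside the class set")


def train(
    model_spec: ModelSpec,
    train_set: tuple,
    val_set: tuple,
    config: TrainingConfig | None = None,
) -> tuple[object, TrainingHistory]:
    """Train a realized model; return the best-checkpoint network and history.

    ``train_set``/``val_set`` are ``(X, y)`` with one-hot ``y``; for the
    merged model ``X`` is a ``(sequence_batch, graph_matrix)`` tuple.
    ``config.class_weights`` maps class *index* (or label equal to the index)
    to a positive weight applied to the training loss only.
    """
    config = config or TrainingConfig()
    X_tr, y_tr = train_set
    X_va, y_va = val_set
    n_tr, n_va = _n_samples(X_tr), _n_samples(X_va)
    if n_tr == 0 or n_va == 0:
        raise ValueError("empty train or validation set")
    _check_onehot(np.asarray(y_tr), model_spec.n_classes, "train")
    _check_onehot(np.asarray(y_va), model_spec.n_classes, "validation")

    rng = np.random.default_rng(config.seed)
    net = realize(model_spec, rng)
    adam = nn.Adam(net.params, lr=config.learning_rate)

    if config.class_weights is not None:
        wvec = np.ones(model_spec.n_classes)
        for cls, w in config.class_weights.items():
            wvec[int(cls)] = w
        sample_w_all = np.asarray(y_tr) @ wvec
    else:
        sample_w_all = None

    stopper = EarlyStopping(config.patience)
    history = TrainingHistory()
    best_weights = net.get_weights()

    for _epoch in range(config.max_epochs):
        perm = rng.permutation(n_tr)
        batch_losses = []
        for start in range(0, n_tr, config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb = _take(X_tr, idx)
            yb = np.asarray(y_tr)[idx]
            wb = None if sample_w_all is None else sample_w_all[idx]
            logits = net.forward(xb, train=True, rng=rng)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb, wb)
            net.backward(dlogits)
            adam.step(net.grads)
            batch_losses.append(loss)
        history.train_loss.append(float(np.mean(batch_losses)))

        proba = net.predict_proba(X_va)
        val_loss = float(
            -np.mean(np.log(np.sum(proba * np.asarray(y_va), axis=1) + 1e-12))
        )
        val_acc = float(
            np.mean(proba.argmax(axis=1) == np.asarray(y_va).argmax(axis=1))
        )
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)

        improved = val_loss < stopper.best
        stop = stopper.update(val_loss)
        if improved:
            best_weights = net.get_weights()
        if stop:
            break

    history.best_epoch = stopper.best_epoch
    net.set_weights(best_weights)
    return net, history


def stratified_folds(
    labels: np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Deterministic class-balanced folds (per-class counts differ by <= 1)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    start = 0
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if len(idx) < n_folds:
            raise ValueError(
                f"class {cls!r} has {len(idx)} samples, fewer than {n_folds} folds"
            )
        idx = rng.permutation(idx)
        # rotate the starting fold per class so remainders spread evenly
        for i, sample in enumerate(idx):
            folds[(start + i) % n_folds].append(int(sample))
        start += len(idx)
    return [np.sort(np.asarray(f)) for f in folds]


def median_validation_curve(histories: list[TrainingHistory]) -> np.ndarray:
    """Per-epoch median validation loss across folds.

    Folds that stopped early carry their last validation loss forward so the
    median stays defined at every epoch up to the longest history.
    """
    longest = max(len(h) for h in histories)
    padded = np.empty((len(histories), longest))
    for i, h in enumerate(histories):
        vals = np.asarray(h.val_loss)
        padded[i, : len(vals)] = vals
        padded[i, len(vals) :] = vals[-1]
    return np.median(padded, axis=0)


def ten_fold_cv(
    dataset: tuple,
    model_builder,
    config: TrainingConfig | None = None,
    n_folds: int = 10,
) -> tuple[list[TrainingHistory], np.ndarray, list[np.ndarray]]:
    """Ten-fold cross-validation on class-balanced folds.

    ``dataset`` is ``(X, y)`` with one-hot ``y``; ``model_builder()`` returns
    a fresh :class:`ModelSpec` per fold.  Returns the per-fold histories, the
    per-epoch median validation-loss curve, and the fold index arrays.
    """
    config = config or TrainingConfig()
    X, y = dataset
    labels = np.asarray(y).argmax(axis=1)
    folds = stratified_folds(labels, n_folds, config.seed)
    histories = []
    for k, val_idx in enumerate(folds):
        train_idx = np.sort(
            np.concatenate([f for i, f in enumerate(folds) if i != k])
        )
        fold_cfg = TrainingConfig(
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            patience=config.patience,
            max_epochs=config.max_epochs,
            seed=config.seed + k,
            class_weights=config.class_weights,
        )
        _, hist = train(
            model_builder(),
            (_take(X, train_idx), np.asarray(y)[train_idx]),
            (_take(X, val_idx), np.asarray(y)[val_idx]),
            fold_cfg,
        )
        histories.append(hist)
    return histories, median_validation_curve(histories), folds


def one_hot(labels, classes: list) -> np.ndarray:
    """One-hot encode labels against a frozen class order."""
    index = {c: i for i, c in enumerate(classes)}
    y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        if lab not in index:
            raise ValueError(f"label {lab!r} outside the class set")
        y[i, index[lab]] = 1.0
    return y


def stack_inputs(encoded: list, channel: str):
    """Stack per-record encodings into one model input."""
    if channel == "graph":
        return sparse.vstack([e.to_sparse() for e in encoded]).tocsr()
    return np.stack([e.values for e in encoded])
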