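"""Early stopping, checkpoint-best, class weights and cross-validation."""

import numpy as np
import pytest

from ncrclass.models import build_grenc
from ncrclass.training import (
    EarlyStopping,
    TrainingConfig,
    TrainingHistory,
    compute_class_weights,
    median_validation_curve,
    one_hot,
    stratified_folds,
    ten_fold_cv,
    train,
)


def run_stopper(losses, patience):
    stopper = EarlyStopping(patience)
    for epoch, loss in enumerate(losses, start=1):
        if stopper.update(loss):
            return epoch, stopper.best_epoch
    return len(losses), stopper.best_epoch


def test_early_stopping_hand_trace():
    """Minimum at epoch 2, five stale epochs -> stop after epoch 7."""
    losses = [0.5, 0.4, 0.41, 0.42, 0.43, 0.44, 0.45]
    stop_epoch, best_epoch = run_stopper(losses, patience=5)
    assert (stop_epoch, best_epoch) == (7, 2)


def test_early_stopping_never_triggers_on_decreasing():
    losses = list(np.linspace(1.0, 0.1, 20))
    stop_epoch, best_epoch = run_stopper(losses, patience=5)
    assert (stop_epoch, best_epoch) == (20, 20)


def test_early_stopping_counter_resets_on_improvement():
    losses = [0.5, 0.5, 0.5, 0.5, 0.45, 0.5, 0.5, 0.5, 0.5, 0.44]
    stop_epoch, best_epoch = run_stopper(losses, patience=5)
    assert stop_epoch == 10  # reset at epochs 5 and 10, never 5 stale in a row
    assert best_epoch == 10


def test_early_stopping_tie_is_not_improvement():
    losses = [0.4, 0.4, 0.4, 0.4]
    stop_epoch, best_epoch = run_stopper(losses, patience=3)
    assert (stop_epoch, best_epoch) == (4, 1)


@pytest.mark.parametrize(
    "labels,expected",
    [
        (["a"] * 100 + ["b"] * 100 + ["c"] * 100, {"a": 1.0, "b": 1.0, "c": 1.0}),
        (["A"] * 100 + ["B"] * 50, {"A": 0.75, "B": 1.5}),
        (["x"] * 7, {"x": 1.0}),
    ],
)
def test_compute_class_weights(labels, expected):
    weights = compute_class_weights(labels)
    assert weights.keys() == expected.keys()
    for k in expected:
        assert weights[k] == pytest.approx(expected[k])


def test_compute_class_weights_empty_errors():
    with pytest.raises(ValueError):
        compute_class_weights([])


def _toy_dataset(rng, n_per_class=30, n_classes=3, dim=12):
    """Linearly separable blobs on a dense input."""
    X, labels = [], []
    for c in range(n_classes):
        center = np.zeros(dim)
        center[c] = 3.0
        X.append(center + 0.3 * rng.normal(size=(n_per_class, dim)))
        labels += [c] * n_per_class
    y = one_hot(labels, list(range(n_classes)))
    return np.vstack(X), y


def _toy_spec(dim=12, n_classes=3):
    spec = build_grenc(input_dim=dim, n_classes=n_classes)
    return spec


def test_train_checkpoint_best_and_reproducible(rng):
    X, y = _toy_dataset(rng)
    spec = _toy_spec()
    cfg = TrainingConfig(batch_size=16, max_epochs=15, seed=9)
    net, hist = train(spec, (X[::2], y[::2]), (X[1::2], y[1::2]), cfg)
    # checkpointed model is at least as good as the final epoch's model
    proba = net.predict_proba(X[1::2])
    ckpt_loss = -np.mean(np.log(np.sum(proba * y[1::2], axis=1) + 1e-12))
    assert ckpt_loss <= hist.val_loss[-1] + 1e-9
    assert ckpt_loss == pytest.approx(min(hist.val_loss), abs=1e-9)
    assert hist.val_loss[hist.best_epoch - 1] == min(hist.val_loss)
    # same seed, same histories
    _, hist2 = train(spec, (X[::2], y[::2]), (X[1::2], y[1::2]), cfg)
    assert hist2.val_loss == hist.val_loss
    assert hist2.train_loss == hist.train_loss


def test_train_unit_class_weights_match_unweighted(rng):
    X, y = _toy_dataset(rng)
    cfg = TrainingConfig(batch_size=16, max_epochs=5, seed=3)
    cfg_w = TrainingConfig(
        batch_size=16, max_epochs=5, seed=3,
        class_weights={0: 1.0, 1: 1.0, 2: 1.0},
    )
    _, h_plain = train(_toy_spec(), (X, y), (X, y), cfg)
    _, h_weighted = train(_toy_spec(), (X, y), (X, y), cfg_w)
    assert np.allclose(h_plain.train_loss, h_weighted.train_loss, atol=1e-7)


def test_train_input_validation(rng):
    X, y = _toy_dataset(rng)
    cfg = TrainingConfig(max_epochs=1)
    with pytest.raises(ValueError, match="empty"):
        train(_toy_spec(), (X[:0], y[:0]), (X, y), cfg)
    bad = y.copy()
    bad[0] = 0  # row outside the class set
    with pytest.raises(ValueError, match="class set"):
        train(_toy_spec(), (X, bad), (X, y), cfg)


def test_one_hot_rejects_unknown_label():
    with pytest.raises(ValueError, match="outside the class set"):
        one_hot(["a", "z"], ["a", "b"])


def test_stratified_folds_partition_balance_determinism():
    labels = np.repeat(np.arange(6), 103)  # 103 per class: remainders spread
    folds = stratified_folds(labels, 10, seed=5)
    all_idx = np.concatenate(folds)
    assert len(all_idx) == len(labels)
    assert len(np.unique(all_idx)) == len(labels)  # disjoint partition
    for cls in range(6):
        counts = [int((labels[f] == cls).sum()) for f in folds]
        assert max(counts) - min(counts) <= 1
    folds2 = stratified_folds(labels, 10, seed=5)
    assert all(np.array_equal(a, b) for a, b in zip(folds, folds2))
    with pytest.raises(ValueError, match="fewer than"):
        stratified_folds(np.repeat(np.arange(2), 9), 10, seed=0)


def test_ten_fold_cv_runs_and_balances(rng):
    X, y = _toy_dataset(rng, n_per_class=20, n_classes=3)
    cfg = TrainingConfig(batch_size=20, max_epochs=3, seed=1)
    histories, median_curve, folds = ten_fold_cv(
        (X, y), lambda: _toy_spec(), cfg
    )
    assert len(histories) == 10
    assert len(folds) == 10
    labels = y.argmax(axis=1)
    for f in folds:
        counts = np.bincount(labels[f], minlength=3)
        assert counts.tolist() == [2, 2, 2]  # 20 per class over 10 folds
    assert len(median_curve) == max(len(h) for h in histories)


def test_median_curve_carries_last_value_forward():
    h1 = TrainingHistory(val_loss=[1.0, 0.5])
    h2 = TrainingHistory(val_loss=[0.9, 0.8, 0.7, 0.6])
    curve = median_validation_curve([h1, h2])
    # h1 contributes 0.5 at epochs 3 and 4
    assert curve.tolist() == [0.95, 0.65, 0.6, 0.55]
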