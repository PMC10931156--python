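"""Training, evaluation and dataset splitting for the ripeness classifier.

The training protocol mirrors the reference recipe: cross-entropy loss, SGD
with momentum 0.9 and weight decay 1e-4, and a three-step learning-rate
schedule 0.01 -> 0.005 -> 0.001 whose breakpoints sit at 60 % and 90 % of
the epoch budget (the proportions of epochs 300 and 450 out of 500).  Desk
defaults train for a handful of epochs at batch size 32; the full-scale
protocol (500 epochs, batch 256) is reachable through the same config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layers import SGD, softmax_cross_entropy
from .model import DenseNetClassifier


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 8
    batch_size: int = 32
    lr_steps: tuple[float, float, float] = (0.01, 0.005, 0.001)
    lr_breakpoints: tuple[float, float] = (0.6, 0.9)  # fractions of the epoch budget
    momentum: float = 0.9
    weight_decay: float = 1e-4
    seed: int = 0
    # re-estimate batch-norm running statistics with the final weights after
    # the last epoch; with few epochs and a high learning rate the running
    # averages otherwise lag the parameters and depress eval-mode accuracy
    bn_recalibrate: bool = True
    recal_batches: int = 24

    def lr_at(self, epoch: int) -> float:
        frac = epoch / max(self.epochs, 1)
        if frac < self.lr_breakpoints[0]:
            return self.lr_steps[0]
        if frac < self.lr_breakpoints[1]:
            return self.lr_steps[1]
        return self.lr_steps[2]


@dataclass
class TrainState:
    """Carries the optimizer across calls so training is resumable."""

    optimizer: SGD
    epochs_done: int = 0
    history: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["epoch", "lr", "loss", "accuracy"]))


def split_dataset(n: int, ratio: tuple[int, int] = (17, 3), seed: int = 0) -> np.ndarray:
    """Seeded random train/validation partition ("train"/"val" labels),
    disjoint and exhaustive, rounding toward the training split."""
    from ..synth.ripeness import split_assignments

    return split_assignments(n, ratio, np.random.default_rng(seed))


def train(
    model: DenseNetClassifier,
    images: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
    state: TrainState | None = None,
    epochs: int | None = None,
) -> TrainState:
    """Train in place for ``epochs`` (default: the remaining budget).

    Raises when any class index expected by the model is absent from the
    training labels.  A zero-epoch call returns an unchanged model and an
    empty history.
    """
    present = set(np.unique(labels).tolist())
    missing = [c for c in range(model.config.num_classes) if c not in present]
    if missing:
        raise ValueError(f"training split is missing class indices {missing}")
    if state is None:
        state = TrainState(optimizer=SGD(model.params(), momentum=config.momentum,
                                         weight_decay=config.weight_decay))
    n_epochs = (config.epochs - state.epochs_done) if epochs is None else epochs
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, state.epochs_done]))
    n = len(labels)
    records = []
    for _ in range(n_epochs):
        epoch = state.epochs_done
        lr = config.lr_at(epoch)
        order = rng.permutation(n)
        total_loss, total_correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            x, y = images[idx], labels[idx]
            logits = model.forward(x, train=True)
            loss, dlogits, probs = softmax_cross_entropy(logits, y)
            state.optimizer.zero_grad()
            model.backward(dlogits)
            state.optimizer.step(lr)
            total_loss += loss * len(idx)
            total_correct += int((probs.argmax(axis=1) == y).sum())
        records.append({"epoch": epoch, "lr": lr,
                        "loss": total_loss / n, "accuracy": 100.0 * total_correct / n})
        state.epochs_done += 1
    if records:
        new = pd.DataFrame(records)
        state.history = new if state.history.empty else pd.concat(
            [state.history, new], ignore_index=True)
    if records and config.bn_recalibrate:
        recalibrate_batchnorm(model, images, config.batch_size, config.recal_batches,
                              rng=np.random.default_rng(config.seed))
    return state


def recalibrate_batchnorm(model: DenseNetClassifier, images: np.ndarray,
                          batch_size: int, n_batches: int,
                          rng: np.random.Generator | None = None) -> None:
    """Replace every batch-norm layer's running statistics with the average
    of batch statistics under the current weights (cumulative moving average
    over up to ``n_batches`` forward passes)."""
    from .layers import BatchNorm2d

    bns = [layer for layer in _walk_layers(model) if isinstance(layer, BatchNorm2d)]
    if not bns:
        return
    saved = [bn.momentum for bn in bns]
    order = (rng.permutation(len(images)) if rng is not None
             else np.arange(len(images)))
    starts = range(0, len(images), batch_size)
    try:
        for i, start in enumerate(list(starts)[:n_batches]):
            for bn in bns:
                bn.momentum = 1.0 / (i + 1)
            model.forward(images[order[start:start + batch_size]], train=True)
    finally:
        for bn, m in zip(bns, saved):
            bn.momentum = m


def _walk_layers(model: DenseNetClassifier):
    from .model import DenseBlock, DenseLayer, Transition

    for layer in model.body + model.head:
        yield layer
        if isinstance(layer, DenseBlock):
            for sub in layer.layers:
                yield sub.bn
        elif isinstance(layer, (Transition, DenseLayer)):
            yield layer.bn


def predict(model: DenseNetClassifier, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    preds = []
    for start in range(0, len(images), batch_size):
        logits = model.forward(images[start:start + batch_size], train=False)
        preds.append(logits.argmax(axis=1))
    return np.concatenate(preds) if preds else np.empty(0, dtype=int)


@dataclass(frozen=True)
class EvalReport:
    """Confusion matrix with the derived accuracy / precision / recall /
    macro-F1 metrics (F1 per class = 2pr/(p+r), zero when p + r = 0)."""

    confusion: np.ndarray  # (K, K), rows = true class
    classes: tuple[str, ...]

    @property
    def accuracy(self) -> float:
        total = self.confusion.sum()
        return 100.0 * np.trace(self.confusion) / total if total else 0.0

    @property
    def precision(self) -> np.ndarray:
        col = self.confusion.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(col > 0, np.diag(self.confusion) / col, 0.0)
        return p

    @property
    def recall(self) -> np.ndarray:
        row = self.confusion.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(row > 0, np.diag(self.confusion) / row, 0.0)
        return r

    @property
    def f1_per_class(self) -> np.ndarray:
        p, r = self.precision, self.recall
        s = p + r
        with np.errstate(invalid="ignore", divide="ignore"):
            f1 = np.where(s > 0, 2 * p * r / s, 0.0)
        return f1

    @property
    def macro_f1(self) -> float:
        return float(self.f1_per_class.mean())

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy,
            "macro_f1": self.macro_f1,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1_per_class": self.f1_per_class.tolist(),
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
        }


def report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                            classes: tuple[str, ...]) -> EvalReport:
    k = len(classes)
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[t, p] += 1
    return EvalReport(confusion=confusion, classes=tuple(classes))


def evaluate(model: DenseNetClassifier, images: np.ndarray, labels: np.ndarray,
             classes: tuple[str, ...]) -> EvalReport:
    if len(images) == 0:
        raise ValueError("evaluation split must not be empty")
    return report_from_predictions(labels, predict(model, images), classes)
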