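"""Training protocol for segmentation models.

The protocol: mini-batches of 4 with seeded shuffling, Adam at learning
rate 1e-4, up to 40 epochs, early stopping when the validation loss has
not improved for 5 consecutive epochs, and the weights with the
smallest validation loss restored at the end.  "Improve" means a strict
decrease (no minimum delta); ties on the minimum keep the earlier
epoch.

A dataset here is a list of ``(x, y)`` samples with ``x`` a
channels-first float tensor ``(C, X, Y, Z)`` and ``y`` integer class
labels ``(X, Y, Z)``.

:class:`UNetSegmenter` wraps the same loop in a scikit-learn estimator
(fit/predict/predict_proba/score, get_params/set_params) so models
compose with sklearn model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .errors import ValidationError
from .metrics import MetricsReport, dice_coefficient, metrics_report
from .nn import (
    Adam,
    SegmentationModel,
    soft_dice_loss,
    softmax_cross_entropy,
    weighted_cross_entropy,
)
from .unet import UNetConfig, build_unet, save_checkpoint

__all__ = [
    "TrainConfig",
    "TrainResult",
    "early_stop_decision",
    "train",
    "evaluate",
    "predict_labels",
    "UNetSegmenter",
]

Sample = tuple[np.ndarray, np.ndarray]

_LOSSES = ("cross_entropy", "weighted_cross_entropy", "soft_dice")


def _resolve_loss(name: str, train_set: list["Sample"], n_classes: int):
    """Bind the named loss to a ``(logits, target) -> (loss, dlogits)`` callable.

    ``weighted_cross_entropy`` derives normalized inverse-frequency
    class weights from the training-set labels, the standard rebalancing
    when tumor classes occupy a small voxel fraction.
    """
    if name == "cross_entropy":
        return softmax_cross_entropy
    if name == "soft_dice":
        return soft_dice_loss
    counts = np.zeros(n_classes, dtype=np.int64)
    for _, y in train_set:
        counts += np.bincount(y.ravel(), minlength=n_classes)
    freq = counts / max(1, counts.sum())
    weights = 1.0 / np.maximum(freq, 1e-6)
    weights = (weights / weights.sum()).astype(np.float32)
    return lambda logits, target: weighted_cross_entropy(logits, target, weights)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters; defaults follow the training protocol
    (batch 4, 40 epochs, lr 1e-4, patience 5, monitor validation loss)."""

    batch_size: int = 4
    max_epochs: int = 40
    learning_rate: float = 1e-4
    patience: int = 5
    monitor: str = "val_loss"
    loss: str = "cross_entropy"
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValidationError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.max_epochs < 1:
            raise ValidationError(f"max_epochs must be >= 1, got {self.max_epochs}")
        if self.patience < 0:
            raise ValidationError(f"patience must be >= 0, got {self.patience}")
        if self.learning_rate <= 0:
            raise ValidationError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.loss not in _LOSSES:
            raise ValidationError(f"unknown loss {self.loss!r}; available: {list(_LOSSES)}")
        if self.optimizer != "adam":
            raise ValidationError(f"unknown optimizer {self.optimizer!r}")
        if self.monitor != "val_loss":
            raise ValidationError(f"only 'val_loss' monitoring is supported, got {self.monitor!r}")


@dataclass
class TrainResult:
    """Per-epoch history plus the identity of the restored best epoch."""

    history: list[dict] = field(default_factory=list)
    best_epoch: int = 0
    best_checkpoint: Path | None = None
    stopped_early: bool = False

    @property
    def val_losses(self) -> list[float]:
        return [h["val_loss"] for h in self.history]


def early_stop_decision(val_losses, patience: int) -> tuple[bool, int]:
    """Early-stopping rule on a validation-loss sequence.

    ``best_epoch`` is the argmin (first occurrence on ties).  With
    ``patience > 0``, stop once ``patience`` epochs have elapsed since
    the best; with ``patience == 0``, stop at the first epoch that
    fails to improve on the running best.
    """
    losses = list(val_losses)
    if not losses:
        raise ValidationError("val_losses must be nonempty")
    best_epoch = int(np.argmin(losses))  # first occurrence on ties
    since_best = len(losses) - 1 - best_epoch
    stop = since_best >= (patience if patience > 0 else 1)
    return stop, best_epoch


def _validate_set(dataset: list[Sample], model: SegmentationModel, name: str) -> None:
    if not dataset:
        raise ValidationError(f"{name} set must be nonempty")
    for x, y in dataset:
        if x.ndim != 4 or y.ndim != 3:
            raise ValidationError(f"{name} samples must be (C,X,Y,Z) inputs with (X,Y,Z) labels")
        if x.shape[0] != model.in_channels:
            raise ValidationError(
                f"{name} sample has {x.shape[0]} channels but the model expects {model.in_channels}"
            )
        if x.shape[1:] != y.shape:
            raise ValidationError(f"{name} sample spatial shape {x.shape[1:]} != label shape {y.shape}")


def _dataset_loss(model: SegmentationModel, dataset: list[Sample], loss_fn) -> tuple[float, float]:
    """Mean loss and global Dice of argmax predictions over a dataset."""
    losses = []
    preds, truths = [], []
    for x, y in dataset:
        logits = model.forward_logits(x[None], train=False)
        loss, _ = loss_fn(logits, y[None])
        losses.append(loss)
        preds.append(np.argmax(logits[0], axis=0))
        truths.append(y)
    pred = np.stack(preds)
    truth = np.stack(truths)
    dice = float(dice_coefficient(pred, truth, model.n_classes, mode="global"))
    return float(np.mean(losses)), dice


def train(
    model: SegmentationModel,
    train_set: list[Sample],
    val_set: list[Sample],
    config: TrainConfig = TrainConfig(),
    *,
    checkpoint_path: str | Path | None = None,
    checkpoint_meta: dict | None = None,
) -> TrainResult:
    """Run the full training loop; the model ends with the best weights.

    Checkpoints are kept in memory and additionally written to
    ``checkpoint_path`` (``.npz`` + JSON sidecar) when given.  Fully
    deterministic given ``config.seed``.
    """
    _validate_set(train_set, model, "train")
    _validate_set(val_set, model, "validation")
    loss_fn = _resolve_loss(config.loss, train_set, model.n_classes)
    rng = np.random.default_rng(config.seed)
    model.set_dropout_rng(np.random.default_rng(rng.integers(2**31)))
    trainable = getattr(model, "trainable_parameters", model.parameters)()
    opt = Adam(trainable, lr=config.learning_rate)

    result = TrainResult()
    best_loss = np.inf
    best_weights = model.get_weights()

    n = len(train_set)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x = np.stack([train_set[i][0] for i in idx])
            y = np.stack([train_set[i][1] for i in idx])
            logits = model.forward_logits(x, train=True)
            loss, dlogits = loss_fn(logits, y)
            epoch_losses.append(loss)
            for p in trainable:
                p.zero_grad()
            model.backward(dlogits)
            opt.step()
        val_loss, val_dice = _dataset_loss(model, val_set, loss_fn)
        result.history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
                "val_dice": val_dice,
            }
        )
        if val_loss < best_loss:
            best_loss = val_loss
            best_weights = model.get_weights()
        stop, best_epoch = early_stop_decision(result.val_losses, config.patience)
        result.best_epoch = best_epoch
        if stop:
            result.stopped_early = True
            break

    model.set_weights(best_weights)
    if checkpoint_path is not None:
        meta = dict(checkpoint_meta or {})
        meta.setdefault("best_epoch", result.best_epoch)
        meta.setdefault("best_val_loss", float(best_loss))
        result.best_checkpoint = save_checkpoint(
            model, checkpoint_path, train_seed=config.seed, extra=meta,
            modalities=meta.get("modalities"),
        )
    return result


def predict_labels(model: SegmentationModel, x: np.ndarray) -> np.ndarray:
    """Argmax class labels for one ``(C, X, Y, Z)`` input."""
    probs = model.forward(x[None], train=False)
    return np.argmax(probs[0], axis=0)


def evaluate(model: SegmentationModel, test_set: list[Sample]) -> MetricsReport:
    """Forward every test subject, argmax to labels, and compute the six
    metrics (plus per-class IoU) over all test voxels pooled together."""
    _validate_set(test_set, model, "test")
    preds = np.stack([predict_labels(model, x) for x, _ in test_set])
    truths = np.stack([y for _, y in test_set])
    return metrics_report(preds, truths, model.n_classes)


class UNetSegmenter(BaseEstimator):
    """Scikit-learn style 3D U-Net voxel classifier.

    Parameters mirror :class:`~xaimri.unet.UNetConfig` and
    :class:`TrainConfig`.  ``fit(X, y)`` takes ``X`` of shape
    ``(n_subjects, C, X, Y, Z)`` and integer labels ``y`` of shape
    ``(n_subjects, X, Y, Z)``; a validation set may be passed
    explicitly or is split off with ``val_fraction``.

    Fitted attributes: ``model_`` (the trained network), ``history_``,
    ``best_epoch_``, ``stopped_early_``, ``n_iter_``.
    """

    def __init__(self, n_classes: int = 4, depth_levels: int = 4, base_filters: int = 16,
                 dropout_rate: float = 0.2, kernel_size: int = 3, batch_size: int = 4,
                 max_epochs: int = 40, learning_rate: float = 1e-4, patience: int = 5,
                 loss: str = "cross_entropy", val_fraction: float = 0.15,
                 random_state: int = 0):
        self.n_classes = n_classes
        self.depth_levels = depth_levels
        self.base_filters = base_filters
        self.dropout_rate = dropout_rate
        self.kernel_size = kernel_size
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.patience = patience
        self.loss = loss
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _to_samples(self, X, y) -> list[Sample]:
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 5 or y.ndim != 4 or X.shape[0] != y.shape[0]:
            raise ValidationError(
                f"expected X (n, C, X, Y, Z) and y (n, X, Y, Z); got {X.shape} and {y.shape}"
            )
        return [(X[i], y[i].astype(np.int64)) for i in range(X.shape[0])]

    def fit(self, X, y, *, validation_data: tuple | None = None) -> "UNetSegmenter":
        samples = self._to_samples(X, y)
        config = UNetConfig(
            in_channels=int(np.asarray(X).shape[1]), n_classes=self.n_classes,
            depth_levels=self.depth_levels, base_filters=self.base_filters,
            dropout_rate=self.dropout_rate, kernel_size=self.kernel_size,
        )
        self.model_ = build_unet(config, seed=self.random_state)
        if validation_data is not None:
            train_samples = samples
            val_samples = self._to_samples(*validation_data)
        else:
            n_val = max(1, int(round(self.val_fraction * len(samples))))
            if n_val >= len(samples):
                raise ValidationError(
                    f"val_fraction={self.val_fraction} leaves no training samples for n={len(samples)}"
                )
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(len(samples))
            val_samples = [samples[i] for i in order[:n_val]]
            train_samples = [samples[i] for i in order[n_val:]]
        train_config = TrainConfig(
            batch_size=self.batch_size, max_epochs=self.max_epochs,
            learning_rate=self.learning_rate, patience=self.patience,
            loss=self.loss, seed=self.random_state,
        )
        result = train(self.model_, train_samples, val_samples, train_config)
        self.history_ = result.history
        self.best_epoch_ = result.best_epoch
        self.stopped_early_ = result.stopped_early
        self.n_iter_ = len(result.history)
        self.n_features_in_ = int(np.asarray(X).shape[1])
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        return np.stack([predict_labels(self.model_, x) for x in X])

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        return np.stack([self.model_.forward(x[None], train=False)[0] for x in X])

    def score(self, X, y) -> float:
        """Macro mean IoU of the predictions against ``y``."""
        from .metrics import mean_iou

        pred = self.predict(X)
        return mean_iou(pred, np.asarray(y), self.n_classes)

    def evaluation_report(self, X, y) -> MetricsReport:
        samples = self._to_samples(X, y)
        return evaluate(self.model_, samples)
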