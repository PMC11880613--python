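"""Feature-level fusion of two pre-trained dual-modality models.

The ensemble strips each base model's output layer, concatenates the
penultimate feature maps along channels, fuses them with a 3×3×3
stride-1 16-channel ReLU convolution, and finishes with a 1³
convolution to the class count under a softmax — so the new head
learns to arbitrate between the two bases' representations.

The default pairing is T2+T1ce with T1ce+FLAIR.  Because T1ce appears
in both pairs, the ensemble consumes a 3-channel union tensor
(T2, T1ce, FLAIR) and a routing table forwards each base the channels
it was trained on, in its own order.  With ``freeze_base`` (the
default) only the fusion convolution and output head are trainable;
base weights are bit-identical before and after fusion training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import StructuralError, ValidationError
from .nn import Conv3d, Param, ReLU, SegmentationModel
from .nn.network import UNet3D
from .phantom import MODALITIES
from .unet import UNetConfig, build_unet

__all__ = [
    "EnsembleConfig",
    "FeatureExtractor",
    "EnsembleNet",
    "strip_output_layer",
    "build_ensemble",
    "ensemble_forward",
    "save_ensemble_checkpoint",
    "load_ensemble_checkpoint",
    "FusionEnsembleSegmenter",
]


@dataclass(frozen=True)
class EnsembleConfig:
    """Fusion-head hyperparameters (3³ kernel, stride 1, 16 channels)."""

    fusion_filters: int = 16
    fusion_kernel: int = 3
    fusion_stride: int = 1
    freeze_base: bool = True
    n_classes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fusion_filters < 1:
            raise ValidationError(f"fusion_filters must be >= 1, got {self.fusion_filters}")
        if self.fusion_kernel % 2 != 1:
            raise ValidationError(f"fusion_kernel must be odd, got {self.fusion_kernel}")
        if self.fusion_stride != 1:
            raise ValidationError("only stride 1 is supported (shape-preserving fusion)")
        if self.n_classes < 2:
            raise ValidationError(f"n_classes must be >= 2, got {self.n_classes}")


class FeatureExtractor:
    """A base model with its output layer removed.

    Calling it yields the activations that fed the removed output
    layer; spatial dims equal the input's.
    """

    def __init__(self, model: UNet3D):
        if not hasattr(model, "forward_features") or not hasattr(model, "out_conv"):
            raise StructuralError(
                f"{type(model).__name__} has no identifiable output layer to strip"
            )
        self.model = model
        self.out_channels = model.penultimate_channels

    def __call__(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        return self.model.forward_features(x, train=train)

    def backward(self, dfeats: np.ndarray) -> np.ndarray:
        return self.model.backward_from_features(dfeats)


def strip_output_layer(model: UNet3D) -> FeatureExtractor:
    """Remove the final classification layer, keeping everything before it."""
    return FeatureExtractor(model)


def _union_order(pair_a: tuple[str, ...], pair_b: tuple[str, ...]) -> list[str]:
    order: list[str] = []
    for m in list(pair_a) + list(pair_b):
        if m not in order:
            order.append(m)
    return order


class EnsembleNet(SegmentationModel):
    """Two frozen (or finetunable) feature extractors + trainable fusion head.

    Named activations: ``fusion`` (post-ReLU fused maps) and
    ``out_conv`` (logits); Grad-CAM targets ``fusion`` by default.
    """

    def __init__(self, base_a: UNet3D, base_b: UNet3D,
                 modalities_a: tuple[str, ...], modalities_b: tuple[str, ...],
                 config: EnsembleConfig = EnsembleConfig()):
        if base_a.n_classes != base_b.n_classes:
            raise StructuralError(
                f"base models disagree on n_classes: {base_a.n_classes} vs {base_b.n_classes}"
            )
        for name, pair in (("base_a", modalities_a), ("base_b", modalities_b)):
            if len(pair) != 2:
                raise ValidationError(f"{name} modality pair must have exactly 2 entries, got {pair}")
            unknown = [m for m in pair if m not in MODALITIES]
            if unknown:
                raise ValidationError(f"{name} has unknown modality name(s) {unknown}")
        for name, model, pair in (("base_a", base_a, modalities_a), ("base_b", base_b, modalities_b)):
            if model.in_channels != len(pair):
                raise StructuralError(
                    f"{name} expects {model.in_channels} channels but its pair {pair} has {len(pair)}"
                )
        self.config = config
        self.extractor_a = strip_output_layer(base_a)
        self.extractor_b = strip_output_layer(base_b)
        self.modalities_a = tuple(modalities_a)
        self.modalities_b = tuple(modalities_b)
        self.union_modalities = _union_order(self.modalities_a, self.modalities_b)
        self.routing = {
            "base_a": tuple(self.union_modalities.index(m) for m in self.modalities_a),
            "base_b": tuple(self.union_modalities.index(m) for m in self.modalities_b),
        }
        self.in_channels = len(self.union_modalities)
        self.n_classes = config.n_classes
        rng = np.random.default_rng(config.seed)
        concat_ch = self.extractor_a.out_channels + self.extractor_b.out_channels
        self.fusion_conv = Conv3d(concat_ch, config.fusion_filters, config.fusion_kernel,
                                  rng, "fusion_conv")
        self.fusion_relu = ReLU()
        self.out_conv = Conv3d(config.fusion_filters, config.n_classes, 1, rng, "out_conv")
        self._capture: tuple = ()
        self.activations: dict[str, np.ndarray] = {}
        self.captured_grads: dict[str, np.ndarray] = {}
        self._feat_split = self.extractor_a.out_channels

    @property
    def activation_names(self) -> list[str]:
        return ["fusion", "out_conv"]

    @property
    def fusion_channels(self) -> int:
        return self.config.fusion_filters

    def parameters(self) -> list[Param]:
        return (
            self.extractor_a.model.parameters()
            + self.extractor_b.model.parameters()
            + self.fusion_conv.parameters()
            + self.out_conv.parameters()
        )

    def trainable_parameters(self) -> list[Param]:
        head = self.fusion_conv.parameters() + self.out_conv.parameters()
        if self.config.freeze_base:
            return head
        return self.parameters()

    def _dropout_layers(self):
        if self.config.freeze_base:
            return []
        return self.extractor_a.model._dropout_layers() + self.extractor_b.model._dropout_layers()

    def _route(self, x: np.ndarray, key: str) -> np.ndarray:
        return np.ascontiguousarray(x[:, list(self.routing[key])])

    def forward_logits(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 5 or x.shape[1] != self.in_channels:
            raise ValidationError(
                f"expected (N, {self.in_channels}, X, Y, Z) input in union modality order "
                f"{self.union_modalities}, got shape {x.shape}"
            )
        base_train = train and not self.config.freeze_base
        fa = self.extractor_a(self._route(x, "base_a"), train=base_train)
        fb = self.extractor_b(self._route(x, "base_b"), train=base_train)
        h = np.concatenate([fa, fb], axis=1)
        h = self.fusion_conv.forward(h, train=train)
        h = self.fusion_relu.forward(h, train=train)
        if self._capture and "fusion" in self._capture:
            self.activations["fusion"] = h
        logits = self.out_conv.forward(h, train=train)
        if self._capture and "out_conv" in self._capture:
            self.activations["out_conv"] = logits
        return logits

    def backward(self, dlogits: np.ndarray) -> np.ndarray | None:
        """Backprop through the head (and the bases unless frozen)."""
        if self._capture and "out_conv" in self._capture:
            self.captured_grads["out_conv"] = dlogits
        g = self.out_conv.backward(dlogits)
        if self._capture and "fusion" in self._capture:
            self.captured_grads["fusion"] = g
        g = self.fusion_relu.backward(g)
        g = self.fusion_conv.backward(g)
        if self.config.freeze_base:
            return None
        ga, gb = g[:, : self._feat_split], g[:, self._feat_split :]
        dxa = self.extractor_a.backward(np.ascontiguousarray(ga))
        dxb = self.extractor_b.backward(np.ascontiguousarray(gb))
        dx = np.zeros(
            (dxa.shape[0], self.in_channels) + dxa.shape[2:], dtype=np.float32
        )
        for j, idx in enumerate(self.routing["base_a"]):
            dx[:, idx] += dxa[:, j]
        for j, idx in enumerate(self.routing["base_b"]):
            dx[:, idx] += dxb[:, j]
        return dx


def build_ensemble(
    base_a: UNet3D | tuple[UNet3D, tuple[str, str]],
    base_b: UNet3D | tuple[UNet3D, tuple[str, str]] = None,
    config: EnsembleConfig = EnsembleConfig(),
    *,
    modalities_a: tuple[str, str] = ("T2", "T1ce"),
    modalities_b: tuple[str, str] = ("T1ce", "FLAIR"),
) -> EnsembleNet:
    """Assemble the fusion ensemble from two pre-trained base models.

    Bases may be passed as ``(model, modality_pair)`` tuples or as bare
    models with the pairs given via keywords (defaults: T2+T1ce and
    T1ce+FLAIR).
    """
    if isinstance(base_a, tuple):
        base_a, modalities_a = base_a
    if isinstance(base_b, tuple):
        base_b, modalities_b = base_b
    return EnsembleNet(base_a, base_b, tuple(modalities_a), tuple(modalities_b), config)


def ensemble_forward(model: EnsembleNet, x: np.ndarray) -> np.ndarray:
    """Per-voxel class probabilities for a union-modality input tensor."""
    single = x.ndim == 4
    probs = model.forward(x[None] if single else x, train=False)
    return probs[0] if single else probs


def save_ensemble_checkpoint(model: EnsembleNet, path: str | Path, *, extra: dict | None = None) -> Path:
    """Weights archive + JSON sidecar recording both base configs and the
    channel routing table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    weights = model.get_weights()
    np.savez(path, **{f"w{i}": w for i, w in enumerate(weights)})

    def _base_config(m: UNet3D) -> dict:
        return {
            "in_channels": m.in_channels, "n_classes": m.n_classes,
            "depth_levels": m.depth_levels, "base_filters": m.base_filters,
            "dropout_rate": m.dropout_rate, "kernel_size": m.kernel_size,
            "init_seed": m.seed,
        }

    sidecar = {
        "ensemble_config": {
            "fusion_filters": model.config.fusion_filters,
            "fusion_kernel": model.config.fusion_kernel,
            "fusion_stride": model.config.fusion_stride,
            "freeze_base": model.config.freeze_base,
            "n_classes": model.config.n_classes,
            "seed": model.config.seed,
        },
        "base_a": {"config": _base_config(model.extractor_a.model), "modalities": list(model.modalities_a)},
        "base_b": {"config": _base_config(model.extractor_b.model), "modalities": list(model.modalities_b)},
        "union_modalities": model.union_modalities,
        "routing": {k: list(v) for k, v in model.routing.items()},
    }
    if extra:
        sidecar.update(extra)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    Path(str(npz_path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return npz_path


def load_ensemble_checkpoint(path: str | Path) -> tuple[EnsembleNet, dict]:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())

    def _rebuild(entry: dict) -> UNet3D:
        cfg = dict(entry["config"])
        seed = cfg.pop("init_seed", 0)
        return build_unet(UNetConfig(**cfg), seed=seed)

    model = EnsembleNet(
        _rebuild(sidecar["base_a"]), _rebuild(sidecar["base_b"]),
        tuple(sidecar["base_a"]["modalities"]), tuple(sidecar["base_b"]["modalities"]),
        EnsembleConfig(**sidecar["ensemble_config"]),
    )
    with np.load(path) as archive:
        model.set_weights([archive[f"w{i}"] for i in range(len(archive.files))])
    return model, sidecar


class FusionEnsembleSegmenter:
    """Estimator-style wrapper: fit the fusion head on union-modality data.

    ``base_a`` and ``base_b`` are fitted :class:`~xaimri.train.UNetSegmenter`
    instances (or bare networks); ``fit(X, y)`` expects ``X`` stacked in
    the union modality order exposed as ``union_modalities_`` after
    construction of the inner network.
    """

    def __init__(self, base_a, base_b, *, modalities_a=("T2", "T1ce"),
                 modalities_b=("T1ce", "FLAIR"), fusion_filters: int = 16,
                 freeze_base: bool = True, batch_size: int = 4, max_epochs: int = 40,
                 learning_rate: float = 1e-4, patience: int = 5,
                 loss: str = "cross_entropy", val_fraction: float = 0.15,
                 random_state: int = 0):
        self.base_a = base_a
        self.base_b = base_b
        self.modalities_a = tuple(modalities_a)
        self.modalities_b = tuple(modalities_b)
        self.fusion_filters = fusion_filters
        self.freeze_base = freeze_base
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.patience = patience
        self.loss = loss
        self.val_fraction = val_fraction
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "base_a", "base_b", "modalities_a", "modalities_b", "fusion_filters",
            "freeze_base", "batch_size", "max_epochs", "learning_rate", "patience",
            "loss", "val_fraction", "random_state",
        )}

    def set_params(self, **params) -> "FusionEnsembleSegmenter":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValidationError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _network(self, obj) -> UNet3D:
        return obj.model_ if hasattr(obj, "model_") else obj

    def fit(self, X, y, *, validation_data: tuple | None = None) -> "FusionEnsembleSegmenter":
        from .train import TrainConfig, train

        net_a, net_b = self._network(self.base_a), self._network(self.base_b)
        config = EnsembleConfig(
            fusion_filters=self.fusion_filters, freeze_base=self.freeze_base,
            n_classes=net_a.n_classes, seed=self.random_state,
        )
        self.model_ = EnsembleNet(net_a, net_b, self.modalities_a, self.modalities_b, config)
        self.union_modalities_ = self.model_.union_modalities
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        samples = [(X[i], y[i].astype(np.int64)) for i in range(X.shape[0])]
        if validation_data is not None:
            Xv, yv = validation_data
            Xv = np.asarray(Xv, dtype=np.float32)
            val_samples = [(Xv[i], np.asarray(yv)[i].astype(np.int64)) for i in range(Xv.shape[0])]
            train_samples = samples
        else:
            n_val = max(1, int(round(self.val_fraction * len(samples))))
            if n_val >= len(samples):
                raise ValidationError("val_fraction leaves no training samples")
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(len(samples))
            val_samples = [samples[i] for i in order[:n_val]]
            train_samples = [samples[i] for i in order[n_val:]]
        result = train(
            self.model_, train_samples, val_samples,
            TrainConfig(batch_size=self.batch_size, max_epochs=self.max_epochs,
                        learning_rate=self.learning_rate, patience=self.patience,
                        loss=self.loss, seed=self.random_state),
        )
        self.history_ = result.history
        self.best_epoch_ = result.best_epoch
        self.stopped_early_ = result.stopped_early
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        probs = self.model_.forward(X, train=False)
        return np.argmax(probs, axis=1)

    def predict_proba(self, X) -> np.ndarray:
        return self.model_.forward(np.asarray(X, dtype=np.float32), train=False)

    def score(self, X, y) -> float:
        from .metrics import mean_iou

        return mean_iou(self.predict(X), np.asarray(y), self.model_.n_classes)
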