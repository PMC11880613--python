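"""U-Net model factory and modality stacking.

A trained model is only meaningful together with the modality order its
input channels were stacked in, so checkpoints persist the
:class:`UNetConfig`, the modality order and the training seed in a JSON
sidecar next to the weight archive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .nn import UNet3D
from .phantom import MODALITIES
from .preprocess import PreprocessedSubject

__all__ = ["UNetConfig", "build_unet", "stack_modalities", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters of the 3D U-Net.

    ``depth_levels`` counts resolution stages including the bottleneck;
    input spatial dims must be divisible by ``2**(depth_levels-1)``.
    Filters double per stage starting from ``base_filters``.
    """

    in_channels: int = 2
    n_classes: int = 4
    depth_levels: int = 4
    base_filters: int = 16
    dropout_rate: float = 0.2
    kernel_size: int = 3

    def __post_init__(self) -> None:
        if not 1 <= self.in_channels <= 4:
            raise ValidationError(f"in_channels must be in 1..4, got {self.in_channels}")
        if self.n_classes < 2:
            raise ValidationError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.depth_levels < 1:
            raise ValidationError(f"depth_levels must be >= 1, got {self.depth_levels}")
        if self.base_filters < 1:
            raise ValidationError(f"base_filters must be >= 1, got {self.base_filters}")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError(f"dropout_rate must be in [0,1), got {self.dropout_rate}")
        if self.kernel_size % 2 != 1:
            raise ValidationError(f"kernel_size must be odd, got {self.kernel_size}")


def build_unet(config: UNetConfig, seed: int = 0) -> UNet3D:
    """Instantiate a seeded 3D U-Net from the config."""
    return UNet3D(
        in_channels=config.in_channels,
        n_classes=config.n_classes,
        depth_levels=config.depth_levels,
        base_filters=config.base_filters,
        dropout_rate=config.dropout_rate,
        kernel_size=config.kernel_size,
        seed=seed,
    )


def stack_modalities(
    subject: PreprocessedSubject | dict[str, np.ndarray],
    modalities: list[str],
) -> np.ndarray:
    """Stack preprocessed modality volumes into a channel-first tensor.

    The channel order is exactly the given list; models must be fed the
    same order they were trained with.
    """
    volumes = subject.volumes if isinstance(subject, PreprocessedSubject) else subject
    if len(set(modalities)) != len(modalities):
        dup = sorted({m for m in modalities if modalities.count(m) > 1})
        raise ValidationError(f"duplicate modality name(s) in stack order: {dup}")
    unknown = [m for m in modalities if m not in MODALITIES]
    if unknown:
        raise ValidationError(f"unknown modality name(s): {unknown}; valid: {list(MODALITIES)}")
    missing = [m for m in modalities if m not in volumes]
    if missing:
        raise ValidationError(f"subject lacks modality volume(s): {missing}")
    return np.stack([np.asarray(volumes[m], dtype=np.float32) for m in modalities], axis=0)


def save_checkpoint(
    model: UNet3D,
    path: str | Path,
    *,
    modalities: list[str] | None = None,
    train_seed: int | None = None,
    extra: dict | None = None,
) -> Path:
    """Persist weights (``.npz``) plus a JSON sidecar with the config,
    modality order and training seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    weights = model.get_weights()
    np.savez(path, **{f"w{i}": w for i, w in enumerate(weights)})
    sidecar = {
        "config": {
            "in_channels": model.in_channels,
            "n_classes": model.n_classes,
            "depth_levels": model.depth_levels,
            "base_filters": model.base_filters,
            "dropout_rate": model.dropout_rate,
            "kernel_size": model.kernel_size,
        },
        "init_seed": model.seed,
        "modalities": modalities,
        "train_seed": train_seed,
    }
    if extra:
        sidecar.update(extra)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    Path(str(npz_path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return npz_path


def load_checkpoint(path: str | Path) -> tuple[UNet3D, dict]:
    """Rebuild a U-Net from a checkpoint; returns (model, sidecar)."""
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    config = UNetConfig(**sidecar["config"])
    model = build_unet(config, seed=sidecar.get("init_seed", 0))
    with np.load(path) as archive:
        weights = [archive[f"w{i}"] for i in range(len(archive.files))]
    model.set_weights(weights)
    return model, sidecar
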