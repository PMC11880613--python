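"""Volumetric Grad-CAM for 3D segmentation models, with slice overlays.

Grad-CAM needs a scalar score to differentiate; for segmentation the
default is the mean logit of the target class over the voxels the
model actually predicts as that class (falling back to the whole-volume
mean when the predicted region is empty).  Channel weights are the
spatial mean of the score gradient at the target layer; the heat map is
the ReLU of the weighted activation sum, trilinearly upsampled to the
input grid and min-max normalized to [0, 1] (an all-zero map stays
zero).

For U-Nets the default target layer is the last convolution before the
output head (finest resolution); for the fusion ensemble it is the
fusion convolution, making the fused representation the explanandum.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import matplotlib
import numpy as np
from skimage.transform import resize as _skimage_resize

from .errors import StructuralError, ValidationError
from .nn import SegmentationModel

__all__ = ["GradCamConfig", "HeatMap", "compute_gradcam", "overlay"]


@dataclass(frozen=True)
class GradCamConfig:
    """Target selection and rendering options.

    ``target_layer=None`` picks the model's default explanation layer.
    ``score_reduction``: ``"predicted_region_mean"`` (default) or
    ``"volume_mean"``.  ``target_class`` defaults to 3, the enhancing
    tumor class after label remapping.
    """

    target_layer: str | None = None
    target_class: int = 3
    score_reduction: str = "predicted_region_mean"
    colormap: str = "jet"
    alpha: float = 0.4

    def __post_init__(self) -> None:
        if self.score_reduction not in ("predicted_region_mean", "volume_mean"):
            raise ValidationError(f"unknown score_reduction {self.score_reduction!r}")
        if not 0 <= self.alpha <= 1:
            raise ValidationError(f"alpha must be in [0,1], got {self.alpha}")
        if self.target_class < 0:
            raise ValidationError(f"target_class must be >= 0, got {self.target_class}")


@dataclass
class HeatMap:
    """Grad-CAM relevance volume in [0, 1] aligned to the input grid."""

    relevance: np.ndarray
    config: GradCamConfig
    model_hash: str = ""
    meta: dict = field(default_factory=dict)


def _default_target_layer(model: SegmentationModel) -> str:
    names = model.activation_names
    if "fusion" in names:
        return "fusion"
    # last convolution before the output head
    for name in reversed(names):
        if name != "out_conv":
            return name
    raise StructuralError("model exposes no convolutional activation to target")


def _weights_hash(model: SegmentationModel) -> str:
    h = hashlib.sha1()
    for p in model.parameters():
        h.update(np.ascontiguousarray(p.value).tobytes())
    return h.hexdigest()[:16]


def compute_gradcam(model: SegmentationModel, x: np.ndarray,
                    config: GradCamConfig = GradCamConfig()) -> HeatMap:
    """Grad-CAM relevance for one ``(C, X, Y, Z)`` input tensor."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 4:
        raise ValidationError(f"expected a single (C, X, Y, Z) input, got shape {x.shape}")
    target_layer = config.target_layer or _default_target_layer(model)
    if target_layer not in model.activation_names:
        raise StructuralError(
            f"model has no layer {target_layer!r}; available: {model.activation_names}"
        )
    if config.target_class >= model.n_classes:
        raise ValidationError(
            f"target_class {config.target_class} out of range for {model.n_classes} classes"
        )

    # backward caches are needed, but stochastic layers must stay inert:
    # zero out dropout for the pass and restore afterwards
    drops = model._dropout_layers()
    saved_rates = [d.rate for d in drops]
    for d in drops:
        d.rate = 0.0
    try:
        model.request_capture([target_layer])
        logits = model.forward_logits(x[None], train=True)
        pred = np.argmax(logits[0], axis=0)
        region = pred == config.target_class
        meta: dict = {"target_layer": target_layer, "fallback_volume_mean": False}
        dlogits = np.zeros_like(logits)
        if config.score_reduction == "predicted_region_mean" and region.any():
            dlogits[0, config.target_class][region] = 1.0 / region.sum()
        else:
            if config.score_reduction == "predicted_region_mean":
                meta["fallback_volume_mean"] = True
            dlogits[0, config.target_class] = 1.0 / pred.size
        model.backward(dlogits)
        activation = model.activations[target_layer][0]  # (K, x, y, z)
        grad = model.captured_grads[target_layer][0]
    finally:
        for d, r in zip(drops, saved_rates):
            d.rate = r
        model.clear_capture()

    channel_weights = grad.mean(axis=(1, 2, 3))  # (K,)
    cam = np.maximum(np.tensordot(channel_weights, activation, axes=(0, 0)), 0.0)
    if cam.shape != x.shape[1:]:
        cam = _skimage_resize(cam, x.shape[1:], order=1, anti_aliasing=False,
                              preserve_range=True, mode="edge")
    peak = float(cam.max())
    if peak > 0:
        cam = cam / peak
    return HeatMap(
        relevance=cam.astype(np.float32),
        config=replace(config, target_layer=target_layer),
        model_hash=_weights_hash(model),
        meta=meta,
    )


def _to_gray_rgb(slice2d: np.ndarray) -> np.ndarray:
    lo, hi = float(slice2d.min()), float(slice2d.max())
    norm = (slice2d - lo) / (hi - lo) if hi > lo else np.zeros_like(slice2d)
    return np.repeat(norm[:, :, None], 3, axis=2)


def overlay(
    heatmap: HeatMap,
    background: np.ndarray,
    slice_index: int,
    alpha: float | None = None,
    *,
    out_path: str | Path | None = None,
    panel_backgrounds: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Blend the colormapped relevance over a grayscale background slice.

    Returns the rendered uint8 RGB image (and writes it as PNG when
    ``out_path`` is given).  ``panel_backgrounds`` renders the given
    modality slices side by side before the overlay, as in a figure
    panel.  ``alpha=0`` reproduces the grayscale background exactly.
    """
    background = np.asarray(background)
    if background.shape != heatmap.relevance.shape:
        raise ValidationError(
            f"background shape {background.shape} != heat-map shape {heatmap.relevance.shape}"
        )
    if not 0 <= slice_index < background.shape[2]:
        raise ValidationError(f"slice_index {slice_index} out of range for depth {background.shape[2]}")
    a = heatmap.config.alpha if alpha is None else float(alpha)
    if not 0 <= a <= 1:
        raise ValidationError(f"alpha must be in [0,1], got {a}")

    gray = _to_gray_rgb(background[:, :, slice_index])
    cmap = matplotlib.colormaps[heatmap.config.colormap]
    colors = cmap(heatmap.relevance[:, :, slice_index])[:, :, :3]
    blended = (1.0 - a) * gray + a * colors

    panels = []
    if panel_backgrounds:
        for name in panel_backgrounds:
            vol = np.asarray(panel_backgrounds[name])
            if vol.shape != background.shape:
                raise ValidationError(f"panel volume {name!r} shape {vol.shape} != {background.shape}")
            panels.append(_to_gray_rgb(vol[:, :, slice_index]))
    image = np.concatenate(panels + [blended], axis=1) if panels else blended
    rgb8 = np.clip(np.round(image * 255.0), 0, 255).astype(np.uint8)

    if out_path is not None:
        import imageio.v3 as iio

        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        iio.imwrite(out_path, rgb8)
    return rgb8
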