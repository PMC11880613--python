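"""ROI-cropping preprocessing for multimodal brain volumes.

The pipeline standardizes a BraTS-geometry subject (240×240×155) to a
cube ready for a 3D segmentation network:

1. On a single reference axial slice of the reference modality
   (default: T1, the middle slice, index 77 of 0..154), compute the
   tight bounding box ``x1:x2, y1:y2`` of all suprathreshold pixels.
2. Keep a contiguous slab of axial slices (default [13, 141), exactly
   128 slices).
3. Crop every modality volume and the mask with the *same* box.
4. Resize each axial slice in-plane to 128×128 — linear interpolation
   for intensities, nearest-neighbor for the mask so no label value is
   ever invented.
5. Min-max normalize intensities to [0, 1] over brain voxels, and
   remap mask labels to contiguous class indices.

Everything here is deterministic: no RNG is used at any stage.  Axis
convention: ``x`` is the first in-plane axis (rows), ``y`` the second
(columns); the depth axis is last.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import resize as _skimage_resize

from .errors import BoundsError, NoForegroundError, ValidationError
from .io import Volume, remap_labels
from .phantom import MODALITIES, SyntheticSubject

__all__ = [
    "RoiBox",
    "PreprocessConfig",
    "PreprocessedSubject",
    "compute_roi_box",
    "crop_depth",
    "apply_roi",
    "resize_inplane",
    "normalize_intensity",
    "preprocess_subject",
    "RoiPreprocessor",
]


@dataclass(frozen=True)
class RoiBox:
    """Half-open in-plane bounding box plus the retained depth slab."""

    x1: int
    x2: int
    y1: int
    y2: int
    reference_slice: int
    depth_range: tuple[int, int]

    def __post_init__(self) -> None:
        if not (0 <= self.x1 < self.x2 and 0 <= self.y1 < self.y2):
            raise ValidationError(f"invalid box bounds ({self.x1},{self.x2},{self.y1},{self.y2})")
        d0, d1 = self.depth_range
        if not 0 <= d0 < d1:
            raise ValidationError(f"invalid depth_range {self.depth_range}")

    @property
    def inplane_shape(self) -> tuple[int, int]:
        return (self.x2 - self.x1, self.y2 - self.y1)

    def to_dict(self) -> dict:
        return {
            "x1": self.x1, "x2": self.x2, "y1": self.y1, "y2": self.y2,
            "reference_slice": self.reference_slice,
            "depth_range": list(self.depth_range),
        }


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the ROI pipeline.

    Defaults match the standard BraTS geometry: reference slice 77 of
    the T1 modality, depth slab [13, 141) (128 slices), in-plane target
    128, foreground = strictly positive intensity.
    """

    reference_modality: str = "T1"
    reference_slice: int = 77
    depth_range: tuple[int, int] = (13, 141)
    target_inplane: int = 128
    foreground_threshold: float = 0.0
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.reference_modality not in MODALITIES:
            raise ValidationError(f"unknown reference modality {self.reference_modality!r}")
        if self.target_inplane < 8:
            raise ValidationError(f"target_inplane must be >= 8, got {self.target_inplane}")
        d0, d1 = self.depth_range
        if not 0 <= d0 < d1:
            raise ValidationError(f"depth_range must be a valid half-open interval, got {self.depth_range}")
        if self.reference_slice < 0:
            raise ValidationError(f"reference_slice must be >= 0, got {self.reference_slice}")

    @property
    def target_depth(self) -> int:
        return self.depth_range[1] - self.depth_range[0]

    @classmethod
    def scaled(cls, grid_shape: tuple[int, int, int], target: int, **overrides) -> "PreprocessConfig":
        """Config for a non-standard grid: centered depth slab of
        ``target`` slices and the middle slice as reference."""
        nz = grid_shape[2]
        if target > nz:
            raise ValidationError(f"target depth {target} exceeds grid depth {nz}")
        start = (nz - target) // 2
        cfg = cls(
            reference_slice=nz // 2,
            depth_range=(start, start + target),
            target_inplane=target,
        )
        return replace(cfg, **overrides) if overrides else cfg


def _as_array(volume: Volume | np.ndarray) -> np.ndarray:
    return volume.data if isinstance(volume, Volume) else np.asarray(volume)


def compute_roi_box(reference: Volume | np.ndarray, config: PreprocessConfig) -> RoiBox:
    """Tight bounding box of suprathreshold pixels on the reference slice.

    Raises :class:`NoForegroundError` if no pixel exceeds the
    threshold — the full frame is never silently returned.
    """
    data = _as_array(reference)
    if data.ndim != 3:
        raise ValidationError(f"reference volume must be 3D, got ndim={data.ndim}")
    if config.reference_slice >= data.shape[2]:
        raise BoundsError(
            f"reference_slice {config.reference_slice} out of range for depth {data.shape[2]}"
        )
    axial = data[:, :, config.reference_slice]
    mask = axial > config.foreground_threshold
    if not mask.any():
        raise NoForegroundError(
            f"no pixel exceeds threshold {config.foreground_threshold} "
            f"on reference slice {config.reference_slice}"
        )
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return RoiBox(
        x1=int(rows[0]), x2=int(rows[-1]) + 1,
        y1=int(cols[0]), y2=int(cols[-1]) + 1,
        reference_slice=config.reference_slice,
        depth_range=config.depth_range,
    )


def crop_depth(volume: Volume | np.ndarray, depth_range: tuple[int, int]) -> np.ndarray:
    """Keep the contiguous axial slab ``[start, end)``."""
    data = _as_array(volume)
    start, end = depth_range
    if start >= end:
        raise BoundsError(f"depth_range start {start} must be < end {end}")
    if start < 0 or end > data.shape[2]:
        raise BoundsError(f"depth_range {depth_range} exceeds volume depth {data.shape[2]}")
    return data[:, :, start:end]


def apply_roi(volume: Volume | np.ndarray, box: RoiBox) -> np.ndarray:
    """Crop every axial slice to the box (pure slicing, no resampling)."""
    data = _as_array(volume)
    if box.x2 > data.shape[0] or box.y2 > data.shape[1]:
        raise BoundsError(
            f"box {box.inplane_shape} at ({box.x1},{box.y1}) exceeds in-plane extents {data.shape[:2]}"
        )
    return data[box.x1 : box.x2, box.y1 : box.y2, :]


def resize_inplane(volume: Volume | np.ndarray, size: int, *, is_label: bool = False) -> np.ndarray:
    """Resample each axial slice to ``size`` × ``size``.

    Intensities use linear interpolation; labels use nearest-neighbor
    (order 0), which can only select values already present.
    """
    if size < 1:
        raise ValidationError(f"size must be >= 1, got {size}")
    data = _as_array(volume)
    if data.shape[0] == size and data.shape[1] == size:
        return data.copy()
    out_shape = (size, size, data.shape[2])
    if is_label:
        out = _skimage_resize(
            data, out_shape, order=0, anti_aliasing=False, preserve_range=True, mode="edge"
        )
        return out.astype(data.dtype)
    out = _skimage_resize(
        data.astype(np.float32), out_shape, order=1, anti_aliasing=False,
        preserve_range=True, mode="edge",
    )
    return out.astype(np.float32)


def normalize_intensity(volume: Volume | np.ndarray, *, foreground_threshold: float = 0.0) -> np.ndarray:
    """Min-max rescale to [0, 1] over suprathreshold (brain) voxels.

    Constant volumes (zero range) map to all zeros; values outside the
    brain range are clipped into [0, 1].
    """
    data = _as_array(volume).astype(np.float32)
    fg = data > foreground_threshold
    if not fg.any():
        return np.zeros_like(data)
    vmin = float(data[fg].min())
    vmax = float(data[fg].max())
    if vmax <= vmin:
        return np.zeros_like(data)
    return np.clip((data - vmin) / (vmax - vmin), 0.0, 1.0)


@dataclass
class PreprocessedSubject:
    """Standardized cube volumes of one subject plus full provenance."""

    subject_id: str
    volumes: dict[str, np.ndarray]  # modality -> (s, s, d) float32 in [0,1]
    mask: np.ndarray | None  # (s, s, d) contiguous class indices, or None
    roi_box: RoiBox
    config: PreprocessConfig

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(next(iter(self.volumes.values())).shape)


def preprocess_subject(
    subject: SyntheticSubject | tuple[dict[str, np.ndarray], np.ndarray | None],
    config: PreprocessConfig = PreprocessConfig(),
    *,
    subject_id: str | None = None,
) -> PreprocessedSubject:
    """Run the full ROI pipeline on one subject.

    Accepts a :class:`~xaimri.phantom.SyntheticSubject` or a
    ``(modality→array dict, labels-or-None)`` pair.  Stage order:
    ROI box on the reference modality → depth crop → in-plane crop →
    in-plane resize → intensity normalization → label remap.  The same
    box is applied to all four modalities and the mask.
    """
    if isinstance(subject, SyntheticSubject):
        volumes = subject.volumes
        labels = subject.labels
        sid = subject.subject_id
    else:
        volumes, labels = subject
        sid = subject_id or "subject"
    missing = [m for m in MODALITIES if m not in volumes]
    if missing:
        raise ValidationError(f"subject is missing modality volume(s): {missing}")
    shapes = {m: tuple(np.asarray(volumes[m]).shape) for m in MODALITIES}
    if len(set(shapes.values())) != 1:
        raise ValidationError(f"modality volumes disagree in shape: {shapes}")
    if labels is not None and tuple(np.asarray(labels).shape) != next(iter(shapes.values())):
        raise ValidationError(
            f"mask shape {np.asarray(labels).shape} differs from modality shape {next(iter(shapes.values()))}"
        )

    box = compute_roi_box(np.asarray(volumes[config.reference_modality]), config)

    out_volumes: dict[str, np.ndarray] = {}
    for m in MODALITIES:
        v = crop_depth(np.asarray(volumes[m]), config.depth_range)
        v = apply_roi(v, box)
        v = resize_inplane(v, config.target_inplane, is_label=False)
        if config.normalize:
            v = normalize_intensity(v, foreground_threshold=config.foreground_threshold)
        out_volumes[m] = v

    out_mask = None
    if labels is not None:
        mk = crop_depth(np.asarray(labels), config.depth_range)
        mk = apply_roi(mk, box)
        mk = resize_inplane(mk, config.target_inplane, is_label=True)
        out_mask = remap_labels(mk).data

    return PreprocessedSubject(
        subject_id=sid, volumes=out_volumes, mask=out_mask, roi_box=box, config=config
    )


class RoiPreprocessor:
    """Transformer-style wrapper over :func:`preprocess_subject`.

    ``transform`` maps a list of subjects to a list of
    :class:`PreprocessedSubject`; ``fit`` only validates the config
    (the pipeline is stateless), mirroring the scikit-learn transformer
    protocol so the stage composes with sklearn pipelines.
    """

    def __init__(self, config: PreprocessConfig = PreprocessConfig()):
        self.config = config

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **params) -> "RoiPreprocessor":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValidationError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "RoiPreprocessor":
        _ = self.config.target_depth  # touches validation
        self.n_features_in_ = len(MODALITIES)
        return self

    def transform(self, X) -> list[PreprocessedSubject]:
        return [preprocess_subject(s, self.config) for s in X]

    def fit_transform(self, X, y=None) -> list[PreprocessedSubject]:
        return self.fit(X, y).transform(X)
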