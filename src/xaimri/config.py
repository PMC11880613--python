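"""Run configuration schema with strict key validation and seed fan-out.

A :class:`RunConfig` nests one section per pipeline stage; each stage
consumes only its own section.  Unknown keys are rejected on load so a
typo never silently falls back to a default.  One global seed fans out
to stage-specific derived seeds (stable CRC hash of the stage name and
the global seed) so every stage is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["RunConfig", "derive_seed", "PhantomSection", "PreprocessSection",
           "ModelSection", "TrainingSection", "EnsembleSection", "GradCamSection"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) % (2**31)


def _from_dict(cls, data: dict):
    if data is None:
        return cls()
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown key(s) {sorted(unknown)} in section {cls.__name__}; "
                              f"allowed: {sorted(known)}")
    coerced = {}
    for f in fields(cls):
        if f.name in data:
            v = data[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


@dataclass(frozen=True)
class PhantomSection:
    n_subjects: int = 8
    grid_shape: tuple[int, int, int] = (48, 48, 40)
    n_tumors: int = 1
    noise_sigma: float = 0.05


@dataclass(frozen=True)
class PreprocessSection:
    cube: int = 32


@dataclass(frozen=True)
class ModelSection:
    depth_levels: int = 2
    base_filters: int = 4
    dropout_rate: float = 0.1


@dataclass(frozen=True)
class TrainingSection:
    batch_size: int = 2
    max_epochs: int = 40
    learning_rate: float = 3e-3
    patience: int = 10
    loss: str = "weighted_cross_entropy"


@dataclass(frozen=True)
class EnsembleSection:
    fusion_filters: int = 16
    freeze_base: bool = True


@dataclass(frozen=True)
class GradCamSection:
    target_class: int = 3
    slice_index: int | None = None
    alpha: float = 0.4
    colormap: str = "jet"


_SECTIONS = {
    "phantom": PhantomSection,
    "preprocess": PreprocessSection,
    "model": ModelSection,
    "training": TrainingSection,
    "ensemble": EnsembleSection,
    "gradcam": GradCamSection,
}


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration: one section per stage plus globals."""

    seed: int = 0
    out_dir: str = "runs/run-000"
    phantom: PhantomSection = field(default_factory=PhantomSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    model: ModelSection = field(default_factory=ModelSection)
    training: TrainingSection = field(default_factory=TrainingSection)
    ensemble: EnsembleSection = field(default_factory=EnsembleSection)
    gradcam: GradCamSection = field(default_factory=GradCamSection)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        sections = {}
        for name, section_cls in _SECTIONS.items():
            sections[name] = _from_dict(section_cls, data.pop(name, None))
        unknown = set(data) - {"seed", "out_dir"}
        if unknown:
            raise ValidationError(f"unknown top-level key(s) {sorted(unknown)}; "
                                  f"allowed: {sorted(_SECTIONS) + ['seed', 'out_dir']}")
        return cls(seed=int(data.get("seed", 0)),
                   out_dir=str(data.get("out_dir", "runs/run-000")), **sections)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)
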