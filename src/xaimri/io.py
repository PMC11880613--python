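"""BraTS-layout dataset I/O: discovery, NIfTI loading, label remapping,
and the subject-level train/validation/test split.

The on-disk convention is one directory per subject holding
``<id>_{t1,t1ce,t2,flair}.nii[.gz]`` and optionally ``<id>_seg.nii[.gz]``.
Raw ground-truth labels use the BraTS dialect {0, 1, 2, 4}; models need
contiguous class indices for a softmax head, so :func:`remap_labels`
applies the bijection 0→0, 1→1, 2→2, 4→3 and records the inverse so
predictions can be exported back in the raw dialect.

Splitting is always at subject level (never slice level) to prevent
leakage between partitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ValidationError
from .phantom import MODALITIES

__all__ = [
    "RAW_TO_CLASS",
    "CLASS_TO_RAW",
    "SubjectRecord",
    "Volume",
    "DatasetSplit",
    "discover_subjects",
    "load_volume",
    "load_subject_arrays",
    "remap_labels",
    "unmap_labels",
    "split_dataset",
]

#: bijective raw-dialect → contiguous-class mapping (and back)
RAW_TO_CLASS = {0: 0, 1: 1, 2: 2, 4: 3}
CLASS_TO_RAW = {v: k for k, v in RAW_TO_CLASS.items()}

_NIFTI_EXTS = (".nii", ".nii.gz")
_SUFFIX_TO_MODALITY = {"t1": "T1", "t1ce": "T1ce", "t2": "T2", "flair": "FLAIR"}


@dataclass(frozen=True)
class SubjectRecord:
    """Resolved file paths of one subject's modalities and segmentation."""

    subject_id: str
    modality_paths: dict[str, Path]  # {T1, T1ce, T2, FLAIR} -> path
    seg_path: Path | None = None

    @property
    def is_labeled(self) -> bool:
        return self.seg_path is not None


@dataclass
class Volume:
    """A 3D array with its spatial affine and a role tag.

    ``role`` is ``"intensity"`` or ``"label"``; label volumes carry
    integer data and must never pass through interpolating resampling.
    ``meta`` holds provenance such as the label inverse map.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    role: str = "intensity"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"Volume must be 3D, got ndim={self.data.ndim}")
        if self.role not in ("intensity", "label"):
            raise ValidationError(f"role must be 'intensity' or 'label', got {self.role!r}")
        if self.role == "label" and not np.issubdtype(self.data.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.data, 1), 0)):
                raise ValidationError("label volume contains non-integer values")
            self.data = self.data.astype(np.int16)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.data.shape)


def _find_file(sub_dir: Path, subject_id: str, suffix: str) -> Path | None:
    for ext in _NIFTI_EXTS:
        p = sub_dir / f"{subject_id}_{suffix}{ext}"
        if p.exists():
            return p
    return None


def discover_subjects(root: str | Path, *, strict: bool = False) -> list[SubjectRecord]:
    """Scan a BraTS-layout directory tree for complete subjects.

    A subject directory must contain all four modality files to be
    included; the segmentation file is optional (unlabeled subjects).
    With ``strict=True`` an incomplete subject raises instead of being
    skipped.  Records are returned sorted by subject id.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    records: list[SubjectRecord] = []
    for sub_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        sid = sub_dir.name
        paths: dict[str, Path] = {}
        missing: list[str] = []
        for suffix, modality in _SUFFIX_TO_MODALITY.items():
            p = _find_file(sub_dir, sid, suffix)
            if p is None:
                missing.append(suffix)
            else:
                paths[modality] = p
        if missing:
            if strict:
                raise ValidationError(
                    f"subject {sid!r} is missing modality file(s): {', '.join(missing)}"
                )
            continue
        records.append(
            SubjectRecord(subject_id=sid, modality_paths=paths, seg_path=_find_file(sub_dir, sid, "seg"))
        )
    return records


def load_volume(path: str | Path, *, as_label: bool = False) -> Volume:
    """Load a 3D NIfTI file as a :class:`Volume`.

    ``as_label=True`` forces integer dtype (validating that the stored
    values are whole numbers) and tags the volume so downstream
    resampling uses nearest-neighbor only.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"{path} has {data.ndim} dimensions; only 3D volumes are supported")
    if as_label:
        return Volume(data=data, affine=np.asarray(img.affine), role="label")
    return Volume(data=data.astype(np.float32), affine=np.asarray(img.affine), role="intensity")


def load_subject_arrays(record: SubjectRecord) -> tuple[dict[str, np.ndarray], np.ndarray | None]:
    """Convenience loader: modality arrays by name plus labels (or None)."""
    volumes = {m: load_volume(record.modality_paths[m]).data for m in MODALITIES}
    labels = load_volume(record.seg_path, as_label=True).data if record.is_labeled else None
    return volumes, labels


def remap_labels(labels: Volume | np.ndarray) -> Volume:
    """Remap raw BraTS labels {0,1,2,4} to contiguous classes {0,1,2,3}.

    The inverse map is stored in ``meta["label_inverse_map"]`` so the
    relabeling can be undone exactly with :func:`unmap_labels`.
    """
    vol = labels if isinstance(labels, Volume) else Volume(data=labels, role="label")
    data = vol.data
    present = set(np.unique(data).tolist())
    unexpected = sorted(present - set(RAW_TO_CLASS))
    if unexpected:
        raise ValidationError(f"unexpected raw label value(s) {unexpected}; allowed: {sorted(RAW_TO_CLASS)}")
    lut = np.zeros(max(RAW_TO_CLASS) + 1, dtype=data.dtype)
    for raw, cls in RAW_TO_CLASS.items():
        lut[raw] = cls
    out = lut[data]
    meta = dict(vol.meta)
    meta["label_inverse_map"] = dict(CLASS_TO_RAW)
    return Volume(data=out, affine=vol.affine.copy(), role="label", meta=meta)


def unmap_labels(labels: Volume | np.ndarray) -> Volume:
    """Inverse of :func:`remap_labels`: contiguous {0,1,2,3} → raw {0,1,2,4}."""
    vol = labels if isinstance(labels, Volume) else Volume(data=labels, role="label")
    data = vol.data
    present = set(np.unique(data).tolist())
    unexpected = sorted(present - set(CLASS_TO_RAW))
    if unexpected:
        raise ValidationError(f"unexpected class index value(s) {unexpected}; allowed: {sorted(CLASS_TO_RAW)}")
    lut = np.zeros(max(CLASS_TO_RAW) + 1, dtype=data.dtype)
    for cls, raw in CLASS_TO_RAW.items():
        lut[cls] = raw
    return Volume(data=lut[data], affine=vol.affine.copy(), role="label", meta=dict(vol.meta))


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint subject-id partition into train/validation/test."""

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fractions: tuple[float, float, float]
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "train_ids": list(self.train_ids),
            "val_ids": list(self.val_ids),
            "test_ids": list(self.test_ids),
            "fractions": list(self.fractions),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetSplit":
        payload = json.loads(Path(path).read_text())
        return cls(
            train_ids=tuple(payload["train_ids"]),
            val_ids=tuple(payload["val_ids"]),
            test_ids=tuple(payload["test_ids"]),
            fractions=tuple(payload["fractions"]),
            seed=int(payload["seed"]),
        )


def split_dataset(
    ids: list[str],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> DatasetSplit:
    """Seeded subject-level 70/15/15 split.

    Sizes are ``floor(n·f_train)`` and ``floor(n·f_val)`` with the
    remainder assigned to test, so the three parts always partition the
    input exactly.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValidationError("subject ids must be unique")
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValidationError(f"need three positive fractions, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(f"fractions must sum to 1 (got sum={sum(fractions)!r})")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(ids)))
    shuffled = [ids[i] for i in order]
    n = len(ids)
    n_train = int(np.floor(n * fractions[0]))
    n_val = int(np.floor(n * fractions[1]))
    return DatasetSplit(
        train_ids=tuple(shuffled[:n_train]),
        val_ids=tuple(shuffled[n_train : n_train + n_val]),
        test_ids=tuple(shuffled[n_train + n_val :]),
        fractions=tuple(fractions),
        seed=int(seed),
    )
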