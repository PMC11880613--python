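"""Seeded multimodal 3D phantom subjects with BraTS-like geometry.

Each phantom is an ellipsoidal "brain" centered in the voxel grid,
containing zero or more nested spheroid tumors: an outer peritumoral
edema shell enclosing a tumor core enclosing an enhancing rim — the
whole-tumor / tumor-core / enhancing-tumor (WT ⊇ TC ⊇ ET) nesting used
for glioma annotation.  Labels follow the raw BraTS dialect
{0 background, 1 core, 2 edema, 4 enhancing}; label 3 is never emitted.

Four modality volumes (T1, T1ce, T2, FLAIR) are rendered from a
tissue-class × modality contrast table plus additive Gaussian noise.
The default table encodes the clinical contrast structure: T2 and FLAIR
make the edema bright, T1ce makes the enhancing rim bright, T1 shows
little tumor contrast.  No single modality separates all three tumor
classes from brain under the default table — by design, so that
multi-modality fusion is genuinely informative downstream.

Intensities are arbitrary units; no MRI physics (bias fields, partial
volume) is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import PlacementError, ValidationError

__all__ = [
    "MODALITIES",
    "TISSUE_CLASSES",
    "RAW_LABELS",
    "DEFAULT_CONTRAST_TABLE",
    "PhantomSpec",
    "SyntheticSubject",
    "generate_subject",
    "generate_cohort",
    "write_brats_layout",
]

MODALITIES = ("T1", "T1ce", "T2", "FLAIR")
TISSUE_CLASSES = ("background", "brain", "edema", "core", "enhancing")

#: raw BraTS-dialect label carried by each tissue class
RAW_LABELS = {"background": 0, "brain": 0, "edema": 2, "core": 1, "enhancing": 4}

#: mean intensity (arbitrary units) per tissue class and modality.
#: Designed contrasts: T2/FLAIR separate edema from brain but not core
#: from enhancing; T1ce separates enhancing (and core, weakly) but barely
#: edema from brain; T1 has almost no tumor contrast.
DEFAULT_CONTRAST_TABLE: dict[str, dict[str, float]] = {
    "background": {"T1": 0.0, "T1ce": 0.0, "T2": 0.0, "FLAIR": 0.0},
    "brain": {"T1": 0.50, "T1ce": 0.40, "T2": 0.30, "FLAIR": 0.35},
    "edema": {"T1": 0.45, "T1ce": 0.44, "T2": 0.80, "FLAIR": 0.85},
    "core": {"T1": 0.45, "T1ce": 0.52, "T2": 0.55, "FLAIR": 0.50},
    "enhancing": {"T1": 0.45, "T1ce": 0.90, "T2": 0.55, "FLAIR": 0.50},
}

_MAX_PLACEMENT_RETRIES = 200


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise parameters of one phantom subject.

    Parameters
    ----------
    grid_shape
        Voxel grid ``(nx, ny, nz)``; the default matches the 240×240
        axial plane with 155 slices of the BraTS acquisitions.
    brain_semiaxes_frac
        Ellipsoid semi-axes as fractions of the grid half-extent per axis.
    n_tumors
        Number of nested spheroid tumors to place (may be 0).
    tumor_radius_frac_range
        Whole-tumor radius range as a fraction of the smallest brain
        semi-axis.
    core_radius_frac, enhancing_radius_frac
        Core and enhancing radii as fractions of the whole-tumor radius
        (must satisfy 0 < enhancing < core < 1 so the nesting is strict).
    contrast_table
        ``{tissue class: {modality: mean intensity}}``; must cover all
        five tissue classes and four modalities.
    noise_sigma
        Std of additive Gaussian noise (intensities clipped at 0).
    seed
        RNG seed; identical spec+seed reproduce the subject bit-for-bit.
    """

    grid_shape: tuple[int, int, int] = (240, 240, 155)
    brain_semiaxes_frac: tuple[float, float, float] = (0.80, 0.85, 0.80)
    n_tumors: int = 1
    tumor_radius_frac_range: tuple[float, float] = (0.30, 0.50)
    core_radius_frac: float = 0.65
    enhancing_radius_frac: float = 0.45
    contrast_table: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CONTRAST_TABLE.items()}
    )
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 4 for n in self.grid_shape):
            raise ValidationError(f"grid_shape must be 3 dims each >= 4, got {self.grid_shape}")
        for frac in self.brain_semiaxes_frac:
            if not 0 < frac <= 1:
                raise ValidationError(f"brain_semiaxes_frac entries must be in (0,1], got {self.brain_semiaxes_frac}")
        if self.n_tumors < 0:
            raise ValidationError(f"n_tumors must be >= 0, got {self.n_tumors}")
        lo, hi = self.tumor_radius_frac_range
        if not (0 < lo <= hi <= 1):
            raise ValidationError(f"tumor_radius_frac_range must satisfy 0 < min <= max <= 1, got {self.tumor_radius_frac_range}")
        if not (0 < self.enhancing_radius_frac < self.core_radius_frac < 1):
            raise ValidationError(
                "need 0 < enhancing_radius_frac < core_radius_frac < 1, got "
                f"enhancing={self.enhancing_radius_frac}, core={self.core_radius_frac}"
            )
        if self.noise_sigma < 0:
            raise ValidationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        missing = [
            (cls, mod)
            for cls in TISSUE_CLASSES
            for mod in MODALITIES
            if cls not in self.contrast_table or mod not in self.contrast_table[cls]
        ]
        if missing:
            raise ValidationError(f"contrast_table missing entries: {missing}")

    def with_seed(self, seed: int) -> "PhantomSpec":
        return replace(self, seed=seed)


@dataclass
class SyntheticSubject:
    """One phantom patient: four modality volumes plus a label volume."""

    subject_id: str
    volumes: dict[str, np.ndarray]  # modality -> float32 grid
    labels: np.ndarray  # int16 grid, raw BraTS dialect {0,1,2,4}
    spec: PhantomSpec

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def generate_subject(spec: PhantomSpec, subject_id: str = "phantom-000") -> SyntheticSubject:
    """Render one phantom subject deterministically from ``spec.seed``.

    The tissue-class map is built first (brain ellipsoid, then each
    tumor's edema/core/enhancing spheres painted innermost-last), then
    each modality volume is drawn as contrast mean + N(0, noise_sigma),
    clipped at zero.

    Raises
    ------
    PlacementError
        If a sampled tumor cannot be fitted inside the brain within a
        bounded number of retries.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(n) for n in spec.grid_shape)
    center = np.array([(n - 1) / 2.0 for n in shape])
    semiaxes = np.array([f * (n / 2.0) for f, n in zip(spec.brain_semiaxes_frac, shape)])

    # class index per voxel: 0 bg, 1 brain, 2 edema, 3 core, 4 enhancing
    tissue = np.zeros(shape, dtype=np.int8)
    tissue[_ellipsoid_mask(shape, center, semiaxes)] = 1

    min_semiaxis = float(semiaxes.min())
    for _ in range(spec.n_tumors):
        lo, hi = spec.tumor_radius_frac_range
        placed = False
        for _attempt in range(_MAX_PLACEMENT_RETRIES):
            r_wt = rng.uniform(lo, hi) * min_semiaxis
            # sample a center uniformly in the bounding box of the brain
            offset = rng.uniform(-1, 1, size=3) * (semiaxes - r_wt).clip(min=0.0)
            c = center + offset
            # tumor sphere must sit fully inside the ellipsoid:
            # shrink each semiaxis by r_wt and test the center
            inner = semiaxes - r_wt
            if np.any(inner <= 0):
                continue
            if np.sum(((c - center) / inner) ** 2) <= 1.0:
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place a tumor of radius range {spec.tumor_radius_frac_range} "
                f"inside brain semiaxes {semiaxes.tolist()} after {_MAX_PLACEMENT_RETRIES} retries"
            )
        r_core = spec.core_radius_frac * r_wt
        r_enh = spec.enhancing_radius_frac * r_wt
        tissue[_ellipsoid_mask(shape, c, (r_wt,) * 3)] = 2  # edema (whole tumor)
        tissue[_ellipsoid_mask(shape, c, (r_core,) * 3)] = 3  # core
        tissue[_ellipsoid_mask(shape, c, (r_enh,) * 3)] = 4  # enhancing

    raw = np.array([RAW_LABELS[c] for c in TISSUE_CLASSES], dtype=np.int16)
    labels = raw[tissue]

    volumes: dict[str, np.ndarray] = {}
    for mod in MODALITIES:
        means = np.array([spec.contrast_table[c][mod] for c in TISSUE_CLASSES], dtype=np.float32)
        img = means[tissue]
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=shape).astype(np.float32)
        volumes[mod] = np.clip(img, 0.0, None).astype(np.float32)

    return SyntheticSubject(subject_id=subject_id, volumes=volumes, labels=labels, spec=spec)


def generate_cohort(spec: PhantomSpec, n_subjects: int, *, id_prefix: str = "phantom") -> list[SyntheticSubject]:
    """Generate ``n_subjects`` phantoms with per-subject derived seeds."""
    subjects = []
    for i in range(n_subjects):
        sub_spec = spec.with_seed(int(spec.seed) + i)
        subjects.append(generate_subject(sub_spec, subject_id=f"{id_prefix}-{i:03d}"))
    return subjects


_SUFFIXES = {"T1": "t1", "T1ce": "t1ce", "T2": "t2", "FLAIR": "flair"}


def write_brats_layout(
    subject: SyntheticSubject,
    root: str | Path,
    *,
    affine: np.ndarray | None = None,
) -> list[Path]:
    """Write a subject as five compressed NIfTI files in BraTS layout.

    Files land in ``root/<subject_id>/<subject_id>_<suffix>.nii.gz``
    with suffixes t1, t1ce, t2, flair, seg and an identity affine
    unless one is given.  Returns the created paths (modalities in
    canonical order, then seg).
    """
    root = Path(root)
    sub_dir = root / subject.subject_id
    sub_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    paths: list[Path] = []
    for mod in MODALITIES:
        p = sub_dir / f"{subject.subject_id}_{_SUFFIXES[mod]}.nii.gz"
        nib.save(nib.Nifti1Image(subject.volumes[mod].astype(np.float32), affine), str(p))
        paths.append(p)
    seg_path = sub_dir / f"{subject.subject_id}_seg.nii.gz"
    nib.save(nib.Nifti1Image(subject.labels.astype(np.int16), affine), str(seg_path))
    paths.append(seg_path)
    return paths
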