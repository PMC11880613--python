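"""Segmentation evaluation metrics over multi-class voxel label volumes.

Six scalar metrics are reported for a prediction/ground-truth pair:
accuracy, mean IoU, Dice similarity coefficient, precision, sensitivity
(recall) and specificity.  Aggregation conventions are explicit because
they change the numbers substantially on class-imbalanced volumes:

* ``accuracy``, ``precision``, ``sensitivity``, ``specificity`` — micro
  aggregation: one-vs-rest confusion counts are summed over classes
  before the ratio is taken.
* ``mean_iou`` — macro aggregation: per-class IoU averaged over all
  classes.  A class absent from both volumes has an empty union; by
  convention it contributes IoU 1 (perfect agreement on "nothing"),
  which is flagged in the report metadata and can be skipped instead.
* ``dice_coef`` — global (soft) Dice over the flattened one-hot
  encoding of all classes including background,
  ``2·Σ(p·t) / (Σp + Σt)``.  With hard labels this is background
  dominated and sits near the voxel accuracy; per-class Dice on the
  foreground sets is available via ``mode="per_class"``.

Zero denominators are never silently coerced to 0: the affected metric
is returned as ``nan`` and listed in ``MetricsReport.undefined``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "accuracy",
    "mean_iou",
    "per_class_iou",
    "dice_coefficient",
    "precision",
    "sensitivity",
    "specificity",
    "metrics_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class one-vs-rest confusion tallies plus micro sums.

    For each class ``c`` the four counts partition the voxel grid:
    ``tp[c] + fp[c] + fn[c] + tn[c] == n_voxels``.
    """

    tp: np.ndarray  # (n_classes,) int64
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    n_voxels: int

    @property
    def n_classes(self) -> int:
        return self.tp.shape[0]

    # micro sums over classes
    @property
    def micro_tp(self) -> int:
        return int(self.tp.sum())

    @property
    def micro_fp(self) -> int:
        return int(self.fp.sum())

    @property
    def micro_fn(self) -> int:
        return int(self.fn.sum())

    @property
    def micro_tn(self) -> int:
        return int(self.tn.sum())


def _validate_pair(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"pred shape {pred.shape} != truth shape {truth.shape}")
    if n_classes < 2:
        raise ValueError(f"n_classes must be >= 2, got {n_classes}")
    for name, arr in (("pred", pred), ("truth", truth)):
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError(f"{name} contains non-integer label values")
            arr = arr.astype(np.int64)
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            bad = np.unique(arr[(arr < 0) | (arr >= n_classes)])
            raise ValueError(f"{name} contains out-of-range labels {bad.tolist()} for n_classes={n_classes}")
        if name == "pred":
            pred = arr
        else:
            truth = arr
    return pred.astype(np.int64), truth.astype(np.int64)


def confusion_counts(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> ConfusionCounts:
    """Exact integer one-vs-rest confusion counts for each class.

    Parameters
    ----------
    pred, truth
        Integer label arrays of identical shape with values in
        ``[0, n_classes)``.
    """
    pred, truth = _validate_pair(pred, truth, n_classes)
    n = pred.size
    # joint histogram: cm[i, j] = #voxels with truth i predicted j
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (truth.ravel(), pred.ravel()), 1)
    tp = np.diag(cm).copy()
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = n - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, n_voxels=n)


def _ratio(num: float, den: float) -> float:
    """num/den with an explicit NaN marker on a zero denominator."""
    if den == 0:
        return float("nan")
    return num / den


def accuracy(counts: ConfusionCounts) -> float:
    """Fraction of correctly labeled voxels, ``Σ_c TP_c / n_voxels``.

    In the binary one-vs-rest reading this is exactly
    ``(TP+TN) / (TP+TN+FP+FN)``: the background class's true positives
    are the foreground class's true negatives.  (Summing TP and TN over
    *all* one-vs-rest problems instead would double-count agreements
    and inflate the value.)
    """
    if counts.n_voxels == 0:
        raise ValueError("accuracy undefined on an empty volume")
    return _ratio(int(counts.tp.sum()), counts.n_voxels)


def per_class_iou(
    pred: np.ndarray,
    truth: np.ndarray,
    n_classes: int,
    *,
    empty_union_value: float = 1.0,
) -> tuple[np.ndarray, list[int]]:
    """Per-class Jaccard index |A∩B| / |A∪B|.

    Returns the per-class IoU vector and the list of class indices whose
    union was empty (those received ``empty_union_value``).
    """
    counts = confusion_counts(pred, truth, n_classes)
    union = counts.tp + counts.fp + counts.fn
    iou = np.empty(n_classes, dtype=float)
    empty: list[int] = []
    for c in range(n_classes):
        if union[c] == 0:
            iou[c] = empty_union_value
            empty.append(c)
        else:
            iou[c] = counts.tp[c] / union[c]
    return iou, empty


def mean_iou(
    pred: np.ndarray,
    truth: np.ndarray,
    n_classes: int,
    *,
    empty_union: str = "one",
) -> float:
    """Macro-averaged IoU over all classes.

    ``empty_union``: ``"one"`` counts classes absent from both volumes
    as IoU 1; ``"skip"`` drops them from the average.
    """
    if empty_union not in ("one", "skip"):
        raise ValueError("empty_union must be 'one' or 'skip'")
    iou, empty = per_class_iou(pred, truth, n_classes)
    if empty_union == "skip":
        keep = [c for c in range(n_classes) if c not in empty]
        if not keep:
            return float("nan")
        return float(iou[keep].mean())
    return float(iou.mean())


def dice_coefficient(
    pred: np.ndarray,
    truth: np.ndarray,
    n_classes: int,
    *,
    mode: str = "global",
) -> float | np.ndarray:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    mode="global" (default): flatten the one-hot encodings of all
    classes and voxels into single vectors and compute one soft Dice,
    ``2·Σ(p·t)/(Σp+Σt)``.  ``pred`` may be hard labels or a
    probability volume of shape ``(n_classes, ...)``.

    mode="per_class": hard-label Dice per class on the voxel sets of
    each class; returns an array of length ``n_classes`` (NaN where
    both sets are empty).
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if mode == "global":
        if pred.ndim == truth.ndim + 1:  # probability volume (n_classes, ...)
            if pred.shape[0] != n_classes or pred.shape[1:] != truth.shape:
                raise ValueError(
                    f"probability volume shape {pred.shape} incompatible with "
                    f"truth {truth.shape} and n_classes={n_classes}"
                )
            p = pred.reshape(n_classes, -1).T.astype(float)
            _, t_lab = _validate_pair(np.zeros_like(truth, dtype=np.int64), truth, n_classes)
        else:
            p_lab, t_lab = _validate_pair(pred, truth, n_classes)
            p = np.eye(n_classes)[p_lab.ravel()]
        t = np.eye(n_classes)[t_lab.ravel()]
        num = 2.0 * float((p * t).sum())
        den = float(p.sum() + t.sum())
        return _ratio(num, den)
    if mode == "per_class":
        counts = confusion_counts(pred, truth, n_classes)
        out = np.empty(n_classes, dtype=float)
        for c in range(n_classes):
            den = 2 * counts.tp[c] + counts.fp[c] + counts.fn[c]
            out[c] = _ratio(2.0 * counts.tp[c], float(den))
        return out
    raise ValueError("mode must be 'global' or 'per_class'")


def precision(counts: ConfusionCounts) -> float:
    """TP / (TP+FP) on micro counts; NaN when nothing is predicted positive."""
    return _ratio(counts.micro_tp, counts.micro_tp + counts.micro_fp)


def sensitivity(counts: ConfusionCounts) -> float:
    """TP / (TP+FN) on micro counts (recall)."""
    return _ratio(counts.micro_tp, counts.micro_tp + counts.micro_fn)


def specificity(counts: ConfusionCounts) -> float:
    """TN / (TN+FP) on micro counts."""
    return _ratio(counts.micro_tn, counts.micro_tn + counts.micro_fp)


@dataclass
class MetricsReport:
    """The six scalar metrics for one prediction/truth pair.

    ``aggregation`` records the convention behind each headline number
    so reports from different settings are never silently compared.
    """

    accuracy: float
    mean_iou: float
    dice_coef: float
    precision: float
    sensitivity: float
    specificity: float
    per_class_iou: list[float] = field(default_factory=list)
    n_classes: int = 0
    n_voxels: int = 0
    empty_union_classes: list[int] = field(default_factory=list)
    undefined: list[str] = field(default_factory=list)
    aggregation: dict = field(
        default_factory=lambda: {
            "accuracy": "micro",
            "mean_iou": "macro",
            "dice_coef": "global_onehot",
            "precision": "micro",
            "sensitivity": "micro",
            "specificity": "micro",
        }
    )

    METRIC_NAMES = (
        "accuracy",
        "mean_iou",
        "dice_coef",
        "precision",
        "sensitivity",
        "specificity",
    )

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in self.METRIC_NAMES}
        d["per_class_iou"] = list(self.per_class_iou)
        d["n_classes"] = self.n_classes
        d["n_voxels"] = self.n_voxels
        d["empty_union_classes"] = list(self.empty_union_classes)
        d["undefined"] = list(self.undefined)
        d["aggregation"] = dict(self.aggregation)
        return d

    def to_json(self, path=None, **kwargs) -> str:
        payload = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def metrics_report(
    pred: np.ndarray,
    truth: np.ndarray,
    n_classes: int,
    *,
    empty_union: str = "one",
) -> MetricsReport:
    """Compute all six metrics plus per-class IoU for one pair.

    ``pred`` must be hard labels here; soft Dice on probability volumes
    is available directly via :func:`dice_coefficient`.
    """
    counts = confusion_counts(pred, truth, n_classes)
    iou_vec, empty = per_class_iou(pred, truth, n_classes)
    report = MetricsReport(
        accuracy=accuracy(counts),
        mean_iou=mean_iou(pred, truth, n_classes, empty_union=empty_union),
        dice_coef=float(dice_coefficient(pred, truth, n_classes, mode="global")),
        precision=precision(counts),
        sensitivity=sensitivity(counts),
        specificity=specificity(counts),
        per_class_iou=[float(v) for v in iou_vec],
        n_classes=n_classes,
        n_voxels=counts.n_voxels,
        empty_union_classes=empty,
    )
    report.undefined = [
        name for name in MetricsReport.METRIC_NAMES if np.isnan(getattr(report, name))
    ]
    return report
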