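"""Segmentation-quality evaluation for five-class tissue maps.

Metrics follow the standard pixelwise definitions: per-class accuracy is the
row-normalized recall (correct pixels over all ground-truth pixels of the
class), IoU is the Jaccard index, DSC is the Dice coefficient
2·TP/(2·TP+FP+FN), and boundary-F1 scores how well class boundaries align
within a distance tolerance.  DSC and IoU are algebraically linked:
DSC = 2·IoU/(1+IoU).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from fibroquant._constants import CLASS_NAMES, N_CLASSES
from fibroquant.ct_io import LabelMap

__all__ = [
    "ConfusionMatrix",
    "accumulate_confusion",
    "class_accuracy",
    "class_iou",
    "class_dsc",
    "boundary_f1",
    "mean_boundary_f1",
    "score_table",
]


class UndefinedClassError(ZeroDivisionError):
    """The metric's denominator is zero for the requested class."""


@dataclass
class ConfusionMatrix:
    """5×5 actual-by-predicted pixel counts (rows = actual)."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"confusion matrix must be {N_CLASSES}x{N_CLASSES}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


def accumulate_confusion(
    truth: LabelMap | np.ndarray,
    pred: LabelMap | np.ndarray,
    acc: ConfusionMatrix | None = None,
) -> ConfusionMatrix:
    """Add one (truth, prediction) pair of label maps into a confusion matrix."""
    t = truth.labels if isinstance(truth, LabelMap) else np.asarray(truth)
    p = pred.labels if isinstance(pred, LabelMap) else np.asarray(pred)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: truth {t.shape} vs prediction {p.shape}")
    inc = np.bincount(
        (t.ravel().astype(np.int64) * N_CLASSES + p.ravel()), minlength=N_CLASSES**2
    ).reshape(N_CLASSES, N_CLASSES)
    base = acc.counts if acc is not None else 0
    return ConfusionMatrix(base + inc)


def class_accuracy(cm: ConfusionMatrix, cls: int) -> float:
    """Recall of one class: diagonal over the actual-class row sum."""
    row = cm.counts[cls].sum()
    if row == 0:
        raise UndefinedClassError(f"class {cls} absent from ground truth")
    return float(cm.counts[cls, cls] / row)


def class_iou(cm: ConfusionMatrix, cls: int) -> float:
    """Jaccard index: TP over (row sum + column sum − TP)."""
    tp = cm.counts[cls, cls]
    union = cm.counts[cls].sum() + cm.counts[:, cls].sum() - tp
    if union == 0:
        raise UndefinedClassError(f"class {cls} absent from truth and prediction")
    return float(tp / union)


def class_dsc(cm: ConfusionMatrix, cls: int) -> float:
    """Dice similarity coefficient 2·TP/(2·TP+FP+FN)."""
    tp = cm.counts[cls, cls]
    fp = cm.counts[:, cls].sum() - tp
    fn = cm.counts[cls].sum() - tp
    denom = 2 * tp + fp + fn
    if denom == 0:
        raise UndefinedClassError(f"class {cls} absent from truth and prediction")
    return float(2 * tp / denom)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Inner boundary: mask pixels with at least one non-mask 4-neighbour
    (image border counts as outside)."""
    padded = np.pad(mask, 1, constant_values=False)
    eroded = ndimage.binary_erosion(padded, structure=ndimage.generate_binary_structure(2, 1))
    return mask & ~eroded[1:-1, 1:-1]


def default_bf_tolerance(shape: tuple[int, int]) -> int:
    """0.75% of the image diagonal, rounded to the nearest pixel (min 1)."""
    diag = float(np.hypot(*shape))
    return max(1, int(round(0.0075 * diag)))


def boundary_f1(
    truth: LabelMap | np.ndarray,
    pred: LabelMap | np.ndarray,
    cls: int,
    tolerance: float | None = None,
) -> float:
    """Boundary-F1 for one class on one image pair.

    Precision counts predicted boundary pixels with a true boundary pixel
    within ``tolerance`` (Euclidean); recall is symmetric.  Returns NaN when
    the class is absent from both maps (the pair is excluded from means).
    """
    t = truth.labels if isinstance(truth, LabelMap) else np.asarray(truth)
    p = pred.labels if isinstance(pred, LabelMap) else np.asarray(pred)
    if t.shape != p.shape:
        raise ValueError("shape mismatch between truth and prediction")
    if tolerance is None:
        tolerance = default_bf_tolerance(t.shape)

    bt = _boundary(t == cls)
    bp = _boundary(p == cls)
    if not bt.any() and not bp.any():
        return float("nan")
    if not bt.any() or not bp.any():
        return 0.0
    # distance from every pixel to the nearest boundary pixel of the other map
    dist_to_truth = ndimage.distance_transform_edt(~bt)
    dist_to_pred = ndimage.distance_transform_edt(~bp)
    precision = float((dist_to_truth[bp] <= tolerance).mean())
    recall = float((dist_to_pred[bt] <= tolerance).mean())
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def mean_boundary_f1(
    truths: list[LabelMap | np.ndarray],
    preds: list[LabelMap | np.ndarray],
    cls: int,
    tolerance: float | None = None,
) -> float:
    """MeanBFScore: boundary-F1 averaged over images where the class occurs."""
    scores = [boundary_f1(t, p, cls, tolerance) for t, p in zip(truths, preds, strict=True)]
    valid = [s for s in scores if not np.isnan(s)]
    if not valid:
        raise UndefinedClassError(f"class {cls} absent from every evaluated image")
    return float(np.mean(valid))


def score_table(cm: ConfusionMatrix) -> dict[str, dict[str, float]]:
    """Accuracy/IoU/DSC per class name from one confusion matrix."""
    out: dict[str, dict[str, float]] = {}
    for cls, name in enumerate(CLASS_NAMES):
        row: dict[str, float] = {}
        try:
            row["accuracy"] = class_accuracy(cm, cls)
            row["iou"] = class_iou(cm, cls)
            row["dsc"] = class_dsc(cm, cls)
        except UndefinedClassError:
            continue
        out[name] = row
    return out
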