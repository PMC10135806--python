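"""Confusion-matrix construction and segmentation metrics.

All metrics derive from a single 3x3 pixel-count confusion matrix with rows
= manual (true) class and columns = predicted class, in the fixed order
(background, fragment, intact).  Pooling pixel counts over every test image
before computing metrics is micro-averaging; the normalized form divides by
the total pixel count so entries sum to 1 and read as joint proportions.

Per class, with TP the diagonal entry, FN the rest of its row and FP the
rest of its column:

    Dice        = 2*TP / (2*TP + FP + FN)
    sensitivity = TP / (TP + FN)                 (true positive rate)
    specificity = TN / (TN + FP)                 (true negative rate)

Dice, sensitivity and specificity are invariant to global rescaling of the
matrix, so counts and normalized matrices give identical metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

CLASS_NAMES = ("background", "fragment", "intact")
BINARY_NAMES = ("background", "osteon")


@dataclass
class ConfusionMatrix:
    """Rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple[str, ...] = CLASS_NAMES
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} matrix, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        if self.normalized and abs(self.counts.sum() - 1.0) > 1e-9:
            raise ValueError("normalized matrix must sum to 1")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def normalize(self) -> "ConfusionMatrix":
        if self.total == 0:
            raise ValueError("cannot normalize an empty confusion matrix")
        return ConfusionMatrix(self.counts / self.total, self.labels, True)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))


def confusion_from_masks(true_masks, pred_masks,
                         n_classes: int = 3) -> ConfusionMatrix:
    """Pixel-count confusion matrix pooled over paired mask lists.

    Accepts single masks or equal-length sequences; each pair must have
    matching shape and values in {0, ..., n_classes-1}.
    """
    from .annotations import LabelMask

    def _grids(obj):
        if isinstance(obj, (LabelMask, np.ndarray)):
            obj = [obj]
        return [m.grid if isinstance(m, LabelMask) else np.asarray(m)
                for m in obj]

    t_list, p_list = _grids(true_masks), _grids(pred_masks)
    if len(t_list) != len(p_list):
        raise ValueError(
            f"unpaired mask lists: {len(t_list)} true vs {len(p_list)} predicted"
        )
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    for i, (t, p) in enumerate(zip(t_list, p_list)):
        if t.shape != p.shape:
            raise ValueError(f"pair {i}: shape mismatch {t.shape} vs {p.shape}")
        joint = np.bincount(
            (t.astype(np.int64) * n_classes + p.astype(np.int64)).ravel(),
            minlength=n_classes * n_classes,
        )
        counts += joint.reshape(n_classes, n_classes)
    return ConfusionMatrix(counts)


def _tp_fp_fn(cm: ConfusionMatrix, c: int) -> tuple[float, float, float]:
    tp = cm.counts[c, c]
    fn = cm.counts[c, :].sum() - tp
    fp = cm.counts[:, c].sum() - tp
    return float(tp), float(fp), float(fn)


def dice_per_class(cm: ConfusionMatrix) -> tuple[np.ndarray, float]:
    """Per-class Dice 2TP/(2TP+FP+FN) and their unweighted mean.

    A class absent from both truth and prediction has an undefined Dice,
    reported as NaN with a warning; the mean is taken over defined values.
    """
    k = len(cm.labels)
    dice = np.full(k, np.nan)
    for c in range(k):
        tp, fp, fn = _tp_fp_fn(cm, c)
        denom = 2 * tp + fp + fn
        if denom == 0:
            warnings.warn(
                f"Dice undefined for empty class {cm.labels[c]!r}", stacklevel=2
            )
            continue
        dice[c] = 2 * tp / denom
    mean = float(np.nanmean(dice)) if np.isfinite(dice).any() else float("nan")
    return dice, mean


def sensitivity_specificity(cm: ConfusionMatrix, class_index: int
                            ) -> tuple[float, float]:
    """(sensitivity, specificity) of one class against the rest."""
    tp, fp, fn = _tp_fp_fn(cm, class_index)
    tn = cm.total - tp - fp - fn
    sens = tp / (tp + fn) if tp + fn > 0 else float("nan")
    spec = tn / (tn + fp) if tn + fp > 0 else float("nan")
    if np.isnan(sens) or np.isnan(spec):
        warnings.warn(
            f"sensitivity/specificity undefined for class "
            f"{cm.labels[class_index]!r} (empty denominator)", stacklevel=2
        )
    return float(sens), float(spec)


def collapse_binary(cm: ConfusionMatrix) -> ConfusionMatrix:
    """Collapse fragment+intact into a single 'osteon' class.

    Total mass is conserved: the osteon/osteon cell sums the 2x2
    fragment-intact block, and the mixed cells sum correspondingly.
    """
    c = cm.counts
    if c.shape != (3, 3):
        raise ValueError("binary collapse expects a 3x3 matrix")
    collapsed = np.array([
        [c[0, 0], c[0, 1:].sum()],
        [c[1:, 0].sum(), c[1:, 1:].sum()],
    ])
    return ConfusionMatrix(collapsed, BINARY_NAMES, cm.normalized)


def class_proportions(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(true, predicted) per-class pixel proportions, in percent.

    Row sums give the manual-annotation class proportions; column sums give
    the automatically predicted ones.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    return (100.0 * cm.counts.sum(axis=1) / total,
            100.0 * cm.counts.sum(axis=0) / total)


@dataclass
class SegmentationMetrics:
    """The full metric bundle computed from one confusion matrix."""

    dice: tuple[float, float, float]
    mean_dice: float
    sensitivity: tuple[float, float, float]
    specificity: tuple[float, float, float]
    binary_dice: float
    binary_sensitivity: float
    binary_specificity: float
    true_proportions: tuple[float, float, float]      # percent
    predicted_proportions: tuple[float, float, float]  # percent
    labels: tuple[str, ...] = CLASS_NAMES

    def to_dict(self) -> dict:
        return asdict(self)

    def rounded(self) -> dict:
        """Reporting form: Dice to 2 decimals, rates/proportions to whole
        percent (raw values remain available on the object)."""
        r2 = lambda x: round(float(x), 2)
        pc = lambda x: round(100.0 * float(x))
        return {
            "dice": {n: r2(d) for n, d in zip(self.labels, self.dice)},
            "mean_dice": r2(self.mean_dice),
            "sensitivity_pct": {n: pc(s) for n, s in
                                zip(self.labels, self.sensitivity)},
            "specificity_pct": {n: pc(s) for n, s in
                                zip(self.labels, self.specificity)},
            "binary_dice": r2(self.binary_dice),
            "binary_sensitivity_pct": pc(self.binary_sensitivity),
            "binary_specificity_pct": pc(self.binary_specificity),
            "true_proportions_pct": {
                n: round(float(p), 1)
                for n, p in zip(self.labels, self.true_proportions)},
            "predicted_proportions_pct": {
                n: round(float(p))
                for n, p in zip(self.labels, self.predicted_proportions)},
        }


def segmentation_metrics(cm: ConfusionMatrix) -> SegmentationMetrics:
    """Compute every reported metric from a 3x3 confusion matrix."""
    dice, mean_dice = dice_per_class(cm)
    sens, spec = zip(*(sensitivity_specificity(cm, c) for c in range(3)))
    bcm = collapse_binary(cm)
    bdice, _ = dice_per_class(bcm)
    bsens, bspec = sensitivity_specificity(bcm, 1)
    tprop, pprop = class_proportions(cm)
    return SegmentationMetrics(
        dice=tuple(dice), mean_dice=mean_dice,
        sensitivity=tuple(sens), specificity=tuple(spec),
        binary_dice=float(bdice[1]),
        binary_sensitivity=bsens, binary_specificity=bspec,
        true_proportions=tuple(tprop), predicted_proportions=tuple(pprop),
    )
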