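"""ROC-based selection of hard thresholds for the prediction maps.

A continuous per-pixel score map becomes a binary segmentation by
thresholding.  The working point is picked per validation image as the
threshold whose (FPR, TPR) is closest, in Euclidean distance, to the
ideal corner (0, 1); the shipped per-class threshold is the median of the
per-image optima.  Reference values for real STED data (rings 0.25 /
fibers 0.4 for the dendritic network, 0.02 for the axonal one) ship as
fallbacks for users without their own validation images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RocCurve", "ThresholdCalibration", "roc_curve", "optimal_threshold",
    "calibrate", "DEFAULT_THRESHOLDS",
]

# reference medians for real STED data; shipped as fallbacks only
DEFAULT_THRESHOLDS = {
    "h_d": {"rings": 0.25, "fibers": 0.4},
    "h_a": {"rings": 0.02},
}


@dataclass
class RocCurve:
    thresholds: np.ndarray  # ascending
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass
class ThresholdCalibration:
    thresholds: dict[str, float]
    n_images: dict[str, int]


def _candidate_thresholds(pred: np.ndarray, grid: int | str) -> np.ndarray:
    if grid == "unique":
        return np.unique(pred)
    # deterministic curve size on large maps
    return np.linspace(0.0, 1.0, int(grid) + 2)[1:-1]


def roc_curve(
    pred: np.ndarray,
    truth: np.ndarray,
    region: np.ndarray | None = None,
    grid: int | str = 512,
) -> RocCurve:
    """FPR/TPR of ``pred >= t`` over a threshold grid (or all unique scores)."""
    pred = np.asarray(pred, dtype=np.float64).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    if region is not None:
        sel = np.asarray(region, dtype=bool).ravel()
        pred, truth = pred[sel], truth[sel]
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth needs at least one positive and one negative pixel")
    thresholds = _candidate_thresholds(pred, grid)
    # sort scores once; count positives/negatives above each threshold
    order = np.argsort(pred)
    sorted_pred = pred[order]
    cum_pos = np.concatenate([[0], np.cumsum(truth[order])])
    idx = np.searchsorted(sorted_pred, thresholds, side="left")
    pos_above = n_pos - cum_pos[idx]
    neg_above = (pred.size - idx) - pos_above
    return RocCurve(
        thresholds=thresholds,
        fpr=neg_above / n_neg,
        tpr=pos_above / n_pos,
    )


def optimal_threshold(roc: RocCurve) -> float:
    """Threshold closest to the ideal operating point (FPR=0, TPR=1).

    Ties are broken toward the larger threshold (the more conservative
    segmentation).
    """
    if len(roc.thresholds) == 0:
        raise ValueError("empty ROC curve")
    d = np.hypot(roc.fpr, 1.0 - roc.tpr)
    # scan from the largest threshold so ties resolve high
    best = len(d) - 1 - int(np.argmin(d[::-1]))
    return float(roc.thresholds[best])


def calibrate(
    preds_and_truths: dict[str, list[tuple[np.ndarray, np.ndarray]]],
    grid: int | str = 512,
    pooled: bool = False,
) -> ThresholdCalibration:
    """Median of the per-image optimal thresholds, per class.

    Images violating the ROC preconditions (single-class truth) are
    skipped with a warning.  ``pooled=True`` concatenates all pixels into
    one ROC curve per class instead (an exposed alternative reading of the
    procedure).
    """
    thresholds: dict[str, float] = {}
    n_images: dict[str, int] = {}
    for cls, pairs in preds_and_truths.items():
        if pooled:
            preds = np.concatenate([np.ravel(p) for p, _ in pairs])
            truths = np.concatenate([np.ravel(t) for _, t in pairs])
            thresholds[cls] = optimal_threshold(roc_curve(preds, truths, grid=grid))
            n_images[cls] = len(pairs)
            continue
        per_image = []
        for i, (pred, truth) in enumerate(pairs):
            try:
                per_image.append(optimal_threshold(roc_curve(pred, truth, grid=grid)))
            except ValueError as err:
                warnings.warn(f"class {cls!r}: skipping validation image {i}: {err}")
        if not per_image:
            raise ValueError(f"class {cls!r}: no usable validation image")
        thresholds[cls] = float(np.median(per_image))
        n_images[cls] = len(per_image)
    return ThresholdCalibration(thresholds=thresholds, n_images=n_images)
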