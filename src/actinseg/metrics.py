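"""Pixel-wise evaluation: confusion counts, F1-family metrics, PR curves, AP.

All metrics are strictly pixel-wise.  Ratios with a zero denominator
return NaN (an explicit undefined marker) rather than a silent zero, so
aggregation code must decide how to treat them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts", "PrCurve", "confusion", "f1", "sensitivity",
    "specificity", "precision", "pr_curve", "ap_of_fixed_segmentation",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    seg: np.ndarray,
    truth: np.ndarray,
    region: np.ndarray | None = None,
) -> ConfusionCounts:
    seg = np.asarray(seg, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if seg.shape != truth.shape:
        raise ValueError(f"shape mismatch: seg {seg.shape} vs truth {truth.shape}")
    if region is not None:
        sel = np.asarray(region, dtype=bool)
        if sel.shape != seg.shape:
            raise ValueError("region shape mismatch")
        seg, truth = seg[sel], truth[sel]
    tp = int(np.sum(seg & truth))
    fp = int(np.sum(seg & ~truth))
    fn = int(np.sum(~seg & truth))
    tn = int(np.sum(~seg & ~truth))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def f1(c: ConfusionCounts) -> float:
    """Overlap between segmentation and ground truth: 2TP / (FP + 2TP + FN)."""
    return _ratio(2.0 * c.tp, c.fp + 2.0 * c.tp + c.fn)


def sensitivity(c: ConfusionCounts) -> float:
    """Proportion of the ground truth recovered: TP / (TP + FN)."""
    return _ratio(c.tp, c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """Proportion of background kept as background: TN / (TN + FP)."""
    return _ratio(c.tn, c.tn + c.fp)


def precision(c: ConfusionCounts) -> float:
    """Proportion of true features among positive predictions: TP / (TP + FP)."""
    return _ratio(c.tp, c.tp + c.fp)


@dataclass
class PrCurve:
    thresholds: np.ndarray   # ascending
    precision: np.ndarray
    recall: np.ndarray
    ap: float


def pr_curve(
    pred: np.ndarray,
    truth: np.ndarray,
    region: np.ndarray | None = None,
    grid: int | str = "unique",
    integration: str = "step",
) -> PrCurve:
    """Precision-recall over a threshold sweep with its average precision.

    AP uses step-wise interpolation by default (the sum over recall
    increments of the precision at the higher-recall side), which is
    robust to sawtooth PR curves; ``integration="trapezoid"`` is the
    alternative rule.
    """
    pred = np.asarray(pred, dtype=np.float64).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    if region is not None:
        sel = np.asarray(region, dtype=bool).ravel()
        pred, truth = pred[sel], truth[sel]
    n_pos = int(truth.sum())
    if n_pos == 0:
        raise ValueError("truth has no positive pixel")

    if grid == "unique":
        thresholds = np.unique(pred)
    else:
        thresholds = np.linspace(0.0, 1.0, int(grid) + 2)[1:-1]
    order = np.argsort(pred)
    sorted_pred = pred[order]
    cum_pos = np.concatenate([[0], np.cumsum(truth[order])])
    idx = np.searchsorted(sorted_pred, thresholds, side="left")
    tp = n_pos - cum_pos[idx]
    pred_pos = pred.size - idx
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(pred_pos > 0, tp / np.maximum(pred_pos, 1), np.nan)
    rec = tp / n_pos

    # integrate over recall, from high threshold (low recall) to low
    r = rec[::-1]
    p = prec[::-1]
    valid = ~np.isnan(p)
    r_v, p_v = r[valid], p[valid]
    # prepend the (recall=0) anchor and append nothing: the sweep ends at
    # the lowest threshold's recall, conservatively leaving higher recall
    # uncovered unless the sweep reaches recall 1
    if integration == "step":
        r_prev = np.concatenate([[0.0], r_v[:-1]])
        ap = float(np.sum((r_v - r_prev) * p_v))
    elif integration == "trapezoid":
        r_all = np.concatenate([[0.0], r_v])
        p_all = np.concatenate([[p_v[0] if len(p_v) else 0.0], p_v])
        ap = float(np.trapezoid(p_all, r_all))
    else:
        raise ValueError(f"unknown integration rule {integration!r}")
    return PrCurve(thresholds=thresholds, precision=prec, recall=rec, ap=ap)


def ap_of_fixed_segmentation(
    seg: np.ndarray,
    truth: np.ndarray,
    region: np.ndarray | None = None,
) -> float:
    """AP-comparable scalar for a binary map (e.g. raw bounding-box labels).

    A binary map has a single operating point (precision p at recall r);
    its two-segment PR curve (precision p from recall 0 to r, undefined
    beyond) integrates to p * r.  This rule makes comparisons between
    networks and their raw polygonal training labels self-consistent; it
    is a package convention, flagged in reports.
    """
    c = confusion(seg, truth, region=region)
    if c.tp + c.fn == 0:
        raise ValueError("truth has no positive pixel")
    p = precision(c)
    r = sensitivity(c)
    if np.isnan(p):  # empty segmentation: zero recall, zero area
        return 0.0
    return float(p * r)
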