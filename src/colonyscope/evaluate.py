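"""Quantitative verification of detections and picking decisions.

The field validates label-free detection against a pluripotency reporter
channel: both the detection mask and the binarized fluorescence image are
treated as 0/1 pixel fields and their Pearson correlation is computed over
the whole frame.  Mask IoU / precision / recall quantify agreement with
ground-truth colony masks, and picking accuracy is the fraction of colonies
whose predicted trigger day falls within +/-k days of the expert day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .detection import BinaryMap


@dataclass
class OverlayReport:
    pearson_r: float | None
    n_pixels: int
    reporter_threshold: float | None
    reason: str | None = None


@dataclass
class MaskMetrics:
    iou_per_colony: dict[int, float]
    precision: float | None
    recall: float | None
    reason: str | None = None


def _as_mask(m) -> np.ndarray:
    return np.asarray(m.mask if isinstance(m, BinaryMap) else m).astype(bool)


def pearson_overlap(
    detection,
    reporter: np.ndarray,
    reporter_threshold: float | None = None,
    mode: str = "binary",
) -> OverlayReport:
    """Frame-wide Pearson correlation of detection vs reporter.

    The reporter is binarized at ``reporter_threshold`` (Otsu when None).
    ``mode="binary"`` (default) correlates the two 0/1 fields;
    ``mode="intensity"`` correlates the raw reporter intensities with the
    binary detection field.  A constant field has undefined correlation and
    is reported as such rather than raising.
    """
    det = _as_mask(detection).astype(np.float64)
    rep = np.asarray(reporter, dtype=np.float64)
    if det.shape != rep.shape:
        raise ValueError("detection and reporter must have identical dims")
    thr = None
    if mode == "binary":
        thr = float(threshold_otsu(rep)) if reporter_threshold is None else float(reporter_threshold)
        rep = (rep >= thr).astype(np.float64)
    elif mode != "intensity":
        raise ValueError(f"unknown mode {mode!r}")
    if det.std() == 0 or rep.std() == 0:
        return OverlayReport(
            pearson_r=None,
            n_pixels=det.size,
            reporter_threshold=thr,
            reason="constant field: correlation undefined",
        )
    r = float(np.corrcoef(det.ravel(), rep.ravel())[0, 1])
    return OverlayReport(pearson_r=r, n_pixels=det.size, reporter_threshold=thr)


def mask_metrics(pred, truth: np.ndarray) -> MaskMetrics:
    """Per-truth-colony best-overlap IoU and global pixel precision/recall."""
    pred_mask = _as_mask(pred)
    truth = np.asarray(truth)
    if pred_mask.shape != truth.shape:
        raise ValueError("masks must have identical dims")
    truth_fg = truth > 0

    tp = int((pred_mask & truth_fg).sum())
    fp = int((pred_mask & ~truth_fg).sum())
    fn = int((~pred_mask & truth_fg).sum())
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None

    from skimage.measure import label as cc_label

    pred_labels = cc_label(pred_mask, connectivity=2)
    ious: dict[int, float] = {}
    for cid in np.unique(truth[truth_fg]):
        region = truth == cid
        overlapping = pred_labels[region]
        overlapping = overlapping[overlapping > 0]
        if overlapping.size == 0:
            ious[int(cid)] = 0.0
            continue
        best, best_iou = None, 0.0
        for pid, inter in zip(*np.unique(overlapping, return_counts=True)):
            union = int(region.sum()) + int((pred_labels == pid).sum()) - int(inter)
            iou = inter / union
            if iou > best_iou:
                best, best_iou = int(pid), float(iou)
        ious[int(cid)] = best_iou
    reason = None
    if precision is None:
        reason = "empty prediction: precision undefined"
    return MaskMetrics(iou_per_colony=ious, precision=precision, recall=recall, reason=reason)


def picking_accuracy(
    predicted: dict[int, int | None],
    truth: dict[int, int],
    k: int = 1,
) -> float:
    """Fraction of truth tracks with |predicted - truth| <= k days.

    Missing or None predictions count as incorrect.
    """
    if not truth:
        raise ValueError("empty truth")
    hits = 0
    for tid, day in truth.items():
        pred = predicted.get(tid)
        if pred is not None and abs(pred - day) <= k:
            hits += 1
    return hits / len(truth)
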