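"""Sliding-window colony detection on one frame.

A 96x96 window slides across the normalized frame from the top-left corner;
each position is scored by the texture classifier, giving a window-level
score grid.  Thresholding the grid and painting every passing window's
footprint yields a pixel-resolution binary map, which is then cleaned by the
fixed post-processing chain: fill enclosed holes, Gaussian-blur the 0/1
mask, re-binarize at a threshold, and drop small connected components
(sparse residuals).  Connected components of the cleaned map are the colony
candidate regions.

Coordinate conventions: 0-based, top-left origin; a window at grid position
(i, j) with stride s covers the half-open pixel block
[i*s, i*s+96) x [j*s, j*s+96).  A right/bottom remainder smaller than one
window is never scored (no padding), so detections cannot extend into it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .classifier import PATCH_SIZE, TextureModel
from .frames import Frame


@dataclass
class ScoreMap:
    """Window-level P(iPSC) grid with its pixel-coordinate mapping."""

    scores: np.ndarray  # (n_rows, n_cols) in [0, 1]
    window: int = PATCH_SIZE
    stride: int = PATCH_SIZE
    frame_shape: tuple[int, int] = (0, 0)
    well: str = "1"
    day: int = 0


@dataclass
class BinaryMap:
    """Pixel-resolution detection mask plus provenance."""

    mask: np.ndarray  # bool, same dims as the source frame
    provenance: dict = field(default_factory=dict)
    well: str = "1"
    day: int = 0


@dataclass
class ColonyRegion:
    region_id: int
    area_px: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    contour: np.ndarray | None = None
    well: str = "1"
    day: int = 0


def grid_shape(frame_shape: tuple[int, int], window: int, stride: int) -> tuple[int, int]:
    H, W = frame_shape
    if H < window or W < window:
        raise ValueError(f"frame {frame_shape} smaller than window {window}")
    return (H - window) // stride + 1, (W - window) // stride + 1


def scan(
    model: TextureModel,
    frame: Frame | np.ndarray,
    window: int = PATCH_SIZE,
    stride: int = PATCH_SIZE,
    batch_size: int = 512,
) -> ScoreMap:
    """Score every window position of a (normalized) frame."""
    is_frame = isinstance(frame, Frame)
    px = np.asarray(frame.pixels if is_frame else frame)
    n_rows, n_cols = grid_shape(px.shape, window, stride)
    positions = [
        (i * stride, j * stride) for i in range(n_rows) for j in range(n_cols)
    ]
    scores = np.empty(len(positions))
    for start in range(0, len(positions), batch_size):
        chunk = positions[start : start + batch_size]
        batch = np.stack([px[y : y + window, x : x + window] for y, x in chunk])
        scores[start : start + len(chunk)] = model.predict_proba_patches(batch)
    return ScoreMap(
        scores=scores.reshape(n_rows, n_cols),
        window=window,
        stride=stride,
        frame_shape=px.shape,
        well=frame.well if is_frame else "1",
        day=frame.day if is_frame else 0,
    )


def binarize(smap: ScoreMap, threshold: float = 0.5) -> BinaryMap:
    """Paint the footprint union of every window scoring >= threshold.

    With stride < window, overlapping footprints combine by union: a pixel is
    set if ANY covering window passes.
    """
    mask = np.zeros(smap.frame_shape, dtype=bool)
    passing = np.argwhere(smap.scores >= threshold)
    w = smap.window
    for i, j in passing:
        y, x = i * smap.stride, j * smap.stride
        mask[y : y + w, x : x + w] = True
    return BinaryMap(
        mask=mask,
        provenance={"threshold": threshold, "window": w, "stride": smap.stride},
        well=smap.well,
        day=smap.day,
    )


def postprocess(
    bmap: BinaryMap,
    sigma: float = 48.0,
    rebin_threshold: float = 0.5,
    min_area_px: int = PATCH_SIZE**2,
) -> BinaryMap:
    """Fixed cleaning chain: hole fill -> Gaussian blur -> re-binarize ->
    remove components smaller than ``min_area_px``."""
    mask = ndimage.binary_fill_holes(bmap.mask)
    if sigma > 0:
        blurred = ndimage.gaussian_filter(mask.astype(np.float64), sigma)
        mask = blurred >= rebin_threshold
    if min_area_px > 0:
        labels = measure.label(mask, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = counts[labels] >= min_area_px  # drop components with area < min_area_px
    return BinaryMap(
        mask=mask,
        provenance={
            **bmap.provenance,
            "sigma": sigma,
            "rebin_threshold": rebin_threshold,
            "min_area_px": min_area_px,
        },
        well=bmap.well,
        day=bmap.day,
    )


def extract_regions(
    bmap: BinaryMap, with_contours: bool = True
) -> list[ColonyRegion]:
    """8-connected components of a (post-processed) binary map."""
    labels = measure.label(bmap.mask, connectivity=2)
    regions = []
    for rp in measure.regionprops(labels):
        contour = None
        if with_contours:
            r0, c0, r1, c1 = rp.bbox
            crop = np.pad(labels[r0:r1, c0:c1] == rp.label, 1)
            cs = measure.find_contours(crop.astype(float), 0.5)
            if cs:
                contour = max(cs, key=len) + [r0 - 1, c0 - 1]
        regions.append(
            ColonyRegion(
                region_id=int(rp.label),
                area_px=int(rp.area),
                centroid=tuple(float(c) for c in rp.centroid),
                bbox=tuple(int(b) for b in rp.bbox),
                contour=contour,
                well=bmap.well,
                day=bmap.day,
            )
        )
    return regions


def detect_frame(
    model: TextureModel,
    frame: Frame | np.ndarray,
    window: int = PATCH_SIZE,
    stride: int = PATCH_SIZE,
    threshold: float | None = None,
    sigma: float = 48.0,
    rebin_threshold: float = 0.5,
    min_area_px: int = PATCH_SIZE**2,
) -> BinaryMap:
    """Convenience: scan -> binarize -> postprocess for one frame."""
    smap = scan(model, frame, window=window, stride=stride)
    thr = model.threshold if threshold is None else threshold
    return postprocess(
        binarize(smap, thr),
        sigma=sigma,
        rebin_threshold=rebin_threshold,
        min_area_px=min_area_px,
    )
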