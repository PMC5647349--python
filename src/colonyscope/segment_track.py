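"""Seeded segmentation and time-lapse colony tracking.

Up to the seed day (default day 12) colony labels are simply the connected
components of the detection map.  For more mature frames the detection map's
blocky outline is refined with a semi-supervised random walker: the previous
day's labels, eroded, seed the colony interiors; the complement of a dilated
envelope seeds the background; every remaining pixel receives the label whose
seeds a random walk on the intensity-weighted 4-connected lattice is most
likely to reach first.  Edge weights are ``w = exp(-beta * dI**2)`` on
normalized intensities and the walk probabilities solve the combinatorial
Dirichlet (discrete Laplace) problem -- equivalently, they are the absorption
probabilities of the absorbing Markov chain whose absorbing states are the
seeds.

Tracks are formed backward in time: every region in the final frame (and any
unclaimed region on the seed day) starts a track, and each region links to
the previous day's region of maximal pixel overlap, requiring
``overlap / min(area) >= 0.3``.  The area-versus-day series of a track is its
growth curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix, diags
from scipy.sparse.linalg import spsolve
from skimage import measure, morphology

from .detection import BinaryMap
from .frames import Frame


@dataclass
class RandomWalkerParams:
    beta: float = 130.0
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")


@dataclass
class ColonyTrack:
    """One colony registered across days: day -> (region_id, area_px)."""

    track_id: int
    regions: dict[int, tuple[int, int]] = field(default_factory=dict)
    seed_day: int | None = None

    @property
    def days(self) -> list[int]:
        return sorted(self.regions)

    @property
    def first_positive_day(self) -> int:
        return min(self.regions)


@dataclass
class GrowthCurve:
    """Area (px^2) per tracked day; missing days are absent, not interpolated."""

    track_id: int
    days: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.days.shape != self.areas.shape:
            raise ValueError("days and areas must have equal length")


def _edge_weights(image: np.ndarray, beta: float):
    """Horizontal and vertical edge weights w = exp(-beta * dI^2)."""
    img = np.asarray(image, dtype=np.float64)
    wh = np.exp(-beta * np.diff(img, axis=1) ** 2)  # (H, W-1)
    wv = np.exp(-beta * np.diff(img, axis=0) ** 2)  # (H-1, W)
    return wh, wv


def random_walker(
    image: np.ndarray,
    seeds: np.ndarray,
    params: RandomWalkerParams | None = None,
):
    """Seeded random-walker segmentation on the 4-connected pixel lattice.

    Parameters
    ----------
    image
        2-D intensity array; pass normalized (roughly [0, 1]) intensities so
        that ``beta`` has its conventional meaning.
    seeds
        Integer label mask, 0 = unlabeled, >= 1 = seed labels.  At least two
        distinct labels are required.

    Returns
    -------
    (labels, probabilities)
        ``labels``: per-pixel argmax label (seed pixels keep their label;
        ties go to the lower label).  ``probabilities``: array of shape
        (n_labels, H, W); per-pixel values sum to 1.
    """
    params = params or RandomWalkerParams()
    image = np.asarray(image, dtype=np.float64)
    seeds = np.asarray(seeds)
    if image.shape != seeds.shape:
        raise ValueError("image and seeds must have the same shape")
    label_values = np.unique(seeds[seeds > 0])
    if len(label_values) < 2:
        raise ValueError("random_walker requires >= 2 distinct seed labels")

    H, W = image.shape
    n = H * W
    idx = np.arange(n).reshape(H, W)
    wh, wv = _edge_weights(image, params.beta)

    rows = np.concatenate([idx[:, :-1].ravel(), idx[:-1, :].ravel()])
    cols = np.concatenate([idx[:, 1:].ravel(), idx[1:, :].ravel()])
    wts = np.concatenate([wh.ravel(), wv.ravel()])

    # Graph Laplacian L = D - A over all pixels.
    A = coo_matrix((wts, (rows, cols)), shape=(n, n))
    A = (A + A.T).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    L = diags(deg) - A

    seeded = seeds.ravel() > 0
    u = np.flatnonzero(~seeded)
    s = np.flatnonzero(seeded)
    Luu = L[u][:, u].tocsc()
    Bus = L[u][:, s].tocsr()

    probs = np.zeros((len(label_values), n))
    if len(u):
        seed_labels = seeds.ravel()[s]
        # Solve for the first n_labels-1 fields; the last follows from the
        # per-pixel simplex constraint.
        for k, lab in enumerate(label_values[:-1]):
            rhs = -Bus @ (seed_labels == lab).astype(np.float64)
            x = spsolve(Luu, rhs)
            resid = np.abs(Luu @ x - rhs).max() if len(rhs) else 0.0
            if not np.isfinite(x).all() or resid > params.tolerance:
                raise RuntimeError(
                    f"random walker linear solve residual {resid:.3e} exceeds "
                    f"tolerance {params.tolerance:.1e}"
                )
            probs[k, u] = x
        probs[-1, u] = 1.0 - probs[:-1, u].sum(axis=0)
    for k, lab in enumerate(label_values):
        probs[k, s[seeds.ravel()[s] == lab]] = 1.0
    probs = probs.reshape(len(label_values), H, W)
    np.clip(probs, 0.0, 1.0, out=probs)

    winner = probs.argmax(axis=0)  # ties -> lower index -> lower label
    labels = label_values[winner]
    labels = np.where(seeds > 0, seeds, labels)
    return labels.astype(seeds.dtype, copy=False), probs


def texture_energy(image: np.ndarray, window: int = 5, smooth: float = 1.5) -> np.ndarray:
    """Local texture-energy transform, robustly normalized to [0, 1].

    Colony and background differ in texture (variance / correlation length)
    rather than brightness, so boundary refinement runs on the local standard
    deviation of intensity: there the colony interior and the background are
    plateaus and the colony edge is a sharp level step, which is what
    edge-weighted diffusion expects.  A small window and light smoothing keep
    the step steep (a steep step is a strong random-walker barrier that the
    boundary snaps to); the 5th..95th percentile normalization saturates both
    plateaus so their internal fluctuations stay conductive.
    """
    px = np.asarray(image, dtype=np.float64)
    mean = ndimage.uniform_filter(px, window)
    sq = ndimage.uniform_filter(px**2, window)
    sd = np.sqrt(np.maximum(sq - mean**2, 0.0))
    if smooth > 0:
        sd = ndimage.gaussian_filter(sd, smooth)
    lo, hi = np.percentile(sd, [5.0, 95.0])
    if hi <= lo:
        return np.zeros_like(sd)
    return np.clip((sd - lo) / (hi - lo), 0.0, 1.0)


def segment_frame(
    bmap: BinaryMap,
    frame: Frame | np.ndarray | None = None,
    day: int | None = None,
    seed_day: int = 12,
    prior_labels: np.ndarray | None = None,
    params: RandomWalkerParams | None = None,
    erosion_radius: int = 5,
    dilation_radius: int = 15,
) -> np.ndarray:
    """Label map for one day's detection.

    Days up to ``seed_day``: plain 8-connected component labels of the
    detection map.  Later days: detection components inherit the prior day's
    identity by maximal overlap (unmatched components get fresh labels --
    colonies may first appear after the seed day) and boundaries are refined
    with a random walker on the frame's texture-energy image, restricted to
    a dilated envelope of the detection map.  Matched colonies are seeded by
    their eroded prior footprint, new ones by their eroded detection
    component.  A prior label with no support in the current detection map
    is emitted as an empty region (colony lost), not an error.
    """
    day = bmap.day if day is None else day
    mask = bmap.mask
    if day <= seed_day:
        return measure.label(mask, connectivity=2).astype(np.uint16)

    if prior_labels is None:
        raise ValueError(f"day {day} > seed_day {seed_day} requires prior_labels")
    if frame is None:
        raise ValueError("intensity frame required for random-walker refinement")
    px = frame.pixels if isinstance(frame, Frame) else frame
    tex = texture_energy(px)

    comps, n_comps = measure.label(mask, connectivity=2, return_num=True)
    if n_comps == 0:
        return np.zeros(mask.shape, dtype=np.uint16)
    envelope = ndimage.binary_dilation(mask, structure=morphology.disk(dilation_radius))

    # every prior label with support in the current detection keeps a seed;
    # detection components touching no prior label are new colonies
    footprint = morphology.disk(erosion_radius)
    seeds = np.zeros(mask.shape, dtype=np.int32)
    next_id = int(prior_labels.max()) + 1

    def plant(region: np.ndarray, lab: int) -> None:
        seed = ndimage.binary_erosion(region, structure=footprint)
        if not seed.any():
            seed = region
        seed = seed & envelope
        if seed.any():
            seeds[seed] = lab

    for lab in np.unique(prior_labels[prior_labels > 0]):
        if (mask & (prior_labels == lab)).any():
            plant(prior_labels == lab, int(lab))

    # deep interior of the detection (well inside the blocky boundary slack)
    # also seeds, so labels keep up with fast growth; ambiguous merged
    # components (several prior labels) rely on prior seeds alone
    interior_depth = 50
    interior = ndimage.distance_transform_edt(mask) > interior_depth
    for c in range(1, n_comps + 1):
        comp = comps == c
        touched = np.unique(prior_labels[comp])
        touched = touched[touched > 0]
        if len(touched) == 0:
            core = comp & interior
            plant(core if core.any() else comp, next_id)
            next_id += 1
        elif len(touched) == 1:
            core = comp & interior & (seeds == 0)
            if core.any():
                seeds[core] = int(touched[0])

    present = np.unique(seeds[seeds > 0])
    if len(present) == 0:
        return np.zeros(mask.shape, dtype=np.uint16)
    bg_label = int(max(present.max(), prior_labels.max())) + 1
    seeds[~envelope] = bg_label
    if not (seeds == bg_label).any():  # envelope covers the whole frame
        seeds[0, 0] = bg_label

    labels, _ = random_walker(tex, seeds, params)
    labels = np.where(labels == bg_label, 0, labels)
    labels = np.where(envelope, labels, 0)
    return labels.astype(np.uint16)


def _region_table(label_map: np.ndarray) -> dict[int, int]:
    ids, counts = np.unique(label_map[label_map > 0], return_counts=True)
    return {int(i): int(c) for i, c in zip(ids, counts)}


def _best_overlap(
    label_map_prev: np.ndarray,
    label_map_curr: np.ndarray,
    region_id: int,
    min_overlap: float,
) -> int | None:
    """Previous-day region with maximal pixel overlap against ``region_id``.

    Requires overlap / min(areas) >= min_overlap.  Ties break toward the
    larger previous region, then the lower region id.
    """
    cur = label_map_curr == region_id
    prev_vals = label_map_prev[cur]
    prev_vals = prev_vals[prev_vals > 0]
    if prev_vals.size == 0:
        return None
    areas_prev = _region_table(label_map_prev)
    cur_area = int(cur.sum())
    ids, ov = np.unique(prev_vals, return_counts=True)
    best = None
    for pid, o in zip(ids, ov):
        pid = int(pid)
        frac = o / min(cur_area, areas_prev[pid])
        if frac < min_overlap:
            continue
        key = (int(o), areas_prev[pid], -pid)
        if best is None or key > best[0]:
            best = (key, pid)
    return None if best is None else best[1]


def link_tracks(
    label_maps: dict[int, np.ndarray],
    min_overlap: float = 0.3,
    seed_day: int | None = None,
) -> list[ColonyTrack]:
    """Backward overlap linking of per-day label maps into colony tracks.

    Tracks originate from the final frame's regions; regions on ``seed_day``
    not already claimed by a track also start tracks (traced backward from
    the seed day).  Regions appearing on other intermediate days only do not
    form tracks.
    """
    if len(label_maps) < 2:
        raise ValueError("need label maps for at least 2 days")
    days = sorted(label_maps)

    def trace_back(start_day: int, region_id: int) -> dict[int, tuple[int, int]]:
        out = {start_day: (region_id, _region_table(label_maps[start_day])[region_id])}
        rid = region_id
        pos = days.index(start_day)
        for k in range(pos, 0, -1):
            d, d_prev = days[k], days[k - 1]
            nxt = _best_overlap(label_maps[d_prev], label_maps[d], rid, min_overlap)
            if nxt is None:
                break
            out[d_prev] = (nxt, _region_table(label_maps[d_prev])[nxt])
            rid = nxt
        return out

    tracks: list[ColonyTrack] = []
    tid = 1
    last = days[-1]
    for rid in sorted(_region_table(label_maps[last])):
        tracks.append(ColonyTrack(track_id=tid, regions=trace_back(last, rid), seed_day=seed_day))
        tid += 1
    if seed_day is not None and seed_day in label_maps and seed_day != last:
        claimed = {t.regions[seed_day][0] for t in tracks if seed_day in t.regions}
        for rid in sorted(_region_table(label_maps[seed_day])):
            if rid not in claimed:
                tracks.append(
                    ColonyTrack(track_id=tid, regions=trace_back(seed_day, rid), seed_day=seed_day)
                )
                tid += 1
    return tracks


def growth_curve(track: ColonyTrack) -> GrowthCurve:
    """Area-versus-day series of one track."""
    if not track.regions:
        raise ValueError("empty track")
    days = track.days
    return GrowthCurve(
        track_id=track.track_id,
        days=np.array(days),
        areas=np.array([track.regions[d][1] for d in days], dtype=float),
    )
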