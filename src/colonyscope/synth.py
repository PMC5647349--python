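"""Synthetic bright-field time-lapse scenes with ground truth.

Every downstream stage (classification, detection, segmentation, tracking,
phase modelling, evaluation) is exercised on scenes produced here, so no
microscopy downloads are needed.  A scene emulates what matters
statistically about the real data, not its photorealism:

* a textured background (fibroblasts/medium) and textured colony interiors
  that differ in variance and spatial-correlation length -- the texture
  contrast is a knob, so classifier tests can be made easy or hard;
* per-colony logistic area growth over a day range (default days 7..22):
  ``A(d) = K / (1 + ((K - A0)/A0) * exp(-r (d - onset)))`` with ``A0``
  a small onset fraction of the carrying capacity ``K``;
* a fluorescence reporter channel co-located with true colonies, with a
  configurable fraction of reporter-silent colony area (real reporter
  populations leave roughly 10% of cells unlabelled);
* expert picking-day labels, defined as the first day the noise-free
  logistic reaches a maturity fraction (default 60%) of ``K``.

Colonies are rendered as discs at fixed centres, so growth is monotone and
footprints stay nested; placement guarantees pairwise disjoint footprints at
carrying capacity or raises after bounded retries.  All generators are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .classifier import PATCH_SIZE, PatchSample
from .frames import Frame, write_frame, write_mask
from .segment_track import GrowthCurve


class SceneGenerationError(RuntimeError):
    """Requested colonies cannot be placed disjointly."""


@dataclass
class TextureParams:
    """Band-limited correlated-noise textures for background and colonies."""

    bg_mean: float = 28000.0
    bg_sd: float = 1200.0
    bg_corr_len: float = 8.0
    colony_mean: float = 30000.0
    colony_sd: float = 3600.0
    colony_corr_len: float = 1.5


@dataclass
class GrowthParams:
    """One colony's logistic growth law (areas in px^2, rate per day)."""

    carrying_capacity: float = 2.0e5
    rate: float = 0.55
    onset_day: float = 8.0
    onset_fraction: float = 0.02  # A0 / K at the onset day


@dataclass
class SceneConfig:
    image_size: tuple[int, int] = (1536, 1536)
    n_colonies: int = 3
    texture_params: TextureParams = field(default_factory=TextureParams)
    growth_params: list[GrowthParams] | None = None
    day_range: tuple[int, int] = (7, 22)
    maturity_fraction: float = 0.6
    # a colony is rendered once its texture footprint is resolvable at the
    # 96-px detection-window scale (~70% of one window)
    min_visible_area: float = 6500.0
    reporter_snr: float = 10.0
    well: str = "1"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        H, W = self.image_size
        if H < 3 * PATCH_SIZE or W < 3 * PATCH_SIZE:
            raise ValueError(f"image_size must be >= {3 * PATCH_SIZE} per side")
        if self.n_colonies < 0:
            raise ValueError("n_colonies must be >= 0")
        if self.day_range[0] > self.day_range[1]:
            raise ValueError("day_range must be (first, last) inclusive")


@dataclass
class GroundTruth:
    """Per-day label masks (0 = background, k >= 1 = colony id) plus tables."""

    masks: dict[int, np.ndarray]
    area_table: pd.DataFrame  # colony_id, day, area_px
    picking_table: pd.DataFrame  # colony_id, picking_day, first_positive_day

    def mask_for(self, day: int) -> np.ndarray:
        return self.masks[day]

    def colony_curve(self, colony_id: int) -> GrowthCurve:
        sub = self.area_table[self.area_table.colony_id == colony_id].sort_values("day")
        return GrowthCurve(
            track_id=colony_id,
            days=sub.day.to_numpy(),
            areas=sub.area_px.to_numpy(),
        )


def logistic_area(p: GrowthParams, day: float | np.ndarray) -> np.ndarray:
    """Closed-form logistic area at a (possibly vector) day; 0 before onset."""
    day = np.asarray(day, dtype=float)
    a0 = p.onset_fraction * p.carrying_capacity
    ratio = (p.carrying_capacity - a0) / a0
    area = p.carrying_capacity / (1.0 + ratio * np.exp(-p.rate * (day - p.onset_day)))
    return np.where(day < p.onset_day, 0.0, area)


def picking_day_of(p: GrowthParams, day_range: tuple[int, int], maturity_fraction: float) -> int | None:
    days = np.arange(day_range[0], day_range[1] + 1)
    mature = logistic_area(p, days) >= maturity_fraction * p.carrying_capacity
    hits = np.flatnonzero(mature)
    return int(days[hits[0]]) if len(hits) else None


def _correlated_noise(shape, corr_len, rng) -> np.ndarray:
    """Zero-mean unit-variance noise with Gaussian correlation length."""
    noise = rng.standard_normal(shape)
    if corr_len > 0:
        noise = ndimage.gaussian_filter(noise, corr_len)
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def default_growth_params(n: int, rng: np.random.Generator) -> list[GrowthParams]:
    """Realistic per-colony variation around the default logistic law."""
    return [
        GrowthParams(
            carrying_capacity=float(rng.uniform(1.4e5, 2.4e5)),
            rate=float(rng.normal(0.55, 0.05)),
            onset_day=float(rng.uniform(7.0, 9.0)),
        )
        for _ in range(n)
    ]


def _place_colonies(config: SceneConfig, params: list[GrowthParams], rng,
                    max_tries: int = 200) -> list[tuple[float, float]]:
    H, W = config.image_size
    centres: list[tuple[float, float]] = []
    radii = [np.sqrt(p.carrying_capacity / np.pi) for p in params]
    margin_gap = 10.0
    for i, r in enumerate(radii):
        for _ in range(max_tries):
            cy = rng.uniform(r, H - r)
            cx = rng.uniform(r, W - r)
            ok = all(
                np.hypot(cy - oy, cx - ox) >= r + radii[j] + margin_gap
                for j, (oy, ox) in enumerate(centres)
            )
            if ok:
                centres.append((cy, cx))
                break
        else:
            raise SceneGenerationError(
                f"could not place colony {i + 1}/{len(params)} disjointly in "
                f"{config.image_size} after {max_tries} tries"
            )
    return centres


def generate_scene(config: SceneConfig) -> tuple[list[Frame], GroundTruth]:
    """Render the time-lapse frames and exact ground truth for one well."""
    rng = np.random.default_rng(config.rng_seed)
    params = config.growth_params
    if params is None:
        params = default_growth_params(config.n_colonies, rng)
    if len(params) != config.n_colonies:
        raise ValueError("growth_params length must equal n_colonies")
    centres = _place_colonies(config, params, rng)

    H, W = config.image_size
    tex = config.texture_params
    yy, xx = np.mgrid[0:H, 0:W]
    days = range(config.day_range[0], config.day_range[1] + 1)

    frames: list[Frame] = []
    masks: dict[int, np.ndarray] = {}
    area_rows = []
    first_positive: dict[int, int] = {}
    for day in days:
        bg = tex.bg_mean + tex.bg_sd * _correlated_noise((H, W), tex.bg_corr_len, rng)
        img = bg
        label = np.zeros((H, W), dtype=np.uint16)
        for cid, (p, (cy, cx)) in enumerate(zip(params, centres), start=1):
            area = float(logistic_area(p, day))
            if area < config.min_visible_area:
                area_rows.append((cid, day, 0))
                continue
            r = np.sqrt(area / np.pi)
            y0, y1 = max(0, int(cy - r) - 1), min(H, int(cy + r) + 2)
            x0, x1 = max(0, int(cx - r) - 1), min(W, int(cx + r) + 2)
            disc = (yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2 <= r**2
            n_px = int(disc.sum())
            if n_px == 0:
                area_rows.append((cid, day, 0))
                continue
            label[y0:y1, x0:x1][disc] = cid
            ctex = tex.colony_mean + tex.colony_sd * _correlated_noise(
                disc.shape, tex.colony_corr_len, rng
            )
            img[y0:y1, x0:x1] = np.where(disc, ctex, img[y0:y1, x0:x1])
            area_rows.append((cid, day, n_px))
            first_positive.setdefault(cid, day)
        frames.append(
            Frame(
                pixels=np.clip(img, 0, 65535).astype(np.uint16),
                well=config.well,
                day=day,
            )
        )
        masks[day] = label

    pick_rows = []
    for cid, p in enumerate(params, start=1):
        pick_rows.append(
            (
                cid,
                picking_day_of(p, config.day_range, config.maturity_fraction),
                first_positive.get(cid),
            )
        )
    truth = GroundTruth(
        masks=masks,
        area_table=pd.DataFrame(area_rows, columns=["colony_id", "day", "area_px"]),
        picking_table=pd.DataFrame(
            pick_rows, columns=["colony_id", "picking_day", "first_positive_day"]
        ),
    )
    return frames, truth


def generate_reporter(
    truth_mask: np.ndarray,
    reporter_snr: float = 10.0,
    coverage_fraction: float = 0.9,
    rng_seed: int = 0,
    background_level: float = 200.0,
    signal_level: float = 10000.0,
) -> np.ndarray:
    """Fluorescence reporter image co-located with true colonies.

    Within each colony a spatially coherent subset covering
    ``coverage_fraction`` of its area carries the reporter signal, emulating
    reporter-silent cells; noise scales as ``signal_level / reporter_snr``
    (an infinite SNR gives a noise-free image).
    """
    if not (0 < coverage_fraction <= 1):
        raise ValueError("coverage_fraction must be in (0, 1]")
    rng = np.random.default_rng(rng_seed)
    truth_mask = np.asarray(truth_mask)
    img = np.full(truth_mask.shape, background_level, dtype=np.float64)
    for cid in np.unique(truth_mask[truth_mask > 0]):
        region = truth_mask == cid
        if coverage_fraction >= 1.0:
            chosen = region
        else:
            fld = _correlated_noise(truth_mask.shape, 4.0, rng)
            cutoff = np.quantile(fld[region], coverage_fraction)
            chosen = region & (fld <= cutoff)
        img[chosen] += signal_level
    if np.isfinite(reporter_snr):
        img += rng.normal(0.0, signal_level / reporter_snr, size=img.shape)
    return np.clip(img, 0, 65535).astype(np.uint16)


def _coverage_positions(mask: np.ndarray, window: int):
    """Summed-area table of colony coverage for every window position."""
    ii = np.pad((mask > 0).astype(np.int64), ((1, 0), (1, 0))).cumsum(0).cumsum(1)
    H, W = mask.shape
    n_y, n_x = H - window + 1, W - window + 1
    cov = (
        ii[window : window + n_y, window : window + n_x]
        - ii[window : window + n_y, :n_x]
        - ii[:n_y, window : window + n_x]
        + ii[:n_y, :n_x]
    )
    return cov  # (n_y, n_x) colony pixel counts per window


def generate_patch_dataset(
    frames: list[Frame],
    truth: GroundTruth,
    n_per_class: int,
    rng_seed: int = 0,
    neg_boundary_fraction: float = 0.3,
    max_neg_coverage: float = 0.5,
) -> list[PatchSample]:
    """Sample labelled 96x96 patches from rendered frames.

    Positives (label 0) lie fully inside a colony; negatives (label 1) are
    anywhere else -- by default a mix of pure background windows and
    boundary-straddling windows whose colony coverage is at most
    ``max_neg_coverage``, which teaches the classifier to reject
    majority-background windows and sharpens detection boundaries.  Raises if
    the scene lacks enough fully-interior colony area.
    """
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    rng = np.random.default_rng(rng_seed)
    w = PATCH_SIZE
    full = w * w

    pos_pool, bnd_pool, bg_pool = [], [], []
    for fi, frame in enumerate(frames):
        mask = truth.masks[frame.day]
        cov = _coverage_positions(mask, w)
        for pool, sel in (
            (pos_pool, cov == full),
            (bg_pool, cov == 0),
            (bnd_pool, (cov > 0) & (cov <= max_neg_coverage * full)),
        ):
            ys, xs = np.nonzero(sel)
            if len(ys):
                pool.append(
                    np.column_stack([np.full(len(ys), fi), ys, xs])
                )
    pos_pool = np.vstack(pos_pool) if pos_pool else np.empty((0, 3), int)
    bg_pool = np.vstack(bg_pool) if bg_pool else np.empty((0, 3), int)
    bnd_pool = np.vstack(bnd_pool) if bnd_pool else np.empty((0, 3), int)

    if len(pos_pool) < n_per_class:
        raise ValueError(
            f"insufficient fully-interior colony area: {len(pos_pool)} candidate "
            f"positions for {n_per_class} positive patches"
        )
    if len(bg_pool) + len(bnd_pool) < n_per_class:
        raise ValueError("insufficient non-colony area for negative patches")

    n_bnd = min(int(round(neg_boundary_fraction * n_per_class)), len(bnd_pool))
    n_bg = n_per_class - n_bnd
    if n_bg > len(bg_pool):
        n_bnd += n_bg - len(bg_pool)
        n_bg = len(bg_pool)

    def draw(pool, n, label):
        idx = rng.choice(len(pool), size=n, replace=False)
        out = []
        for fi, y, x in pool[np.sort(idx)]:
            frame = frames[fi]
            out.append(
                PatchSample(
                    pixels=frame.pixels[y : y + w, x : x + w].copy(),
                    label=label,
                    source=(frame.well, frame.day, int(x), int(y)),
                )
            )
        return out

    patches = draw(pos_pool, n_per_class, 0)
    patches += draw(bg_pool, n_bg, 1)
    if n_bnd:
        patches += draw(bnd_pool, n_bnd, 1)
    return patches


# ---------------------------------------------------------------------------
# curve-level cohorts (no rendering)
# ---------------------------------------------------------------------------


def generate_cohort_curves(
    n_curves: int,
    rng_seed: int = 0,
    day_range: tuple[int, int] = (7, 22),
    maturity_fraction: float = 0.6,
    area_noise_sd: float = 0.03,
    min_visible_area: float = 200.0,
    overgrower_ids: set[int] | None = None,
    overgrowth_factor: float = 3.0,
):
    """Growth-curve cohort with truth picking days, without rendering images.

    Areas follow the same logistic law as rendered scenes plus multiplicative
    measurement noise (segmentation error).  ``overgrower_ids`` (1-based)
    marks curves whose area growth is scaled by ``overgrowth_factor``,
    emulating abnormal overgrowth.

    Returns ``(curves, truth)`` where truth has columns track_id,
    picking_day, first_positive_day, is_overgrower.
    """
    rng = np.random.default_rng(rng_seed)
    overgrower_ids = overgrower_ids or set()
    days_all = np.arange(day_range[0], day_range[1] + 1)
    curves, rows = [], []
    for tid in range(1, n_curves + 1):
        p = default_growth_params(1, rng)[0]
        if tid in overgrower_ids:
            p = replace(p, carrying_capacity=p.carrying_capacity * overgrowth_factor)
        clean = logistic_area(p, days_all)
        visible = clean >= min_visible_area
        days = days_all[visible]
        noisy = clean[visible] * (1.0 + rng.normal(0.0, area_noise_sd, size=visible.sum()))
        noisy = np.maximum.accumulate(np.maximum(noisy, 1.0))  # keep monotone
        curves.append(GrowthCurve(track_id=tid, days=days, areas=np.rint(noisy)))
        pick = picking_day_of(p, day_range, maturity_fraction)
        rows.append((tid, pick, int(days[0]) if len(days) else None,
                     tid in overgrower_ids))
    truth = pd.DataFrame(
        rows, columns=["track_id", "picking_day", "first_positive_day", "is_overgrower"]
    )
    return curves, truth


# ---------------------------------------------------------------------------
# on-disk scene dialect
# ---------------------------------------------------------------------------


def write_scene(frames: list[Frame], truth: GroundTruth, directory: str | Path) -> Path:
    """Write frames (TIFF), truth masks (16-bit PNG) and truth tables (CSV)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for frame in frames:
        write_frame(frame, directory)
    for day, mask in truth.masks.items():
        well = frames[0].well if frames else "1"
        write_mask(mask, directory / f"truth_well{well}_day{day}.png")
    truth.area_table.to_csv(directory / "truth_areas.csv", index=False)
    truth.picking_table.to_csv(directory / "truth_picking.csv", index=False)
    return directory


def save_config(config: SceneConfig, path: str | Path) -> None:
    """Plain-text ``key = value`` scene configuration."""
    tex = config.texture_params
    lines = [
        f"image_height = {config.image_size[0]}",
        f"image_width = {config.image_size[1]}",
        f"n_colonies = {config.n_colonies}",
        f"day_first = {config.day_range[0]}",
        f"day_last = {config.day_range[1]}",
        f"maturity_fraction = {config.maturity_fraction}",
        f"reporter_snr = {config.reporter_snr}",
        f"well = {config.well}",
        f"rng_seed = {config.rng_seed}",
        f"bg_mean = {tex.bg_mean}",
        f"bg_sd = {tex.bg_sd}",
        f"bg_corr_len = {tex.bg_corr_len}",
        f"colony_mean = {tex.colony_mean}",
        f"colony_sd = {tex.colony_sd}",
        f"colony_corr_len = {tex.colony_corr_len}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> SceneConfig:
    kv = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()
    tex = TextureParams(
        bg_mean=float(kv.get("bg_mean", 28000)),
        bg_sd=float(kv.get("bg_sd", 1200)),
        bg_corr_len=float(kv.get("bg_corr_len", 8.0)),
        colony_mean=float(kv.get("colony_mean", 30000)),
        colony_sd=float(kv.get("colony_sd", 3600)),
        colony_corr_len=float(kv.get("colony_corr_len", 1.5)),
    )
    return SceneConfig(
        image_size=(int(kv.get("image_height", 1536)), int(kv.get("image_width", 1536))),
        n_colonies=int(kv.get("n_colonies", 3)),
        texture_params=tex,
        day_range=(int(kv.get("day_first", 7)), int(kv.get("day_last", 22))),
        maturity_fraction=float(kv.get("maturity_fraction", 0.6)),
        reporter_snr=float(kv.get("reporter_snr", 10.0)),
        well=kv.get("well", "1"),
        rng_seed=int(kv.get("rng_seed", 0)),
    )
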