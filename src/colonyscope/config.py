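"""Run manifests, pipeline configuration and the end-to-end driver.

A run manifest lists, per well, the frame file for each day (canonical
naming ``well{W}_day{D}.tif``, or explicit paths).  The pipeline driver
executes the stages in order -- preprocess -> detect -> segment -> track ->
growth curves -> (optionally) phase decoding and picking -- writing each
stage's outputs under the run directory with a provenance header, and is
bit-reproducible given identical inputs and seeds.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detection, phase_model, segment_track
from .classifier import TextureModel
from .frames import FRAME_NAME_RE, read_frame
from .preprocess import AutolevelsParams, autolevels

logger = logging.getLogger("colonyscope")


@dataclass
class PipelineConfig:
    """Per-stage knobs; mirrors the sections of the TOML config file."""

    low_percentile: float = 1.0
    high_percentile: float = 99.0
    window: int = 96
    stride: int = 96
    score_threshold: float = 0.5
    sigma: float = 48.0
    rebin_threshold: float = 0.5
    min_area_px: int = 96 * 96
    seed_day: int = 12
    rw_beta: float = 130.0
    min_overlap: float = 0.3
    n_states: int = 4
    n_restarts: int = 2000
    picking_threshold: float = 0.3
    rng_seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        flat: dict = {}
        for key, value in doc.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in flat.items() if k in known})

    def to_toml_text(self) -> str:
        lines = ["[preprocess]"]
        lines += [f"low_percentile = {self.low_percentile}",
                  f"high_percentile = {self.high_percentile}", "", "[detect]"]
        lines += [f"window = {self.window}", f"stride = {self.stride}",
                  f"score_threshold = {self.score_threshold}",
                  f"sigma = {self.sigma}",
                  f"rebin_threshold = {self.rebin_threshold}",
                  f"min_area_px = {self.min_area_px}", "", "[track]"]
        lines += [f"seed_day = {self.seed_day}", f"rw_beta = {self.rw_beta}",
                  f"min_overlap = {self.min_overlap}", "", "[phases]"]
        lines += [f"n_states = {self.n_states}", f"n_restarts = {self.n_restarts}",
                  f"picking_threshold = {self.picking_threshold}",
                  f"rng_seed = {self.rng_seed}"]
        return "\n".join(lines) + "\n"


class ManifestError(ValueError):
    pass


@dataclass
class RunManifest:
    """Per-well frame paths by day, plus run seeds."""

    wells: dict[str, dict[int, Path]]
    rng_seed: int = 0
    config: PipelineConfig = field(default_factory=PipelineConfig)

    @classmethod
    def from_directory(cls, directory: str | Path, **kwargs) -> "RunManifest":
        wells: dict[str, dict[int, Path]] = {}
        for p in sorted(Path(directory).iterdir()):
            m = FRAME_NAME_RE.search(p.name)
            if m:
                wells.setdefault(m.group("well"), {})[int(m.group("day"))] = p
        if not wells:
            raise ManifestError(f"no canonical frames found in {directory}")
        return cls(wells=wells, **kwargs)

    def validate(self) -> None:
        if not self.wells:
            raise ManifestError("manifest lists no wells")
        for well, days in self.wells.items():
            if not days:
                raise ManifestError(f"well {well} lists no frames")
            for day, path in days.items():
                if not Path(path).exists():
                    raise ManifestError(f"missing frame for well {well} day {day}: {path}")


def run_pipeline(
    manifest: RunManifest,
    model: TextureModel | str | Path,
    out_dir: str | Path,
    picking_days: dict[int, int] | None = None,
    hmm: phase_model.GrowthPhaseResults | None = None,
) -> dict:
    """Execute detect -> segment -> track -> curves (-> phases -> pick).

    ``picking_days`` (track_id -> expert day) trains a phase HMM on this
    run's own tracks; alternatively a pre-trained ``hmm`` decodes them.  The
    returned summary dict is also written as ``summary.json``.
    """
    manifest.validate()
    cfg = manifest.config
    if not isinstance(model, TextureModel):
        model = TextureModel.load(model)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.toml").write_text(cfg.to_toml_text())

    al = AutolevelsParams(cfg.low_percentile, cfg.high_percentile)
    summary: dict = {"wells": {}, "rng_seed": manifest.rng_seed}
    all_curod = []
    decisions_rows = []
    for well, day_paths in sorted(manifest.wells.items()):
        logger.info("well %s: %d frames", well, len(day_paths))
        frames = {d: autolevels(read_frame(p), al) for d, p in sorted(day_paths.items())}

        bmaps = {}
        regions_rows = []
        for day, frame in frames.items():
            bmap = detection.detect_frame(
                model, frame, window=cfg.window, stride=cfg.stride,
                threshold=cfg.score_threshold, sigma=cfg.sigma,
                rebin_threshold=cfg.rebin_threshold, min_area_px=cfg.min_area_px,
            )
            bmaps[day] = bmap
            for reg in detection.extract_regions(bmap, with_contours=False):
                regions_rows.append(
                    (well, day, reg.region_id, reg.area_px,
                     reg.centroid[1], reg.centroid[0], *reg.bbox)
                )
        pd.DataFrame(
            regions_rows,
            columns=["well", "day", "region_id", "area_px", "centroid_x",
                     "centroid_y", "bbox_r0", "bbox_c0", "bbox_r1", "bbox_c1"],
        ).to_csv(out_dir / f"regions_well{well}.csv", index=False)

        label_maps: dict[int, np.ndarray] = {}
        prior = None
        params = segment_track.RandomWalkerParams(beta=cfg.rw_beta)
        for day in sorted(bmaps):
            if day > cfg.seed_day and prior is None:
                prior = np.zeros(bmaps[day].mask.shape, dtype=np.uint16)
            label_maps[day] = segment_track.segment_frame(
                bmaps[day], frames[day], day=day, seed_day=cfg.seed_day,
                prior_labels=prior, params=params,
            )
            prior = label_maps[day] if label_maps[day].any() else prior

        tracks = segment_track.link_tracks(
            label_maps, min_overlap=cfg.min_overlap, seed_day=cfg.seed_day
        )
        curves = [segment_track.growth_curve(t) for t in tracks if t.regions]
        rows = [
            (well, c.track_id, int(d), int(a))
            for c in curves
            for d, a in zip(c.days, c.areas)
        ]
        pd.DataFrame(rows, columns=["well", "track_id", "day", "area_px"]).to_csv(
            out_dir / f"curves_well{well}.csv", index=False
        )
        all_curod.extend(curves)
        summary["wells"][well] = {
            "n_frames": len(frames),
            "n_tracks": len(tracks),
        }

    results = hmm
    if picking_days is not None and results is None:
        usable = [c for c in all_curod if c.track_id in picking_days]
        seqs = [phase_model.extract_features(c) for c in usable]
        labels = [
            phase_model.make_stage_labels(c, picking_days[c.track_id]) for c in usable
        ]
        mdl = phase_model.GrowthPhaseHMM(seqs, labels, n_states=cfg.n_states)
        results = mdl.fit(n_restarts=cfg.n_restarts, seed=cfg.rng_seed)
        results.save(out_dir / "phase_model.json")
    if results is not None:
        for c in all_curod:
            seq = phase_model.extract_features(c)
            d = results.picking_decision(seq, threshold=cfg.picking_threshold)
            decisions_rows.append(
                (c.track_id, d.trigger_day, d.overgrowth_risk)
            )
        pd.DataFrame(
            decisions_rows, columns=["track_id", "trigger_day", "overgrowth_risk"]
        ).to_csv(out_dir / "picking_decisions.csv", index=False)
        summary["n_decisions"] = len(decisions_rows)

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary
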