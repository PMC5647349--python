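"""Shared fixtures: synthetic scenes, a trained texture model, fitted HMMs.

Everything is generated programmatically with fixed seeds; expensive
artifacts are session-scoped so the whole suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from colonyscope.classifier import TrainConfig, train
from colonyscope.detection import BinaryMap
from colonyscope.phase_model import (
    GrowthPhaseHMM,
    extract_features,
    make_stage_labels,
)
from colonyscope.preprocess import autolevels
from colonyscope.synth import (
    GrowthParams,
    SceneConfig,
    generate_cohort_curves,
    generate_patch_dataset,
    generate_scene,
)


@pytest.fixture(scope="session")
def small_scene():
    """768x768, 3 colonies with fixed growth laws; fast to segment."""
    gp = [
        GrowthParams(4.0e4, 0.55, 8.0),
        GrowthParams(3.2e4, 0.5, 8.5),
        GrowthParams(3.6e4, 0.6, 7.5),
    ]
    cfg = SceneConfig(image_size=(768, 768), n_colonies=3, growth_params=gp, rng_seed=2)
    frames, truth = generate_scene(cfg)
    return cfg, frames, truth


@pytest.fixture(scope="session")
def default_scene():
    """Default-size scene used by the end-to-end detection checks."""
    cfg = SceneConfig(rng_seed=5)
    frames, truth = generate_scene(cfg)
    return cfg, frames, truth


@pytest.fixture(scope="session")
def normalized_default_frames(default_scene):
    _, frames, _ = default_scene
    return [autolevels(f) for f in frames]


@pytest.fixture(scope="session")
def trained_model(default_scene, normalized_default_frames):
    """Texture model trained on 500 patches/class of separable texture."""
    _, _, truth = default_scene
    patches = generate_patch_dataset(normalized_default_frames, truth, 500, rng_seed=9)
    return train(patches, TrainConfig(seed=7))


def coverage_bmap(truth_mask: np.ndarray, day: int, stride: int = 48,
                  window: int = 96, coverage: float = 0.7) -> BinaryMap:
    """Detection oracle: union of windows with >= ``coverage`` colony
    fraction -- mirrors the trained detector's geometry without its cost."""
    mask = truth_mask > 0
    H, W = mask.shape
    out = np.zeros_like(mask)
    for y in range(0, H - window + 1, stride):
        for x in range(0, W - window + 1, stride):
            if mask[y : y + window, x : x + window].mean() >= coverage:
                out[y : y + window, x : x + window] = True
    return BinaryMap(mask=out, day=day)


@pytest.fixture(scope="session")
def cohort():
    """100 synthetic growth curves with truth picking days."""
    curves, truth = generate_cohort_curves(100, rng_seed=11)
    return curves, truth


@pytest.fixture(scope="session")
def cohort_fit(cohort):
    """Phase HMM fitted on the cohort with clamped stage labels."""
    curves, truth = cohort
    picking = dict(zip(truth.track_id, truth.picking_day))
    fps = dict(zip(truth.track_id, truth.first_positive_day))
    seqs = [extract_features(c, fps[c.track_id]) for c in curves]
    labels = [make_stage_labels(c, picking[c.track_id], fps[c.track_id]) for c in curves]
    model = GrowthPhaseHMM(seqs, labels)
    results = model.fit(n_restarts=12, seed=3)
    return seqs, labels, results, picking
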