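"""Binary texture classifier over 96x96 bright-field patches.

The detection stage needs one primitive: given a 96x96 window of a
normalized frame, the probability that it shows iPSC colony texture.  The
model is a pluggable contract -- anything trainable on a CPU in minutes that
maps a patch to P(iPSC) will do.  Two backends are provided:

``"logistic"`` (default)
    Hand-crafted multi-scale texture features (local band energies, gradient
    and Laplacian statistics) followed by a standardized logistic regression.
    Deterministic, fast, and easily separates textures differing in
    correlation length and variance.
``"mlp"``
    The same features through a small multilayer perceptron.

Label convention follows the training-data layer of the field: class 0 is
iPSC texture, class 1 is non-iPSC (background / fibroblast).  To avoid double
negation, every probability this module reports is P(iPSC), i.e. the
probability of class 0.

Iterative corrective fine-tuning: misclassified windows flagged by a reviewer
are appended to the training set with increased weight and the model is
refit; the returned model is guaranteed to do at least as well on the
correction set as its predecessor.
"""

from __future__ import annotations

import io
import json
import pickle
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

PATCH_SIZE = 96

#: Gaussian scales (px) whose residual band energies form the core texture
#: features; chosen to bracket typical colony vs background correlation
#: lengths.
_BAND_SCALES = (1.0, 2.0, 4.0, 8.0)


@dataclass
class PatchSample:
    """One labelled training patch.

    label 0 = iPSC texture, 1 = non-iPSC; ``source`` records (well, day, x, y)
    of the window's top-left corner.
    """

    pixels: np.ndarray
    label: int
    source: tuple = ("", -1, -1, -1)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(
                f"patch must be {PATCH_SIZE}x{PATCH_SIZE}, got {self.pixels.shape}"
            )
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


def patch_features(pixels: np.ndarray) -> np.ndarray:
    """Texture feature vector of one patch (works on a batch too).

    Accepts (96, 96) or (n, 96, 96); returns (n_features,) or (n, n_features).
    """
    px = np.asarray(pixels, dtype=np.float64)
    single = px.ndim == 2
    if single:
        px = px[None]
    n = px.shape[0]
    feats = []
    feats.append(px.mean(axis=(1, 2)))
    feats.append(px.std(axis=(1, 2)))
    gy, gx = np.gradient(px, axis=(1, 2))
    feats.append(np.abs(gx).mean(axis=(1, 2)))
    feats.append(np.abs(gy).mean(axis=(1, 2)))
    lap = np.empty_like(px)
    for i in range(n):
        ndimage.laplace(px[i], output=lap[i])
    feats.append(np.sqrt((lap**2).mean(axis=(1, 2))))
    for s in _BAND_SCALES:
        smooth = np.empty_like(px)
        for i in range(n):
            ndimage.gaussian_filter(px[i], s, output=smooth[i])
        feats.append((px - smooth).std(axis=(1, 2)))
    out = np.stack(feats, axis=-1)
    return out[0] if single else out


@dataclass
class TrainConfig:
    backend: str = "logistic"
    seed: int = 0
    val_fraction: float = 0.2
    max_iter: int = 1000
    C: float = 1.0
    hidden: tuple[int, ...] = (32,)
    threshold: float = 0.5


@dataclass
class TextureModel:
    """Trained patch classifier: opaque estimator + training provenance.

    Keeps its (featurized) training set so corrective fine-tuning can refit;
    serializes to a single artifact with a JSON metadata header and reloads
    with bit-identical predictions.
    """

    pipeline: Pipeline
    threshold: float = 0.5
    metadata: dict = field(default_factory=dict)
    train_X: np.ndarray | None = None
    train_y: np.ndarray | None = None
    train_w: np.ndarray | None = None

    # -- prediction -------------------------------------------------------
    def predict_proba_patches(self, patches: np.ndarray) -> np.ndarray:
        """P(iPSC) for a batch of patches, shape (n, 96, 96) -> (n,)."""
        patches = np.asarray(patches)
        if patches.ndim == 2:
            patches = patches[None]
        if patches.shape[1:] != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"patches must be (n, {PATCH_SIZE}, {PATCH_SIZE})")
        X = patch_features(patches)
        proba = self.pipeline.predict_proba(X)
        ipsc_col = list(self.pipeline.classes_).index(0)
        return proba[:, ipsc_col]

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        header = {
            "format": "colonyscope-texture-model",
            "version": 1,
            "patch_size": PATCH_SIZE,
            "threshold": self.threshold,
            "metadata": self.metadata,
        }
        buf = io.BytesIO()
        pickle.dump(
            {
                "pipeline": self.pipeline,
                "train_X": self.train_X,
                "train_y": self.train_y,
                "train_w": self.train_w,
            },
            buf,
        )
        with open(path, "wb") as fh:
            fh.write(json.dumps(header).encode() + b"\n")
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path) -> "TextureModel":
        with open(path, "rb") as fh:
            header = json.loads(fh.readline().decode())
            payload = pickle.load(fh)
        if header.get("format") != "colonyscope-texture-model":
            raise ValueError(f"not a texture model file: {path}")
        return cls(
            pipeline=payload["pipeline"],
            threshold=header["threshold"],
            metadata=header["metadata"],
            train_X=payload["train_X"],
            train_y=payload["train_y"],
            train_w=payload["train_w"],
        )


def _make_pipeline(config: TrainConfig) -> Pipeline:
    if config.backend == "logistic":
        clf = LogisticRegression(C=config.C, max_iter=config.max_iter)
    elif config.backend == "mlp":
        clf = MLPClassifier(
            hidden_layer_sizes=config.hidden,
            max_iter=config.max_iter,
            random_state=config.seed,
        )
    else:
        raise ValueError(f"unknown backend {config.backend!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _fit(config: TrainConfig, X, y, w) -> Pipeline:
    pipe = _make_pipeline(config)
    if config.backend == "mlp":
        # MLPClassifier has no sample_weight support; replicate heavy samples.
        reps = np.maximum(1, np.rint(w).astype(int))
        idx = np.repeat(np.arange(len(y)), reps)
        pipe.fit(X[idx], y[idx])
    else:
        pipe.fit(X, y, clf__sample_weight=w)
    return pipe


def train(patches: Sequence[PatchSample], config: TrainConfig | None = None) -> TextureModel:
    """Fit a texture model; deterministic given the config seed.

    Raises ``ValueError`` unless both classes are present.  Held-out accuracy
    on a ``val_fraction`` split is recorded in the model metadata, then the
    final model is refit on all samples.
    """
    config = config or TrainConfig()
    patches = list(patches)
    if not patches:
        raise ValueError("empty patch set")
    y = np.array([p.label for p in patches])
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes (0 and 1) present")
    X = patch_features(np.stack([p.pixels for p in patches]))
    w = np.ones(len(y))

    rng = np.random.default_rng(config.seed)
    n_val = int(round(config.val_fraction * len(y)))
    perm = rng.permutation(len(y))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    heldout_acc = None
    if n_val and len(np.unique(y[tr_idx])) == 2:
        pipe = _fit(config, X[tr_idx], y[tr_idx], w[tr_idx])
        heldout_acc = float((pipe.predict(X[val_idx]) == y[val_idx]).mean())

    pipe = _fit(config, X, y, w)
    meta = {
        "backend": config.backend,
        "seed": config.seed,
        "n_per_class": {int(k): int(v) for k, v in zip(*np.unique(y, return_counts=True))},
        "heldout_accuracy": heldout_acc,
        "rounds": 0,
    }
    return TextureModel(
        pipeline=pipe,
        threshold=config.threshold,
        metadata=meta,
        train_X=X,
        train_y=y,
        train_w=w,
    )


def predict(model: TextureModel, patch: np.ndarray) -> float:
    """P(iPSC texture) for one 96x96 patch."""
    patch = np.asarray(patch)
    if patch.shape != (PATCH_SIZE, PATCH_SIZE):
        raise ValueError(f"patch must be {PATCH_SIZE}x{PATCH_SIZE}, got {patch.shape}")
    return float(model.predict_proba_patches(patch[None])[0])


def _error_rate(model: TextureModel, X: np.ndarray, y: np.ndarray) -> float:
    proba = model.pipeline.predict_proba(X)
    ipsc = proba[:, list(model.pipeline.classes_).index(0)]
    pred = np.where(ipsc >= model.threshold, 0, 1)
    return float((pred != y).mean())


def fine_tune(
    model: TextureModel,
    corrections: Sequence[PatchSample],
    config: TrainConfig | None = None,
    correction_weight: float = 5.0,
    max_boost_rounds: int = 5,
) -> TextureModel:
    """Corrective refit on reviewer-flagged windows.

    The corrections join the stored training set with boosted weight and the
    model is refit.  The weight is doubled until the refit model's error rate
    on the correction set is no worse than the current model's; if boosting
    alone cannot achieve that, the better of the two models on the correction
    set is returned, so the contract
    ``error_new(corrections) <= error_old(corrections)`` always holds.
    """
    corrections = list(corrections)
    if not corrections:
        raise ValueError("corrections must be non-empty")
    if model.train_X is None:
        raise ValueError("model carries no training set; cannot fine-tune")
    config = config or TrainConfig(
        backend=model.metadata.get("backend", "logistic"),
        seed=model.metadata.get("seed", 0),
        threshold=model.threshold,
    )
    Xc = patch_features(np.stack([p.pixels for p in corrections]))
    yc = np.array([p.label for p in corrections])
    old_err = _error_rate(model, Xc, yc)

    X = np.vstack([model.train_X, Xc])
    y = np.concatenate([model.train_y, yc])
    weight = correction_weight
    best = None
    for _ in range(max_boost_rounds):
        w = np.concatenate([model.train_w, np.full(len(yc), weight)])
        pipe = _fit(config, X, y, w)
        cand = TextureModel(
            pipeline=pipe,
            threshold=model.threshold,
            metadata={**model.metadata, "rounds": model.metadata.get("rounds", 0) + 1},
            train_X=X,
            train_y=y,
            train_w=w,
        )
        err = _error_rate(cand, Xc, yc)
        if best is None or err < best[0]:
            best = (err, cand)
        if err <= old_err:
            return cand
        weight *= 2.0
    # Boosting never matched the old model on the corrections: keep whichever
    # model is better there (ties favour the refit model's enlarged set).
    return best[1] if best[0] <= old_err else model
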