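# colonyscope

Label-free detection, time-lapse tracking and picking-time prediction of
induced pluripotent stem cell (iPSC) colonies in bright-field microscopy.

During somatic reprogramming, nascent iPSC colonies acquire a distinctive
fine-grained texture long before they are ready to harvest. Picking a colony
too early or too late costs quality and consistency, and the judgement is
traditionally made by trained specialists reading wells by eye. colonyscope
implements the computational alternative end to end:

1. **Normalization** — a percentile-clipped linear stretch ("autolevels")
   removes illumination differences between frames; it is exactly invariant
   to positive affine intensity changes.
2. **Sliding-window texture classification** — a 96 × 96 px window slides
   across the frame; a trainable binary classifier scores each window with
   P(iPSC texture). Label convention: class 0 = iPSC, class 1 = non-iPSC.
3. **Binary-map post-processing** — fill enclosed holes, Gaussian-blur the
   0/1 mask, re-binarize, and drop connected components smaller than a
   minimum area (sparse residuals).
4. **Seeded segmentation and tracking** — up to a *seed day* (default
   day 12) colonies are connected components; later, boundaries are refined
   with a semi-supervised random walker (edge weights
   `w = exp(-beta * dI^2)`, the combinatorial Dirichlet problem) seeded by
   the previous day's labels, and colonies are registered backward in time
   by maximal pixel overlap.
5. **Growth-phase HMM** — each track's area-versus-day curve yields four
   features per day (first difference, second difference, area, days since
   first appearance). After screening abnormal growers by the mean
   first-order difference over days 10–20, a 4-state left-to-right
   Gaussian-emission HMM is trained by multi-restart Baum–Welch with two
   stage blocks clamped from expert picking-day labels (first stage: track
   start to two days after first appearance; mature stage: one day before
   the picking day to the end).
6. **Picking trigger** — the forward–backward posterior of the mature state
   is tracked per day; the first day it reaches a threshold (default 0.3,
   calibratable from expert picks) triggers picking. A posterior saturating
   at 1 flags overgrowth/differentiation risk.

A synthetic scene generator (textured colonies on textured background,
logistic area growth, a co-located fluorescence reporter channel, exact
ground-truth masks and picking days) makes every stage testable without any
microscopy data.

## Worked example

```python
import numpy as np
from colonyscope import (SceneConfig, generate_scene, generate_patch_dataset,
                         generate_reporter, autolevels, train, TrainConfig,
                         detect_frame, mask_metrics, pearson_overlap,
                         generate_cohort_curves, extract_features,
                         make_stage_labels, GrowthPhaseHMM)

# synthetic well: 16 daily frames (days 7..22), 3 colonies, exact truth
frames, truth = generate_scene(SceneConfig(rng_seed=5))
frames = [autolevels(f) for f in frames]

# train the texture classifier on 500 patches per class
patches = generate_patch_dataset(frames, truth, n_per_class=500, rng_seed=9)
model = train(patches, TrainConfig(seed=7))
print(f"held-out window accuracy: {model.metadata['heldout_accuracy']:.3f}")

# detect colonies on a mature frame and validate against the truth masks
# and the simulated pluripotency reporter
frame20 = next(f for f in frames if f.day == 20)
bmap = detect_frame(model, frame20, stride=48)
m = mask_metrics(bmap, truth.masks[20])
print(f"day 20: precision={m.precision:.3f} recall={m.recall:.3f}")
reporter = generate_reporter(truth.masks[20], reporter_snr=10.0,
                             coverage_fraction=0.9, rng_seed=3)
print(f"detection vs reporter Pearson r = "
      f"{pearson_overlap(bmap, reporter).pearson_r:.3f}")

# growth-phase model on a 100-track cohort with expert picking labels
curves, cohort = generate_cohort_curves(100, rng_seed=11)
picking = dict(zip(cohort.track_id, cohort.picking_day))
seqs = [extract_features(c) for c in curves]
labels = [make_stage_labels(c, picking[c.track_id]) for c in curves]
results = GrowthPhaseHMM(seqs, labels).fit(n_restarts=16, seed=3)
d = results.picking_decision(seqs[0])
print("mature posterior:", np.round(results.mature_posterior(seqs[0]), 3))
print(f"track 1: trigger day {d.trigger_day} "
      f"(truth picking day {picking[1]})")
print(results.summary())
```

prints

```
held-out window accuracy: 0.995
day 20: precision=0.928 recall=0.982
detection vs reporter Pearson r = 0.880
mature posterior: [0. 0. 0. 0. 0. 0. 0.444 1. 1. 1. 1. 1. 1. 1.]
track 1: trigger day 15 (truth picking day 16)
Growth-phase HMM results
================================================================
states: 4 (left_to_right)   sequences: 100
restarts: 16   seed: 3
log-likelihood: -3559.1109   EM iterations: 38

Emission means (original units)
state        d_area       dd_area          area   growth_days
    1       3300.19       1978.81       9915.08          1.09
    2      10907.25       3582.30      29723.10          3.58
    3      20135.00       5130.13      62822.44          5.32
    4      14962.57      -2264.42     157597.34         10.12
...
```

The precision/recall/Pearson numbers quantify how well the label-free
detector recovers the planted colonies and agrees with the (held-out)
reporter channel; the HMM summary shows the four growth phases the model
found — slow appearance, two acceleration periods, and a large
decelerating mature phase — and the trigger day is where the mature-phase
posterior first crosses 0.3.

There is also a CLI (`colonyscope synth|preprocess|train|detect|track|
phases|pick|eval|run`) operating on directories of `well{W}_day{D}.tif`
frames; see `colonyscope --help`.

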