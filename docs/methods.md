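# Methods

This note documents the models and procedures implemented in colonyscope,
the parameters that matter, what the synthetic data does and does not
emulate, and the numerical and design choices that were genuinely open.

## Detection model

Colonies are recognized by *texture*, not by cell-level morphology: in
bright-field images individual cell boundaries are fuzzy and overlapping,
but an iPSC colony's interior has a characteristic fine-grained appearance
that differs statistically from fibroblast/background texture. Detection
therefore classifies fixed 96 × 96 px windows, slid from the top-left corner
at a configurable stride (default 96, i.e. a non-overlapping mosaic;
stride 48 is used where finer boundaries matter). A right/bottom remainder
smaller than one window is not scored — a documented information loss in
lieu of padding.

**Normalization.** Every frame passes through a percentile-clipped linear
stretch (`autolevels`, defaults: 1st → output min, 99th → output max,
full 16-bit output range). The operation is exactly invariant to positive
affine intensity maps, which is its purpose: it removes illumination
differences so the classifier sees comparable inputs. It is idempotent up
to rounding and the percentile order-statistic granularity (~range/n_pixels)
at the clip boundaries.

**Classifier.** The window classifier is a pluggable contract: anything
mapping a 96 × 96 patch to P(iPSC), trainable on one CPU in minutes. The
default backend extracts nine texture features per patch (mean, standard
deviation, mean |gradient| in x and y, Laplacian energy, and residual band
energies at Gaussian scales 1, 2, 4, 8 px — the scales bracket the
correlation lengths that distinguish colony from background texture) and
fits a standardized logistic regression; an MLP backend sits behind the same
contract. Class labels follow the field's inverted convention at the data
layer (0 = iPSC, 1 = non-iPSC) but all reported probabilities are P(iPSC)
to avoid double negation. Corrective fine-tuning appends reviewer-flagged
windows to the stored training set with boosted weight (doubled until the
refit model is at least as good on the corrections as its predecessor, with
a fall-back to whichever model is better there), mirroring the
expert-in-the-loop rounds used in practice.

**Post-processing.** The fixed chain is: fill enclosed holes → Gaussian
blur of the 0/1 mask (σ default 48 px ≈ half a window) → re-binarize at 0.5
→ remove 8-connected components with area < 96² px (one window). σ and the
re-binarization threshold are not dictated by any external constraint and
are exposed as configuration; the minimum area says that anything smaller
than a single detection window is a fragmented residual.

## Segmentation and tracking

Up to the seed day (default 12; a protocol-specific configuration, not a
constant) colony labels are the 8-connected components of the detection
map. For more mature frames the blocky detection outline is refined with a
semi-supervised random walker: each unlabeled pixel receives the label whose
seeds a random walk on the 4-connected lattice, with edge weights
`w = exp(-beta * dI^2)` (β default 130), reaches first. The probabilities
solve the combinatorial Dirichlet problem; the implementation solves the
sparse Laplacian system directly and verifies the residual against a
tolerance (default 1e-6), and is tested to 1e-6 against an independent
absorbing-Markov-chain fundamental-matrix oracle on all small grids.

**What image the walker sees.** The walker needs boundaries that are
*level steps*. A colony that differs from background in texture rather than
brightness has stronger gradients inside than at its boundary, which would
make the colony interior resistive and systematically shrink labels.
Refinement therefore runs on a local texture-energy transform: the local
standard deviation of intensity (5 px window, smoothed σ 1.5 px), robustly
normalized to [0, 1] by its 5th–95th percentiles so both plateaus saturate
and stay conductive while the colony edge remains a steep, strongly
resistive step the boundary snaps to. On brightness-contrasted data the raw
intensity image can be passed instead.

**Seeding.** Colony seeds are the previous day's labels eroded by 5 px;
every prior label with support in today's detection map is seeded, so two
colonies whose detections merge keep separate identities. For detection
components that touch exactly one prior label, the component's deep
interior (distance > 50 px from the component boundary, safely inside the
blocky overshoot) is added as seed so labels keep up with fast growth.
Components touching no prior label are new colonies (they may first appear
after the seed day) and are seeded by their own interior. Background seeds
are the complement of the detection map dilated by 15 px; labels are
confined to that envelope. A prior colony with no support in today's map is
emitted as an empty region, not an error.

**Tracking.** Label maps are linked backward from the final day: a region
links to the previous day's region of maximal pixel overlap, accepted when
overlap / min(area) ≥ 0.3; ties break toward the larger previous region,
then the lower region id, making linking independent of enumeration order.
Tracks originate from final-frame regions, plus unclaimed seed-day regions.
The area-versus-day series of a track is its growth curve; missing days
stay absent rather than being interpolated.

## Growth-phase model

**Abnormality screen.** The screening statistic is the mean of
consecutive-day area differences over days 10–20. The default acceptance
band is the robust Gaussian-equivalent 5th–95th percentile estimate,
median ± 1.645 · 1.4826 · MAD, of the cohort's statistics: a robust
estimate still recovers the normal subpopulation's band when a minority of
outliers contaminates the cohort, whereas empirical cohort quantiles are
rank-bound and can never reject more than ~5% per side. Empirical
quantiles and explicit bounds remain available. Curves with fewer than two
points in the window are rejected with an explicit reason.

**Features.** Per tracked day: f1 = first difference of area, f2 = first
difference of f1, f3 = area (px²), f4 = days since the track's first
positive day. Undefined boundary differences are set to 0 (dropping the
first days is available behind a flag); differences are absolute by
default, with a relative (Δarea/area) option. Features are z-scored over
the training set and the transform is stored in the model.

**Model.** A 4-state hidden Markov model with left-to-right topology
(upper-triangular transitions — growth phases progress; a full matrix is
available behind a flag) and diagonal-Gaussian emissions over the four
standardized features. Gaussians are the natural choice for continuous
features at small sample sizes; no heavier emission family is warranted by
the data volumes involved. Expert picking-day annotations clamp two stage
blocks during training — first stage from the track start to two days
after the first positive day, mature stage from one day before the picking
day to the end — by masking inadmissible states in the E-step. The
unlabelled middle is initialized by splitting it into two periods of
similar length (states 2 and 3).

**Training.** Multi-restart Baum–Welch: each restart draws jittered
segment-based initial parameters from a deterministic per-restart seed, EM
iterates until the log-likelihood gain falls below 1e-6 or 500 iterations,
and the best-likelihood restart wins. The API default honours 2000
restarts; the test suite and the acceptance script use 12–24, which on
these cohort sizes reach the same solution (the clamped labels make the
likelihood surface benign) in seconds. Variances are floored at 1e-6
(standardized scale) every M-step; transition mass on allowed edges is
floored at 1e-12 before renormalization so clamped sequences never acquire
zero probability mid-EM. Forward–backward runs in a scaled/offset domain
(per-step normalization plus per-day log-offsets), exact to enumeration at
1e-10 on small instances; Viterbi breaks ties toward the lower state index.

**Decoding and picking.** The per-day mature score is the forward–backward
posterior of the last state. The trigger day is the first day the score
reaches the picking threshold (default 0.3); a literal "closest to the
threshold" rule is available, as the operational phrasing of the rule
admits both readings. A score saturating at ≥ 0.999 sets an
overgrowth-risk flag. Threshold calibration minimizes the mean
|trigger − expert| over a 0.01-step grid, ties to the smaller threshold;
with steplike posteriors a whole threshold interval is cost-equivalent and
the tie rule returns its smallest member — recovery of a specific
threshold is only identifiable from graded score series.

## Synthetic data

The generator emulates exactly the statistics the pipeline depends on:

- **Textures**: band-limited correlated Gaussian noise; background mean
  28000, sd 1200, correlation length 8 px; colony mean 30000, sd 3600,
  correlation length 1.5 px (16-bit scale). Separability is a knob —
  tests use contrasts a competent classifier should find easy, so
  passing them validates the pipeline's mechanics, not classifier
  performance on real microscopy.
- **Growth**: per-colony logistic area
  `A(d) = K / (1 + ((K−A0)/A0) e^{−r(d−onset)})`, A0 = 2% of K; defaults
  K ~ U(1.4e5, 2.4e5) px², r ~ N(0.55, 0.05) /day, onset ~ U(7, 9),
  one frame per day over days 7–22. Colonies are discs at fixed centres
  (growth is monotone, footprints nested and pairwise disjoint by
  construction, with a bounded-retry placement that raises when disjoint
  placement is impossible). A colony is rendered once its area reaches
  6500 px² (~70% of one window), so "first positive day" is well defined
  at the detection window scale. The expert picking day is the first day
  the noise-free logistic reaches 60% of K — an arbitrary but fixed
  definition standing in for human labels.
- **Reporter**: a fluorescence channel bright over a spatially coherent
  subset of each colony covering a configurable fraction (default 0.9,
  reflecting that reporter systems leave a minority of cells unlabelled)
  plus Gaussian noise at a configurable SNR.
- **Patch sampling**: positives are windows fully inside a colony;
  negatives are anywhere else — by default 70% pure background and 30%
  boundary-straddling windows with ≤ 50% colony coverage. Teaching the
  classifier to reject majority-background windows moves the window
  decision toward majority coverage and sharpens detection boundaries;
  with background-only negatives the decision fires near 25% coverage and
  systematically over-segments.
- **Curve cohorts**: the same logistic law plus 3% multiplicative
  measurement noise, without rendering, for HMM-scale cohorts; overgrowers
  are planted by scaling the growth statistic 3×.

Not emulated: phase-contrast optics, single cells, colony merging or
splitting, vignetting, focus drift, or any difference between murine and
human reprogramming systems. Passing tests therefore demonstrate the
pipeline's correctness and internal consistency, not its recognition rate
on real wells.

## Problem sizes

Default scenes are 1536 × 1536 px with 3 colonies — large enough that a
mature colony spans many windows, small enough that the full study
(generation, training on 500 patches/class, stride-48 detection, reporter
validation, a 100-track cohort fit, 200-sequence parameter recovery, and
all exactness cross-checks) completes in well under a minute on one CPU.
Cohorts use 100 tracks with 16 EM restarts; exact-inference checks use 100
random instances with ≤ 4 states and length ≤ 8 (65536 paths enumerated).

## Known limitations

- The "modified" part of the original Autolevels preprocessing is not
  public; the implementation is a standard percentile stretch and is
  documented as such.
- Random-walker systems with edge exponents β·ΔI² beyond ~40 are
  numerically singular in double precision (weights underflow); with
  normalized intensities and the default β this regime is not reached, but
  pathological inputs raise a residual error rather than returning a bad
  solution.
- Backward overlap linking handles neither merges nor splits; a merged
  detection keeps both identities only through the random-walker seeds.
- The trigger day is typically the day *before* the truth picking day
  (the mature stage is labelled from one day ahead of the pick), which is
  inside the ±1-day window used throughout but means the trigger is a
  leading, not centred, estimate.
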