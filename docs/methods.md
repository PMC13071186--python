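# Methods

`arenawalk` implements a complete analysis chain for open-field locomotor
assays of a single walking insect (the motivating system is a small
stored-product beetle) in a circular dish, from raw frames to
dose-response and machine-learning summaries. This note records the
models, the defaults and why, and the limits of what the synthetic tests
demonstrate.

## Synthetic arena recordings (`synthgen`)

The generator produces recordings with exact ground truth so that every
downstream stage can be scored against a known answer.

**Motion model.** A correlated random walk gated by a two-state stop/go
Markov chain. Per frame: the chain updates first (go→stop with
probability `stop_rate`, stop→go with `go_rate`); on moving frames the
heading receives a wrapped-normal increment with standard deviation
`1/sqrt(turn_kappa)` rad and the step length is gamma-distributed with
mean `mean_speed / fps` (coefficient of variation `speed_dispersion`,
default 0.3). Long-run mean moving speed therefore converges to
`mean_speed`, which the tests verify to 5%.

**Wall interaction.** Inside a wall-approach band (the outer ~15 px of
the reachable disc) the walker steers along the wall with probability
`wall_bias` per frame; otherwise a step that would cross the confinement
limit is reflected about the local tangent. The wall-following heading
is tilted 20° outward of the tangent so that followers ride the
confinement limit with their antennae inside the 1-mm contact band — a
pure tangent heading would keep the antenna tips just short of the band
and thigmotaxis would be structurally unobservable. Antenna tips that
would cross the dish wall are clamped just inside it (flexion on
contact).

**Body and rendering.** The body is two overlapping dark ellipses (head
lobe strictly smaller than the back lobe) on a light background,
rendered at a desk-scale calibration of 0.11 mm/px (half the reference
rig's full-resolution 0.055 mm/px): dish radius 250 px = 27.5 mm, frames
540×960, body ≈ 3.6 mm. Grey levels default to background 120 and body
15 so that the fixed binarisation threshold of 60 crosses the blurred
body edge near its true boundary; with a much lighter background the
threshold-60 contour would sit ~1 px inside the silhouette and
segmentation IoU against truth would be bounded near 0.75 regardless of
implementation. Additive Gaussian pixel noise (default sd 5 grey
levels) is seeded and reproducible.

**Presets.** Three motion presets model an untreated control and two
sublethal-exposure phenotypes, with treated groups slower, stoppier and
less wall-bound (control / mild / strong: mean speed 6.0 / 4.2 / 2.5
mm/s; wall bias 0.70 / 0.50 / 0.30; stop rate 0.010 / 0.020 / 0.030 per
frame at 60 fps). The mild preset is deliberately intermediate, so
control-vs-strong is an easier classification than mild-vs-strong.
Effect sizes are free parameters of the generator — the reference assay
reports significance, not magnitudes — chosen once to give clearly
ordered group means under 30-s recordings. Individuals within a group
get log-normally jittered mean speeds (cv 0.3) to emulate biological
heterogeneity; without it, any group comparison saturates at 100%
accuracy and the classifier ordering becomes untestable.

**What the generator does not model.** Photorealistic appearance,
antennal kinematics (tips are rigid offsets at ±25° from the body axis,
1 antenna length ahead of the head lobe), grooming/rearing postures,
occlusion, illumination drift, and mechanistic sex differences (sex is a
label only). Passing tests therefore demonstrate correctness of the
measurement chain, not detector robustness on real video.

## Automatic head/back labelling (`autolabel`)

Frames are converted to grey, blurred with a 5×5 Gaussian (sigma from
the kernel by the common `0.3((k-1)/2 - 1) + 0.8` rule) and binarised at
grey level 60, dark side as foreground. The largest component is the
insect; its blob (cropped to its bounding box by default) is eroded with
a 3×3 square element up to 10 times until at least two components of
≥ 5 px² remain. The two largest are the body parts — smaller = head —
and every pre-erosion blob pixel is then assigned to the nearer eroded
centroid (a two-site Voronoi partition) so that the reported boxes and
centroids describe whole lobes, not eroded cores. Equal-area ties break
toward the component leading along a supplied motion direction, else by
scan order. An optional fallback splits an unerodable blob by the line
through the centroid perpendicular to the principal axis; it is off by
default to keep the strict erosion semantics.

Dataset export writes one normalised `class cx cy w h` text annotation
per frame with a seeded shuffle split; counts use floor allocation of
the validation and test ratios with the remainder to train, which maps
1200 frames at 70:20:10 onto exactly 840/240/120. Detection scoring
matches predictions to truths greedily by descending IoU within frame
and class (TP at IoU ≥ 0.5 by default), computes precision, recall, F1,
accuracy (TN = 0 in detection) and AP as the area under the
all-point-interpolated precision–recall curve; `map50` averages AP over
the two classes. With no truths and no predictions anywhere all metrics
are 1 by convention.

## Tracking and conditioning (`tracking`)

The labeller runs frame by frame; failures get likelihood 0 and interior
gaps of at most `max_gap` (default 5) frames are filled linearly. The
body centroid is the head/back midpoint. Conditioning follows the usual
pose-table chain: a centred 3-frame rolling mean (endpoints truncated),
then a velocity low-pass: walking a forward pass, any displacement from
the last accepted position implying more than `speed_cap` (default
50 mm/s, a generous ceiling for small beetles) is a tracking error — the
frame is flagged, removed and re-interpolated. The stop-bout threshold
is 0.5 mm/s; both thresholds are configurable because the literature
value is taxon-dependent. Segment extraction cuts exactly
`duration × fps` frames, centred by default (the reference protocol
analyses the central 2 min of a 5-min recording to avoid acclimation and
handling transients).

## Arena features (`features`)

The dish circle comes from three digitised rim points (circumcentre).
Distances and speeds convert via the px→mm factor; speed is per-frame
displacement × fps, acceleration the per-frame speed difference × fps
(summarised as mean |a|, since the protocol names "acceleration" without
a statistic). Stop time counts frames below the stop threshold, with
frame 0 inheriting the first displacement's speed so every frame
contributes. Zone preference splits the dish at 2/3 of the radius
(boundary counts as inner); wall contact holds where a part's distance
to centre is at least `R − 1 mm` — a band, since exact equality has
measure zero. A thigmotaxis *event* is an entry of an antenna tip into
the band (starting in contact counts once), debounced by a 2-frame
minimum dwell so single-frame jitter does not inflate counts;
contact *time* sums all contact frames undebounced. Body angle is
`atan2` of the back→head vector with the image y axis flipped, so
counter-clockwise (a left turn viewed from above) is positive; wrapped
frame-to-frame differences accumulate separately by sign and each 2π of
accumulated rotation in one direction is one full left or right turn.
The default classifier input is the ten-feature row: distance, mean and
max speed, mean |acceleration|, stop time, inner and outer time, wall
contact time, and left/right thigmotaxis counts; turn counts and
cumulative rotation are reported alongside.

## Dose-response (`doseresp`)

Mortality follows a binomial GLM with probit link on log10 dose, fitted
by maximum likelihood (statsmodels). The exact likelihood handles 0% and
100% kill groups without empirical-probit corrections. Abbott's
correction for control mortality is available but off by default.
Goodness of fit is the Pearson chi-square on `n_doses − 2` df. LC_p is
`10^((probit(p) − a)/b)` with delta-method confidence limits on the
log10 scale. `probit_line_through` builds the exact line through two
(LC, p) anchors for internal-consistency checks — two published LC
values pin down the whole curve.

The simulation-recovery test (LC50 within 10% of truth in ≥ 90% of 200
replicates at 7 doses × 30 animals) uses a steep compound — slope 8
probits per log10 dose with LC50 on a ladder dose. This is a property of
assay information, not of the estimator: on a two-fold dose ladder with
30 animals per dose, the Cramér–Rao bound on log10 LC50 for a shallow
compound (slope ≈ 1.8) is ≈ 0.035, close to the 10% target of 0.041, so
no estimator can reach a 90% hit rate there; in the steep, dose-centred
regime the maximum-likelihood fit does, which is what the test checks.

## Group statistics (`groupstats`)

Per feature: Shapiro–Wilk per group (delegated to scipy; constant groups
are degenerate, get p = NaN and force the nonparametric branch), then
Kruskal–Wallis with tie correction, then Dunn's pairwise z tests on
pooled ranks with the standard tie term, Holm-adjusted. The Holm family
is the set of pairwise comparisons within one feature, not across
features. Dunn p-values are two-sided.

## Classification and attribution (`classify`)

Stratified 4×4 nested cross-validation: the outer loop estimates
generalisation; per outer-training set an inner grid search selects
hyperparameters by mean accuracy. Grids: SVM C on the decade ladder
0.01–100 with linear and rbf kernels; random forest 20–300 trees × depth
2–5; KNN k in 3–15 odd. Candidates are ordered simplest-first (smaller
C, fewer and shallower trees, larger k) so score ties resolve toward the
simpler model; candidates infeasible for a tiny training fold (k above
the fold size) are skipped, and the inner fold count shrinks to the
smallest class when a demo-sized cohort demands it. Standardisation is
fitted inside each training portion only. Outer test predictions pool
into a single confusion matrix, from which accuracy, precision, recall
and F1 are computed (zero-denominator ratios are NaN with a warning).

Shapley attributions are exact: the value of a coalition S is the mean
model output over background rows with the features in S replaced by the
explained sample's values, all 2^d coalitions are enumerated (d ≤ 15
enforced; the ten-feature row gives 1024 coalitions), and each feature
receives its exactly weighted average marginal contribution, so
efficiency holds to machine precision. Group comparisons explain the
KNN model's class-1 neighbourhood proportion (a probability-like output;
hard-label attributions are step functions), per outer fold, against a
training background capped at 64 rows by seeded subsampling.

## Pipeline (`pipeline`, CLI `arenawalk`)

One YAML config with a single master seed drives all stages; every run
directory carries the config, an arena descriptor, per-stage outputs and
a manifest with a parameter hash sufficient to reproduce the run. The
feature table of a synthetic cohort is computed from ground-truth-derived
trajectories passed through the same conditioning chain as tracked
ones, while the frame-by-frame labeller + tracker is demonstrated and
scored against truth on a configurable subset of recordings; labelling
every frame of every video is the job of the detector network this
package's autolabeller bootstraps, and is out of scope here. Defaults
run a desk-scale cohort (3 groups × 2 sexes × 4, 30 s at 60 fps) in a
few minutes on one core.

## Numerical conventions and degenerate inputs

Pixel coordinates are image-style (origin top-left, y down); angles are
arena-style (y up). Boundary membership on the inner-zone circle counts
as inner. Angle differences wrap to (−π, π]. Coincident head/back carry
the previous angle forward, flagged invalid. Circle fitting rejects
collinear points at a relative tolerance of 1e-9. Export ratios must sum
to 1 within 1e-9. All randomness flows from explicit integer seeds;
identical seeds give bitwise-identical cohorts, trajectories and CV
splits.

## Known limitations

- The classical labeller assumes exactly one dark insect on a light
  background; multi-animal frames and non-circular arenas are out of
  scope.
- Antenna channels come from ground truth or an external keypoint table;
  the classical labeller fills head/back only.
- Synthetic acceptance results certify the measurement chain against its
  own generator, not detector performance on real video.
- Delta-method LC limits are symmetric on the log scale; Fieller limits
  are not implemented.
- Exact Shapley is exponential in the feature count by design; no
  sampling approximation is provided.
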