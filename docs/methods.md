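# Methods

This note documents the models, conventions and deliberate choices in
`actinseg`, in the spirit of the methods documentation of packages such
as scanpy or statsmodels.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic scene model

Real training data for this problem (STED images of phalloidin-stained
neurons with expert polygon labels) is not publicly deposited, so the
package ships a generator whose output has the statistical structure the
pipeline assumes, with exact ground truth.

A scene contains `n_processes` neurites, each a random cubic-spline
centerline crossing the field of view (control points walk monotonically
across one axis with bounded lateral steps, so curvature stays gentle),
swept to a tube of width drawn from `process_width_nm` (default 500–900
nm — the caliber range of proximal dendrites and thick axons at this
magnification).  Each centerline is partitioned by arc length:
the first `ring_fraction` carries transverse stripes
`0.5·(1 + cos 2πs/T)` in the arclength coordinate `s` (iso-phase lines
are locally perpendicular to the tangent), period `T` drawn from
`ring_period_nm` (default 180–190 nm); the next `fiber_fraction`
carries 1–4 longitudinal ridges at fixed normal offsets; the remainder
is low-contrast speckle that carries no label, mimicking unpolarised or
mixed signal.  The pattern image is convolved with a Gaussian PSF of
FWHM 60 nm (typical commercial STED performance; both PSFs are config
fields), scaled to
`peak_signal` photons over `background_level`, and subjected to Poisson
noise (optionally plus Gaussian read noise, or no noise for oracle
tests).  Marker channels are the process masks blurred with a 250 nm
FWHM Gaussian (confocal-like), with the same noise model; processes
alternate dendrite-like/axon-like roles.

Geometric edge case: a strongly curved or self-approaching centerline can
enclose a pocket whose nearest-arclength class assignment flips, leaving
a hole inside a class region.  The pattern there is ambiguous, so class
maps are kept simply connected: holes are filled and the filled pixels
join the mask of the nearest process.  This preserves two invariants at
once — class maps remain subsets of the union of process masks, and the
exterior-contour polygon annotations rasterize back to the class maps
bit-for-bit (the polygon dialect cannot express holes).

What the generator does *not* emulate: depletion photophysics, vectorial
PSFs, sample drift, labeling stochasticity, spectrin periodicity, 3-D
structure.  A green end-to-end test therefore establishes that the
pipeline recovers a known pattern mixture under realistic noise and
coarse labels — not that the shipped defaults match any particular
instrument.

### Weak labels

`precise` style traces exact pixel-boundary contours (union of unit
squares per connected component).  `polygon_box` style mimics an
expert's coarse boxes: the convex hull of the component, buffered by
`margin_nm` plus half a pixel plus the jitter amplitude, then
vertex-jittered uniformly within ±`jitter_nm`.  The extra buffer makes
coverage of the component robust to any jitter draw (jittering a convex
polygon's vertices inward by δ moves its edges inward by at most δ).
Defaults 60 nm margin / 40 nm jitter give boxes covering roughly 1.3–2×
the precise area, comparable to hand-drawn bounding boxes.

### Condition presets

Four presets emulate stimulation series used for activity-dependent
remodeling: ring/fiber centerline fractions (0.60, 0.10), (0.45, 0.25),
(0.30, 0.45), (0.10, 0.60).  Only the ordering (rings fall, fibers
rise with stimulation strength) is meaningful; the absolute values were
fixed once as plausible mid-range mixtures and are not tuned.

## Dataset conventions

* **Rasterization**: a pixel belongs to a polygon if its center
  (0-based, x = column) lies inside or on it; even-odd rule (equal to
  nonzero for the simple polygons of the dialect).
* **Crops**: stride = window − overlap (128 − 16 = 112 at full scale);
  when the stride tiling leaves a remainder, one extra window is
  anchored flush with the trailing edge so the whole image is covered —
  edge handling is a genuine design choice, and full coverage keeps
  training statistics consistent with tiled inference.
* **Class-imbalance filter**: a crop is kept iff the union of its label
  maps covers ≥ 1 % of the window area; 0 disables the filter (the
  axonal-dataset convention).
* **Normalization**: `m` = median of per-image minima, `M` = median of
  per-image maxima + 3·SD of those maxima with the *population*
  convention (ddof = 0) — the only reading consistent with a statistic
  of the maxima themselves.  The 0.8 factor compresses [m, M] onto
  [0, 0.8] (rather than widening the interval), leaving headroom so the
  intensity-scale augmentation rarely clips; the final clip to [0, 1]
  makes the map total.  Note normalization at factor 0.8 is *not*
  idempotent.
* **Augmentation**: flip up-down, flip left-right, intensity scale,
  gamma — each independently with p = 0.5; scale and gamma are drawn
  from U(0.8, 1.2) (mild ranges, exposed as arguments).  Flips act identically on label maps; intensity ops act
  on the image only.
* **Corruption**: omission removes `round(f·n)` instances per class
  uniformly without replacement; the crop population is *not*
  re-filtered afterwards, keeping the crop count constant so corruption
  levels differ only in supervision.  Dilation rasterizes and dilates
  with a disk of `round(r_nm / pixel_size)` pixels; sub-pixel radii warn
  and return the identity.

## Networks and training

Both networks are U-Net-style encoder-decoders: per resolution step,
[3×3 conv → batchnorm → ReLU] × 2 then 2×2 max-pool; a same-width
bottleneck block; per expanding step a 2×2 stride-2 transposed
convolution, concatenation (not addition) of the matching encoder
features, and another conv block; a final 1×1 convolution with sigmoid.
Output channels are treated independently (a pixel can be ring *and*
fiber).  Input sides must divide `2^depth`; inference pads or tiles.

Losses: RMSE is `sqrt(mean((p−t)²))` over all pixels and channels of
the batch; cross-entropy is pixel-wise binary cross-entropy without
class weighting (per-image RMSE and class-weighted BCE are possible
variants; the batch-level unweighted forms are the package defaults).  Adam runs at lr 0.001 with
default moments.  Early stopping keeps the best-validation-epoch
weights and stops after `patience` (default 10) epochs without
improvement, with `max_epochs` 200 by default.

The engine is pure NumPy (im2col + GEMM convolutions, hand-written
backward passes, float32).  This was a forced choice — no GPU framework
is available in the target environment — and bounds practical model
sizes; the shipped full-scale configurations train on CPU in hours, the
scaled-down test configurations in minutes.  Determinism: every
stochastic step (init, shuffling, augmentation) derives from explicit
seeds, so identical data + seed reproduce the training history exactly.

Tiled inference uses the training window with 16 px overlap and
averages overlapping scores, matching training receptive-field
statistics.  Note that pooling makes the network equivariant only to
shifts that are multiples of `2^depth`; constant inputs map to a
pooling-lattice-periodic (not constant) score pattern.

## Threshold calibration

Per validation image and class, the ROC curve is computed over a fixed
grid of 512 thresholds in (0, 1) (deterministic curve size; exact
unique-value enumeration is available and used by the oracle tests).
The working point minimises the Euclidean distance to (FPR, TPR) =
(0, 1); ties break toward the larger (more conservative) threshold.
The shipped calibration is the per-class *median* over images (midpoint
convention for even counts); pooling all pixels into one curve first is exposed as an
option (`pooled=True`).

## Metrics

F1 = 2TP/(FP+2TP+FN), sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), precision = TP/(TP+FP).  Ratios with zero denominator
return NaN, never 0 — silent zeros would bias aggregation.  AP
integrates the PR curve step-wise (sum over recall increments of the
precision at the higher-recall side), robust to sawtooth curves;
trapezoidal integration is an option.  A fixed binary map (e.g. raw
bounding-box labels) gets the AP-comparable score `precision × recall`
— its one-point PR curve integrated with zero precision credited beyond
its recall.  This rule is a package convention and is what makes "network AP vs. label AP" comparisons
self-consistent; reports flag it.

## Morphometry

Masks come from Gaussian blur (σ = 20 px default) + Otsu on the marker
channel.  The skeleton is a standard unit-width morphological thinning.
Nodes are skeleton pixels with exactly one 8-neighbor (endpoints) or ≥3
(joints); adjacent node pixels merge into one node whose representative
is the member with minimal chain-distance eccentricity, and segment
lengths include the chain distance from the entry pixel to that
representative — without this, multi-pixel junction clusters silently
swallow 1–2 px per arm.  Segment length is the chain-code sum (1 per
axial step, √2 per diagonal).  Leaf segments shorter than 3 px are
pruned as thinning artifacts (config-exposed).  Total branch length is
the sum of segment lengths; maximal branch length is the weighted graph
diameter — the maximum over connected node pairs of the shortest-path
distance — which yields a single linear stretch rather than a sum of
sibling branches.  Both are reported in µm.  Isolated cycles receive a
deterministic anchor node so their length is counted.

Thinning erodes process ends by roughly half the local width, so
skeleton length of a generated tube underestimates the centerline arc
length by about one width per process; tests account for exactly this
term.

## Resampling statistics

Bootstrap: `n_rep` (default 10 000) resamples with replacement, mean
vector each.  Randomization test: the pooled rows are permuted into
groups of the original sizes (the standard construction; each replicate
uses an independent permutation drawn via per-replicate sorting keys,
so results do not depend on execution order).  The difference-of-means
cloud is summarized by a bivariate normal fit (population covariance);
the p-value is the χ²(df = dim) upper tail of the Mahalanobis distance
of the observed difference — an omnibus two-sided test.  The parametric
tail is primary because an empirical tail over 10 000 permutations is
bounded below by ~10⁻⁴ while strongly separated data legitimately
produce far smaller values; the empirical fraction `(1 + #{≥ observed})/(n_rep+1)`
is always reported next to it, and a singular permutation covariance
falls back to it with a warning.  No multiple-testing correction is
applied by default; a Bonferroni option exists.

## Scaled-down test settings

The acceptance tests shrink the problem to one CPU: 64 px crops,
encoder filters (8, 16, 32), ≤ 14 epochs, 4 training scenes of
384×384 px, and 1 000-permutation tests.  These reductions are stated
in the tests themselves; the full-scale defaults remain those given
above.

## Known limitations

* The NumPy engine is CPU-bound; the full 16/32/64/128 configuration at
  batch 72 is slow (hours) though exact.
* Polygon annotations cannot express holes; precise contours of a class
  region with an interior hole would rasterize filled (the generator
  guarantees hole-free class maps for its own scenes).
* `h_a`-specific behavior (no minimum labeled area, cross-entropy) is
  implemented and tested at the unit level, but the shipped end-to-end
  demonstrations exercise the dendritic configuration.
* The skeleton graph is 2-D; no attempt is made to resolve crossing
  processes into separate branches.
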