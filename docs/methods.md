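# Methods

`logstage` implements a self-supervised pipeline for four-class T-staging of
grayscale 2D slices: Laplacian-of-Gaussian (LoG) texture enhancement, a small
convolutional feature extractor, sequential information-bottleneck (sIB)
clustering of the features, and an alternating loop that trains the network
on its own cluster assignments ("pseudo-labels").  This note records the
models, the parameters that matter, and the design choices that were
genuinely open.

## LoG filtering

The LoG operator is the Laplacian of an unnormalized Gaussian,

    LoG(x, y) = ((x^2 + y^2 - 2 sigma^2) / sigma^4) * exp(-(x^2 + y^2) / (2 sigma^2)),

sampled on the integer lattice with support `2*ceil(3*sigma) + 1` (the
conventional 3-sigma truncation).  The truncated kernel does not sum to zero,
so the tap mean is subtracted from every tap; discrete constants are then
annihilated exactly, which makes the zero-crossing detector well defined on
flat regions.  Filtering uses reflect padding so the response has the input
shape.  Anchor values used as tests: the raw tap at the origin is
`-2/sigma^2` and the taps vanish on the circle `x^2 + y^2 = 2 sigma^2`.

Zero-crossings are 4-neighbor sign changes; a crossing is "strong" when the
jump `|resp(p) - resp(q)|` across the sign change exceeds a threshold
(default `0.05 * max|resp|`; the scale of "strong" is data dependent and
exposed).  Candidate keypoints are screened two ways: the principal-curvature
test keeps a point only if its response Hessian has `Det > 0` and
`Tr^2/Det < (r+1)^2/r` with `r = 10` (the canonical default for this test),
rejecting edge-like ridges; the Shi-Tomasi score (minimum eigenvalue of the
structure tensor over a 5x5 window) ranks corner stability.  The multi-scale
pyramid is fixed at four levels, 640x480 / 320x240 / 160x120 / 80x60; inputs
of other sizes are bilinearly resized to 640x480 first, and each coarser
level is a 2x2 block mean of the previous.

**Image preprocessing for training** uses Laplacian *sharpening*: the model
input is `image - LoG*image`, then per-image standardization.  Sharpening
steepens boundaries while keeping the intensity structure (lumen vs wall
levels); using the raw LoG response instead discards absolute intensity and
measurably weakened staging on phantoms.  The enhancement sigma defaults to
1.6.  Setting `use_log_filter=False` in `TrainConfig` is the first ablation
axis.

## The information-bottleneck clustering

Feature vectors (nonnegative after the penultimate ReLU) are recast as a
discrete joint distribution: each image `x` receives uniform mass `1/N`, its
feature vector is clipped at zero, floored with `eps = 1e-8` and normalized
into `p(y|x)` over feature coordinates `y`.  sIB seeks a hard 4-way partition
`T` maximizing

    L = I(T; Y) - (1/lambda) * I(T; X),        lambda = 100.

For a hard partition `I(T;X)` is the cluster entropy `H(T)`, so with
`lambda = 100` the compression term is a ~1% regularizer; the optimization is
dominated by preserving feature information `I(T;Y)`.

The optimizer is the draw-and-merge sweep.  Each point is drawn out of its
cluster and re-merged into the cluster `t` of minimal merger cost

    dL = p_m * JS_w[p(y|x), p(y|t)] - (1/lambda) * p_m * H(w),

with `p_m = p(x) + p(t)` and weights `w = (p(x), p(t)) / p_m`.  The second
term is the Jensen-Shannon divergence of the disjoint membership indicators
over X, which reduces to the binary entropy `H(w)`.  The merger cost equals
the from-scratch objective difference exactly; the test suite enforces
agreement to 1e-9 against an independent oracle that rebuilds `p(t, y)` from
the partition and recomputes both mutual informations.  Consequences used as
invariants: the objective trace is non-decreasing, the sweep terminates
(convergence = a full pass with no reassignment), and `I(T;Y) <= I(X;Y)`.

Numerical choices: natural-log units; ties at the argmin break to the lowest
cluster index; a point that is the sole member of its cluster is not drawn
(keeps the cluster count at four); each restart starts from a random balanced
partition and the best of 5 restarts (by objective) is returned; the sweep
order is a fresh seeded permutation every pass.  One pass evaluates at most
`N*k` merger costs of `O(D)` each, i.e. `O(N k D)` per pass; the suite checks
the evaluation count rather than wall-clock.

## Backbone and training

Four desk-scale architectures share one interface (single grayscale channel,
penultimate fully connected feature layer, linear 4-way head): `tiny_cnn`
(three 3x3 conv/pool blocks, the default), `vgg_small` (two convs per
block), `resnet_small` (identity-skip blocks), `alex_small` (5x5 stem).  The
layer stack (im2col convolution, max pooling, backprop, SGD with momentum
0.9) is implemented in numpy in `logstage.nn`; float64 forward passes are
bit-deterministic and initialization is a pure function of the seed.

The alternating loop (per round): extract features of clean deterministic
views, cluster them with sIB into four pseudo-stages, then train with
minibatch SGD (lr 0.01, batch 16) on the negative log-softmax loss against
those pseudo-labels with train-time augmentation.  Three loop details matter
and were settled empirically on phantoms:

- **Multi-scale cluster views.**  Cluster-time features are concatenated
  over three deterministic views (resize to `in_size + m`, central-crop to
  `in_size`, for m = 0, 8, 16 px).  Mirrors the multi-scale pyramid idea and
  stabilizes the partition.
- **Ramped epoch schedule.**  Round `r` trains `3*(r+1)` epochs.  Early
  pseudo-labels are noisy; training hard on them entrenches wrong partitions,
  while the ramp lets re-clustering correct them before the backbone commits.
  Re-clustering every epoch (an alternative schedule) never lets features
  consolidate and performed clearly worse.
- **Scale-preserving augmentation.**  Random crops use area fractions
  0.95-1.0 before resizing back.  Aggressive random-resized crops rescale the
  image by up to ~20%, which directly corrupts the wall-thickness cue the
  stages are defined by.

The stage head is reinitialized at the start of every round because cluster
identities are arbitrary across rounds; the backbone persists (the standard
deep-clustering remedy).  If one cluster exceeds 70% of samples a collapse
warning is logged.  Clusters are anonymous; when labels exist for any subset,
the Hungarian assignment on the 4x4 confusion matrix pins cluster ids to
stages T1-T4 as a pure relabeling.  Swapping sIB for k-means
(`clusterer="kmeans"`) is the second ablation axis.

## Synthetic phantoms

Each phantom is a bright ring (bowel-wall cross-section) on a dark
background with a dimmer lumen (0.3 of wall intensity).  Stage `s` controls
wall thickness (3, 5, 8, 11 px) and outer-boundary irregularity (sinusoidal
lobes of amplitude 0, 0.8, 1.6, 2.6 px at angular frequency 5): both grow
monotonically with stage, emulating invasion depth and boundary roughness.
Each image additionally gets a random lobe phase (rotation), +/-10% scale
jitter, and i.i.d. Gaussian noise (default sd 0.05 of the unit wall
contrast).  Class proportions default to 18/27/35/20% and are honored for
any n by largest-remainder rounding.  Everything is a pure function of the
seed.

The generator doubles as its own oracle: wall thickness is recoverable from
the radial profile (`area / (2 pi r_mean)`), and at zero noise the oracle
classifier is exact.  What the phantom does *not* emulate: anatomy,
modality-specific contrast, partial-volume effects, multi-modal redundancy,
or inter-patient appearance variation.  Passing phantom tests shows the
pipeline recovers a monotone geometric staging signal through its own
machinery; it does not certify clinical performance.

## Evaluation

Per-stage one-vs-rest metrics at the image level: accuracy, sensitivity,
specificity, balanced accuracy = (sensitivity + specificity)/2.  Zero
denominators yield NaN (an explicit undefined marker, never a silent 0);
macro means average the defined parts.  ROC curves sweep unique score
thresholds (ties merge into diagonal segments) with trapezoidal AUC, which
equals the tie-averaged Mann-Whitney statistic; a brute-force pairwise
comparison is the test oracle.  k-fold splits are seeded and, by default,
grouped by patient so no patient straddles a fold boundary.

## The phantom benchmark and its variance

The standard benchmark (`pipeline.phantom_benchmark`) generates one cohort
of 200 phantoms (noise sd 0.02, a level at which the radial oracle is
exact), holds out 25%, and repeats the 5-round fit over 5 independent
training seeds.  Deep-cluster training at this problem size has genuine
run-to-run variance: the loop occasionally locks into a partition that
merges two adjacent stages (typically T1/T2) and is self-consistent under
further training.  Across training seeds the pseudo-label NMI against truth
typically rises from ~0.45 (round 1) to 0.6-0.85 (round 5), and held-out
balanced accuracy after Hungarian mapping spans roughly 0.77-0.92.  The
benchmark therefore reports all seeds; single-run numbers should be read
with that spread in mind.  Problem sizes (n=200, 5 rounds, 64x64 inputs)
were chosen so the full benchmark runs in minutes on one CPU core.

## Known limitations

- The loop has no explicit escape from self-consistent wrong partitions;
  more rounds helps slowly, restarts of the whole fit help more.
- The sIB representation row-normalizes features, discarding overall
  activation magnitude.
- DICOM loading covers plain single-frame series ordered by slice location;
  registration, bias-field correction and multi-modal fusion are out of
  scope (slices of any modality are independent samples).
- Metrics are image-level; pixel-level staging masks are not produced.
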