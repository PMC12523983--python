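# Methods

## Overview

phenotrack turns a time-lapse movie of segmented, tracked cells into a fixed
quantitative profile per cell and uses those profiles for feature selection
and classification. The pipeline has four stages:

1. **Linking.** Each tracking row (frame, track id, x, y) is associated with
   the mask label at the nearest integer pixel to its coordinates (rounding
   half-away-from-zero). A coordinate that lands on background is rescued by
   the nearest non-zero label within a Chebyshev radius of 2 pixels
   (configurable); still-unresolved rows are dropped with a logged warning.
   The radius is kept small to avoid capturing a neighbouring cell. Tracker
   exports do not document how their spot coordinates relate to mask
   rasterisation, so this centroid-lookup rule is a package contract rather
   than an inherited one.
2. **Per-frame features.** 72 features per cell per frame, in five
   categories (8 size, 12 shape, 48 texture, 1 movement, 3 density).
3. **Time-series summarisation.** Each feature's trajectory series is
   reduced to 15 statistics; 3 whole-trajectory features are appended:
   72 × 15 + 3 = **1083** features per cell, a frozen, versioned contract
   (registry version 1.0).
4. **Selection and classification.** Features are ranked by a
   between/within-class variance ratio, thresholded at the elbow of the
   descending score profile, and fed to an XGBoost multiclass classifier
   whose accuracy is reported as per-class true positive rates (TPR).

## Per-frame feature conventions

Exact conventions matter more than the particular estimator chosen, because
the summarisation stage amplifies any frame-to-frame inconsistency into
spurious temporal signal. The choices:

* **Perimeter** counts unit pixel edges between foreground and background
  (a filled n×n square has perimeter 4n). This is exactly computable and
  testable against brute-force edge enumeration; smoother estimators
  (Crofton) trade that testability for lower bias on diagonal boundaries.
* **Convex measures.** ConvexArea is the pixel count of the rasterised
  convex hull image, so Solidity of a convex region is exactly 1.
  ConvexPerimeter is the perimeter of the hull polygon of pixel centres.
  Degenerate hulls (single pixels, collinear masks) fall back to the plain
  area/perimeter so every downstream ratio stays finite.
* **Moment ellipse.** Axis lengths are 4·√λ of the second central moments'
  eigenvalues (the ellipse with matching second moments). A single-pixel
  mask reports AspectRatio 1 and Eccentricity 0 by convention.
* **Radial and curvature shape statistics** use boundary pixels (foreground
  pixels with a 4-neighbour outside the mask) and the marching-squares
  outline polygon respectively; curvature is the absolute turning angle per
  outline vertex, making it invariant to traversal direction and 90°
  rotations.
* **Texture** is computed at three scales: the original crop and 2×/4×
  block-mean downsamples. The downsampling grid is anchored to the mask's
  bounding box (not the frame origin) so texture is translation-invariant;
  a block survives if at least half its pixels are foreground, and its
  value is the mean over foreground pixels only. Per scale: six first-order
  statistics of the masked intensities plus ten grey-level co-occurrence
  (GLCM) statistics. The GLCM uses 16 levels quantised per cell by min–max
  (texture therefore ignores absolute illumination: any positive affine
  intensity rescaling leaves the GLCM statistics unchanged), distance 1,
  and the four standard offsets; each offset's symmetric count matrix is
  normalised separately and the four probability matrices are averaged with
  equal weight. Equal weighting (rather than pooling raw counts) keeps the
  diagonal offsets — which have fewer valid pairs in a bounded crop — from
  being underweighted. Zero-variance conventions: skewness/kurtosis of
  constant data are 0, GLCM correlation with zero marginal variance is 0;
  a scale with no surviving foreground reports zeros, and one with pixels
  but no valid pair reports the single-state matrix (ASM 1, the rest 0).
* **Movement/density.** Displacement from the previous frame's centroid
  (0 on a trajectory's first frame); neighbour count within a radius
  (default 100 px, configurable), nearest-neighbour distance (sentinel:
  the image diagonal when the cell is alone), and an inverse-distance
  density Σ 1/max(d, 1) over the other cells. Density features see every
  labelled cell in the frame, tracked or not. Cells touching the image
  border are retained (a border flag is stored for optional filtering).
* Disconnected masks keep their largest 8-connected component with a
  logged warning.

## Time-series summarisation

Per feature series: mean, median, sample SD (n−1), skewness, excess
kurtosis, maximum, and — from an orthonormal Haar wavelet decomposition at
levels 1–3 — the detail energy Σd², the largest positive detail (max
ascent) and the largest negative detail magnitude (max descent) per level.
The Haar detail at level 1 for a pair (x₁, x₂) is (x₂−x₁)/√2; deeper levels
act on the running approximations (x₁+x₂)/√2. Odd lengths are right-padded
by repeating the final value before each pairing. Orthonormality gives the
Parseval identity on dyadic lengths (detail energies plus final
approximation energy equal the series energy), which the tests use as the
correctness oracle. The transform is implemented directly because the
repeat-last padding applied at every level is not a standard signal
extension mode.

**Minimum track length is 8 frames** — the shortest series with a
non-degenerate level-3 detail — and is configurable. **Gap policy:** missing
frames inside a trajectory are filled by linear interpolation of both
centroids and feature values when the gap is ≤ 3 frames; longer gaps split
the trajectory into independent segments (ids ``track_id·1000 + segment``),
each kept only if it meets the minimum length. Interpolation keeps the
series contiguous for the wavelet transform; it is exact for locally linear
signals and attenuates high-frequency content across the gap, which is the
conservative direction for the detail energies.

Whole-trajectory features: total track length (sum of consecutive steps),
net displacement (first to last), and trajectory area (convex hull of the
visited centroids; 0 for collinear paths). These carry the movement
category.

## Separation scores and the elbow threshold

For one feature over G classes with sizes n_g, class means x̄_g and class
sample variances s_g²:

    x̄̄  = (1/N) Σ n_g x̄_g,            N = Σ n_g
    VB = (1/(N−G)) Σ n_g (x̄_g − x̄̄)²
    VW = (1/(N−G)) Σ (n_g − 1) s_g²
    Separation = VB / VW

Both variances share the N−G normaliser, so the score is the ratio of the
between- and within-class sums of squares; for G = 2 it equals the pooled
two-sample ratio, and in general it is F·(G−1)/(N−G) for the one-way ANOVA
F statistic (the tests cross-check both identities). Conventions: VB = 0
gives score 0; VW = 0 with VB > 0 gives +∞. Features containing non-finite
values are scored on the finite subset of cells and flagged.

**Elbow threshold.** Scores are sorted descending; a chord joins the
largest and smallest finite scores; the elbow is the score with the maximum
*signed* vertical distance below the chord (on a descending convex profile
the elbow lies below the chord, so scores above it cannot be elbows); ties
resolve to the smallest index (fewest features). Infinite scores rank
first, are always selected, and are excluded from the chord so they cannot
flatten it. With ≤ 2 finite scores the threshold is the minimum (all
selected). Selection is inclusive (score ≥ threshold), so the elbow feature
itself is always retained and the selected set is never empty. No
multiple-testing control is applied: this is a ranking procedure, not a
family of hypothesis tests.

## Classification and population structure

XGBoost multiclass, defaults 200 trees, depth 4, learning rate 0.1, fixed
seed — deliberately generic gradient-boosting settings, exposed in the
classifier spec, since no tuned values exist for this problem family.
Features are z-scored with training-set statistics; trees do not need it,
but the identical preprocessing then feeds PCA (components' signs fixed by
making each one's largest-magnitude loading positive) and Ward-linkage
agglomerative clustering, so all analyses see the same inputs. Accuracy is
reported per class as TPR = 100·diagonal/row-sum of the confusion matrix,
plus the macro average. Train and test profiles arrive as separate labelled
tables; a seeded stratified splitter is provided for synthetic work. Label
regrouping (e.g. collapsing cell lines into disease status) remaps classes
and drops unmapped cells with a logged count, after which scores and models
are recomputed on the new grouping.

## The synthetic movie generator

Cells are rotated ellipses (area ~ Normal(mean_area, area_sd), fixed
per-class aspect ratio, uniform orientation) rasterised by the
pixel-centre-inside-ellipse rule on a constant background (10) with
per-pixel Gaussian interior noise (base intensity 100, class-specific SD).
Centroids follow isotropic Gaussian random walks (class-specific step SD),
reflected at the image borders so cells never leave the frame and track
lengths stay well defined. Overlap is resolved by rejection sampling on
bounding-circle separation — initial placements and motion steps that would
collide are re-drawn (at most 100 attempts; a cell whose every step
collides stays put for that frame) — which guarantees disjoint labels and
that every emitted track coordinate lies inside its own label region (the
linking oracle the tests rely on). Per-frame label ids are a deterministic
permutation of cell ids, so the track-to-mask linking stage is genuinely
exercised rather than trivially satisfied. One master seed drives per-cell
substreams keyed by (seed, cell index), giving bit-identical reruns.

Per-class density structure is available through a seeding-spread
parameter (cells of a class scatter around a class-specific centre instead
of uniformly), since crowding is one of the axes on which real populations
differ.

The **two-class motility benchmark** fixes every parameter equal across
classes except the step SD (0.5 vs 4.0 px/frame), with 20 cells per class,
32 frames, 512×512 px. Any feature separating its classes must therefore
trace back to movement, which makes it a parameter-recovery test for the
whole pipeline: the top-ranked feature must be movement-category and a
classifier trained on one simulated movie must reach ≥ 90% per-class TPR on
an independently seeded one. These sizes keep a full pipeline run around
twenty seconds while leaving the recovery margins wide.

What the generator does **not** emulate: realistic quantitative-phase
texture (interior noise is white, so texture features carry no class signal
beyond noise scale), cell division, death, or entry/exit, touching-cell
segmentation ambiguity, tracking errors, and intensity drift. Passing the
synthetic suites therefore demonstrates the pipeline's bookkeeping,
invariances and discriminative machinery — not segmentation robustness or
biological fidelity of any individual feature.

## Numerical and degenerate-input choices

* Feature tables round-trip through CSV at full repr precision (≥ 12
  significant digits); readers validate the 1083-column width and the
  column names.
* Natural sort for per-frame filename ordering compares digit runs
  numerically (t2 before t10) and is total and deterministic.
* Zero-variance columns: dropped (with a warning) before PCA; passed
  through centred for z-scoring elsewhere.
* Empty selections are impossible by construction; empty profile lists are
  an error on write, and an extraction that yields no qualifying
  trajectory writes an empty table with the correct header.

## Known limitations

* The per-frame feature registry is this package's canon: the category
  structure (size/shape/texture/movement/density) and the 1083-feature
  total are fixed contracts, but individual definitions (e.g. the
  edge-count perimeter, the three-scale texture pyramid) are package
  choices among several defensible conventions.
* Gap interpolation fabricates values; with default settings it affects at
  most 3 consecutive frames per gap.
* The elbow rule always selects at least one feature even when no feature
  separates the classes; inspect the score magnitudes, not just the
  selected set.
* XGBoost determinism is guaranteed for fixed seed, data and thread count
  (the package pins single-threaded fitting).
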