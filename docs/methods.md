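# Methods

This note records the models, conventions, and numerical choices behind
`chromage`, and what the synthetic generators do and do not establish.

## Texture features (TAS)

Per nucleus and channel, the mean masked intensity v_m is computed over the
nucleus pixels only. The 28 binarization intervals are, in frozen order:
the static interval (v_m, ∞); the lower-bounded family (v_m − v_m·p, ∞);
the upper-bounded family (v_m + v_m·p, ∞); and the band family
(v_m − v_m·p, v_m + v_m·p], each for p = 0.1 … 0.9. Interval membership is
`lo < v ≤ hi` — the strict lower bound deterministically excludes
exactly-mean pixels from the static interval. Since p ≤ 0.9, lower bounds
never go negative.

For each binarization, the statistic vector entry k is the fraction of
foreground pixels with exactly k foreground neighbors under full
connectivity (8 in 2D, 26 in 3D); neighbors outside the image or the
nucleus mask count as background. Blocks with no foreground emit zeros,
not NaN, so downstream linear algebra never propagates missing values.
Feature order is channel → family → p ascending → k ascending; names encode
all four. Because the intervals scale with v_m, the features are exactly
invariant to multiplying a nucleus' intensities by any c > 0 (tested).

The implementation counts neighbors with one 3^d convolution; a brute-force
per-pixel scan serves as the independent oracle in the test suite.

## Segmentation input and size filter

Masks come from an external segmenter; the package never segments.
Objects with area (2D) or volume (3D) strictly below that of a sphere of
radius `min_radius_um` (default 4 µm — midpoint of the field-typical 3–7 µm
range, overridable) are removed before feature extraction; the filter is
idempotent and order-preserving. The size filter is applied before feature
extraction (cheaper; the result is identical either way). Z-stacks can be
analyzed as 3D volumes or as per-channel maximum projections; 2D projection
is the default analysis mode. Illumination correction is assumed done
upstream; a logging hook records whether it was declared.

## Bootstrap means, z-scoring, splits

Bootstrap strata are single animals (never pooled): each row is the mean of
200 cells drawn with replacement from one animal, 1000 rows per animal by
default. Rationale: the age signal lives largely in cell-type composition,
which only aggregated samples expose.

The z-scoring standardizer is fitted on the training rows of each split
iteration only and applied to everything else (no leakage; asserted by a
construction test). Zero-variance features get SD 1, transforming to a
constant 0, and are logged.

75/25 train/test splits run at bootstrap-row level by default, stratified
by animal so both classes appear in every train set; only young and old
rows are ever trained on. **Caveat**: because bootstrap rows within one
animal are correlated, row-level splits leak animal identity — under a null
(no drift) fixture the ImAge–age correlation of trained animals is
anti-conservative. An animal-level split mode (`split_by_animal=True`)
holds out whole animals and is calibrated; the null-calibration tests use
it. Row-level remains the default because it is the protocol the readout
is defined by, and the middle/perturbation groups — the scientific targets —
are never trained on in either mode.

## Axes and readouts

The centroid axis runs from the young to the old training centroid and is
anchored at the young centroid; the SVM axis is the unit normal of a
soft-margin linear SVM (C = 1 by default, recorded in config) anchored at
the centroid of all training points, with the SVM's own decision boundary
retained as classification threshold. Both axes are re-oriented so the old
group's mean projection exceeds the young group's. Projection readout
p and orthogonal distance d_o satisfy p² + d_o² = ‖x − origin‖² to 1e−9;
a negative radicand from rounding is clamped at zero.

Per-animal summary readout is the median of that animal's test readouts
(mean available; the choice is recorded in the output). The organ-pair
correlation screen computes Spearman per organ pair per channel on the full
age set and on every leave-one-age-group-out subset, Bonferroni-corrects by
(#pairs × #channels × #subsets), and flags a pair robust only if
significant in the full set and every subset.

## Information distance and hyperbolic embedding

D(X,Y) = (2H(X,Y) − H(X) − H(Y)) / H(X,Y) over 10-bin histograms of the two
samples' feature values (joint histogram 10×10), with D := 0 when
H(X,Y) = 0. Bin edges are [0,0.1), …, [0.9,1.0] with the last bin closed.
Min-max normalization is computed over the union of the two samples being
compared by default (`normalization="given"` for pre-normalized inputs).
Entropies use base 2; D is a ratio, so the base cancels (tested to 1e−12).
Note the estimate saturates toward 1 when samples have few features — the
histograms are then mostly noise — so information-distance analyses are
meant for feature vectors of TAS-like dimensionality (hundreds).

Hyperbolic geometry uses the Lorentz (hyperboloid) model: points with
⟨x,x⟩_L = −1, physical distance arcosh(−⟨x,y⟩_L)/√κ in a space of curvature
−κ (κ stored as a positive magnitude). HMDS minimizes squared stress,
unweighted. Rather than explicit Riemannian retraction steps, the
optimization runs L-BFGS on the spatial chart (the time-like coordinate is
recomputed), which keeps the hyperboloid constraint exact by construction
and converged more reliably than hand-stepped gradient descent in testing;
the analytic chart gradient is supplied. Five starts (classical-MDS
initialization plus seeded perturbations) are run and the best stress kept;
results are bit-reproducible given the seed. Geometry selection is a grid
search maximizing Shepherd R², ties broken toward the smallest dimension
then the smallest curvature, with the full diagnostic table returned.
Dataset-specific curvature values are fits, not constants of the method.

Karcher means iterate tangent-space averaging via the closed-form log/exp
maps to tolerance 1e−8. Geodesic projection minimizes the (convex)
distance to the geodesic with a bounded scalar search (tolerance 1e−10),
with p scaled so p(young centroid) = 0 and p(old centroid) = d_H(a,b). The
geodesic variance fraction log-maps all points to the tangent space at the
geodesic midpoint and reports Var(component along the geodesic direction) /
total tangent variance. In the flat limit (κ·scale → 0) the geodesic
readouts agree with the Euclidean projection to 1e−3 (tested).

## Identity erosion

Silhouettes are computed directly on raw rows under the chosen metric
(information or Euclidean) with a precomputed distance matrix; cells are
subsampled (default 300/age) because the matrix is quadratic, and 100
bootstrap resamples give the CI. KS profiles subsample up to 5000 cells per
(type, age) without replacement, seeded; for >2 types the statistic is the
mean over all pairs, and the per-feature p-value summary is the maximum
over pairs (conservative). The two-stage significance gate (KS test
p < 0.05 with |r| > 0.85; KS–age Pearson p < 0.05 with |r| > 0.95) keeps
both thresholds configurable; with only 3 ages, p < 0.05 forces
|r| > 0.997, so meaningful screens need ≥ 4–5 age groups.

## Signature cells

Thresholds are linear-interpolation percentiles of the reference
single-cell readouts: young signature a < q(old, 5), old signature
a > q(young, 95), strict inequalities (ties are intermediate). By
construction each reference group contains ≤ 5% of the other group's
signature; the 0/100 variant yields pure signatures at the cost of counts.
Labels are invariant under any strictly monotone transform of the
readouts. If the references are so separated that both rules fire, the
larger margin wins (documented tie rule). The reprogramming report
compares each treated animal to the old animal with the lowest median
readout (Mann–Whitney), tests old-vs-treated variance (Levene on
per-animal medians), and reports signature-proportion deltas against that
reference.

## Behavior link

Readouts are trial-averaged, z-scored across animals, filtered by
univariate correlation with ImAge (drop p > 0.3), and clustered by
average-linkage under d = 1 − |r| with the cluster count chosen by
silhouette (degenerate cuts — all together / all singletons — are chosen
when all pairwise distances fall below / above 0.5). The representative is
the cluster medoid. The unit-norm coefficients maximizing corr(Fα, t) are
the normalized OLS coefficients of t on the standardized representatives
(pseudoinverse fallback for rank deficiency); a sphere-search oracle
verifies the closed form in tests. Significance is by permutation of
animals (default 10⁴ permutations), since the norm constraint invalidates
the parametric t distribution. Stability: leave-one-trial-out jackknife
plus 1000 random trial recombinations (each readout contributes one
uniformly drawn trial); the reported α is the sign-aligned mean over draws
with its SD as spread.

## Synthetic generators: what they emulate, and what a green test means

All generators draw from named substreams of one root seed and are
bit-reproducible.

* **Images**: non-overlapping disk/ball nuclei textured with
  Gaussian-smoothed white noise whose kernel width grows with a latent age
  in [0,1] (granularity 1 + 3·age pixels), base intensity 100 grey levels,
  texture contrast 30, additive noise SD 5. This makes the TAS statistics
  provably age-sensitive but models no optics, PSF, or illumination
  artifacts — a green test shows the pipeline recovers planted texture
  drift, not that it handles microscope systematics.
* **Feature tables**: per-age mixtures of cell-type Gaussians (default 2
  types spaced 4 SD apart along the drift direction); age enters as a mean
  shift along a known unit drift direction (default scale 3 noise-SD at
  the oldest age), as a composition shift toward the "late" types, or
  both. Defaults: ages 2/15/27 months, 4 animals per group, 1000 cells
  per animal — a typical rodent aging-cohort scale.
* **Behavior**: per-cluster latent factors w·z(ImAge) + ε with unit factor
  noise; readouts load on their factor with within-cluster correlation
  0.9 and carry i.i.d. trial noise (SD 0.3, 4 trials). Unit factor noise
  is required for the clusters to be near-orthogonal at all: since every
  factor shares the age signal, cross-cluster correlation is
  w₁w₂/√((w₁²+s²)(w₂²+s²)) ≈ 0.45 at s = 1 and |w| ≤ 1, versus ≈ 0.8 at
  s = 0.5, which would contradict the orthogonal-cluster structure the
  clustering step assumes. Sign recovery of α at ~18 animals needs planted
  couplings of roughly |w| ≥ 0.8 (≈ 2 standard errors); weaker couplings
  are not sign-identifiable at that cohort size.

Tests scale simulations down from the production defaults (e.g. 50–200
bootstrap rows per animal instead of 1000, hundreds of cells instead of
thousands) to stay within a CI time budget; the statistical structure is
unchanged and the production defaults remain those stated above.

## Known limitations

* Quantities reported on real mouse cohorts (age correlations,
  dataset-specific curvatures) depend on imaging data that is not
  distributed with the package and are not reproduced here.
* Row-level split leakage (above) means trained-animal readout
  correlations should not be read as held-out evidence; use animal-level
  splits for inference about generalization.
* The information distance needs hundreds of features per sample to be
  informative; on low-dimensional tables it saturates near 1.
* HMDS stress is non-convex; multi-start mitigates but does not guarantee
  global optimality, and the embedding is only defined up to isometry.
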