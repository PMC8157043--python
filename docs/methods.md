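# Methods

`contourspm` tests hypotheses about 2D contour shape without landmarks.
Given a set of closed outlines with group labels (and optional covariates
such as size), it registers the outlines to a common template, establishes
point correspondence, evaluates Hotelling's T² at every contour point, and
corrects the resulting family of tests through the distribution of the
field maximum — parametrically via 1D random-field theory or
nonparametrically by permutation. The univariate baseline (Generalized
Procrustes Analysis + Procrustes ANOVA) is included for comparison.

## Processing chain

### Point-set registration (CPD)

Contours from different specimens generally have different point counts and
no shared indexing, so registration uses coherent point drift: the moving
point set parameterizes the centroids of an isotropic Gaussian mixture
fitted to the fixed set by EM, with closed-form similarity (rotation +
isotropic scale + translation) updates in the M step. Only the similarity
variant is exposed by default — downstream analysis interprets residual
deformation as biological signal, and a nonrigid transform would absorb it.

The EM objective has local optima under large rotations. `cpd_register`
therefore probes `n_starts = 8` evenly spaced initial rotations with a
short EM run (30 iterations) and refines the best basin to convergence
(relative change of the negative log-likelihood below `tol = 1e-8`,
at most `max_iter = 300` iterations). The outlier weight default is
`w = 0`: inputs are clean closed contours. With noiseless planted
similarity transforms the recovered alignment is exact to machine
precision for equal point counts and accurate to a few 1e-4 RMS when the
two sets sample the same curve at different densities (discretization
bias of the mixture optimum, not an EM failure).

### Ordering, parameterization, resampling, roll

Input point order is treated as arbitrary. `order_points` reconstructs a
cyclic traversal: two candidate tours (angular sort about the centroid,
which is exact for star-shaped outlines, and a nearest-neighbour tour
started from the point nearest the centroid-angle origin) are each refined
by best-improvement 2-opt until no improving swap remains, and the shorter
tour wins; the result is canonicalized to counter-clockwise orientation.
2-opt from a single nearest-neighbour start proved unreliable (it can
terminate in crossing-free tours ~40% longer than the true traversal),
which is why two initializations are kept. A tour that still
self-intersects raises an ordering error rather than propagating a broken
correspondence.

`parameterize` fits a periodic cubic spline through the ordered points
with the parameter `u ∈ [0, 1)` assigned by normalized cumulative chord
length (u = 0 and u = 1 are the same curve location). `resample` evaluates
the spline at m equally spaced u values. `optimum_roll` then evaluates the
deformation energy E(k) = Σᵢ ‖moving[(i+k) mod m] − template[i]‖² for all
m cyclic shifts and both traversal orientations and keeps the minimum
(ties: unreversed, then smallest shift). The roll is discrete; with
m ≈ 100 the correspondence granularity is ≤ 1% of the perimeter, which
bounds how exactly two identical shapes can be made to coincide when their
parameterizations start at different vertices.

`correspond_sample` chains these stages per shape against the template,
which is the shape with the maximum point count (ties broken by lowest
shape id).

### Pointwise statistic

For two corresponded groups, at every point i

T²ᵢ = (n₁n₂/(n₁+n₂)) (r̄₁ᵢ − r̄₂ᵢ)ᵀ Wᵢ⁻¹ (r̄₁ᵢ − r̄₂ᵢ),

where Wᵢ is the pooled 2×2 covariance of the point's position with
n₁ + n₂ − 2 degrees of freedom. A singular Wᵢ raises an error naming the
point (an optional ridge `ε·tr(W)/2·I`, ε = 1e-8, is deliberately *not*
applied silently). The general-design version (`mancova_field`) fits a
two-component linear model per point and tests a single-df contrast with
the remaining regressors partialled out; with an intercept + group design
it reduces to the two-sample field exactly (verified to ~1e-13).

### Inference on the field maximum

**Parametric.** The null distribution of T²max over the contour is
approximated by the expected Euler characteristic of the excursion set:

P(T²max > u) ≈ EC₀(u) + R₁ · ρ₁(u),

where EC₀ is the exact pointwise tail via the T² → F transformation
(T²·(ν−p+1)/(pν) ~ F(p, ν−p+1)), ρ₁ is the 1D Euler-characteristic
density of an F field with (p, ν−p+1) degrees of freedom evaluated at the
transformed threshold, and R₁ = m / FWHM is the resel count of the closed
domain. The F-density constants were cross-checked analytically against
the Gaussian and t-field limits (χ²₁ density = twice the Gaussian
upcrossing density; F with one numerator df = twice the t density).

Smoothness (FWHM) is estimated from the model residuals: both position
components of every residual shape are stacked as separate fields, squared
forward differences along the contour (cyclic wrap) are pooled and
normalized by the pointwise sum of squares, and FWHM is the reciprocal of
the mean resel-per-node density. Applied to generated data the estimator
returns the generating kernel FWHM within a few percent (median).

Two deliberate choices on the circular domain: the full circle has Euler
characteristic 0, but the pointwise EC₀ term is retained with coefficient
1 (configurable to 0) for conservatism, matching common 1D practice; and
because the continuum expansion overshoots for very rough fields (ratio
~1.2 at FWHM ≈ 1), the reported threshold and p value take the lesser of
the random-field and Bonferroni corrections, which also makes the two
corrections coincide in the uncorrelated limit. Under smooth nulls
(m = 101, FWHM 20, n = 10 + 10) the measured type-I error at α = 0.05 is
0.03–0.07 across 1000-replicate batches.

**Nonparametric.** Group labels are permuted and the full T² field maximum
recomputed per permutation. All C(n, n₁) assignments are enumerated when
there are at most 10,000; then p = #{T²max* ≥ T²max}/#assignments exactly.
Otherwise 10,000 random permutations are drawn (batched into BLAS matrix
products; ~0.1 s for 10,000 permutations at n = 20, m = 101) and
p = (b+1)/(n_perm+1). On shared smooth Gaussian nulls the permutation and
random-field thresholds agree to ~3% median relative error, the empirical
counterpart of the parametric/nonparametric convergence claim. MANCOVA
contrasts use the Freedman–Lane scheme (permute reduced-model residuals).

### Univariate baseline

`procrustes_anova` computes a Goodall-style one-way F on GPA-aligned
coordinates (the shape-space dimension factor cancels from a one-way F but
is kept for interpretability) with label-permutation inference, exact
enumeration below 10,000 assignments, and the (b+1)/(n_perm+1) convention
otherwise. GPA centers every shape, scales it to unit centroid size, and
iteratively rotates onto the evolving mean until the mean moves < 1e-10.

## Synthetic data

The generator emulates the method's natural test bed: noisy circles of
m = 101 points sampled at equally spaced angles (so generated samples are
corresponded by construction), n = 5 shapes per group by default. A shape's
radius is `base_radius(group) + radius_sd·ε`. Point noise is produced by
circularly convolving white Gaussian noise with a Gaussian kernel of FWHM
`noise_fwhm` points and rescaling to `noise_sd`, so the generated
smoothness is exactly the quantity the random-field machinery estimates.
Signal is a Gaussian pulse in the radial direction centered at u₀ with
width σ (in u), with amplitude `group_amp` (group B only) plus
`size_coef · radius` (size-dependent).

Defaults: base_radius 1.0, radius_sd 0.05, noise_sd 0.05 (5% of radius —
visibly noisy circles), noise_fwhm 20 points, pulse at u₀ = 0.25 with
σ = 0.05. Noise is isotropic (independent smooth fields on x and y): a
purely radial mode exists but confines each point's variation to one fixed
direction, making the pointwise 2×2 covariance exactly singular — the
statistic is undefined under it — so the bivariate default is the one
consistent with the model the statistic assumes.

What the generator does **not** emulate: real outline classes (hearts,
hammers, …) with corners and concavities, non-star-shaped geometry,
outliers, digitization artifacts, or registration error beyond what the
pipeline itself introduces. Passing the calibration and recovery
experiments therefore demonstrates the statistical machinery is correct
under its own assumptions, not that the full chain is robust on arbitrary
real outlines — the point-ordering sensitivity utility
(`sensitivity_experiment`) exists precisely because the real-data chain is
sensitive to processing choices.

## Validation experiments

`contourspm.validation` (driven by `scripts/acceptance.py` and the
acceptance test suite) recomputes, from freshly generated data:

- exactness of the pointwise statistic against a textbook implementation
  and of permutation p values against exhaustive enumeration;
- type-I error of parametric inference (1000 nulls, n = 10 + 10, FWHM 20);
- median relative difference between parametric and 10,000-permutation
  thresholds (100 nulls);
- the Bonferroni limit at FWHM ≈ 1 and the rough > smooth threshold
  ordering;
- power and pulse localization for a 4×noise_sd group pulse. The pulse
  amplitude fixes the effect size; the run uses the same n = 10 + 10 as the
  other inference experiments and size-registers shapes first (unit mean
  radius), since between-shape size scatter is similarity variation, not
  shape signal. At the generator's small-sample default (n = 5 + 5) the
  same experiment tops out
  near 0.8 power — a sample-size statement, not a defect, and the reason
  the inference experiments standardize on n = 10;
- MANCOVA: exact reduction to the two-sample field, and agreement of
  group-effect fields between unscaled and size-registered inputs when
  size is modeled (overlapping excursion sets, maxima within 5 points);
- whole-pipeline null uniformity: p values from the complete
  contours mass-MV branch (shuffle → CPD → order → spline/resample → roll →
  T² → exact permutation inference) on 100 seeded null datasets, tested
  against uniformity by Kolmogorov–Smirnov.

## Numerical choices and degenerate inputs

- 2×2 covariance inverses are analytic; singularity is declared when
  det ≤ 1e-14·tr² and reported with the offending point index.
- The critical-threshold equation is solved by bracketed Brent iteration
  (xtol 1e-10).
- Contours must have ≥ 4 points and no zero-length segments (including the
  wrap-around pair); landmark sets ≥ 3 points; designs must be full rank
  with a nonzero contrast; permutation counts below 100 are recorded as a
  warning in the result metadata rather than rejected.
- All stochastic stages take explicit seeds and results carry them in
  their metadata; repeated runs are bit-identical.

## Known limitations

- The 1D EC density for the T² field uses the F-field density at the
  transformed threshold rather than the exact Hotelling-field density; the
  approximation is validated by simulation (type-I error, convergence to
  permutation thresholds) rather than derived exactly.
- Discrete roll correspondence cannot resolve sub-point offsets; two
  identical shapes parameterized from different start vertices coincide
  only to ~half the inter-point spacing unless their points are equally
  spaced along the curve.
- Ordering assumes a simple closed curve; heavily non-star-shaped or
  self-intersecting point clouds may fail (loudly).
- Landmark-branch inference treats landmarks as an ordered 1D field in
  index order; with spatially disparate landmarks the Bonferroni threshold
  (always available, and automatically taken when smaller) is the safer
  correction.
- p values from the full contour chain are sensitive to the random input
  point order in borderline cases; `sensitivity_experiment` quantifies
  this per dataset instead of pretending it away.
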