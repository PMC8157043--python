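# contourspm

Landmark-free classical hypothesis testing for 2D contour shapes.

Comparing outline shapes between groups usually means digitizing a handful
of homologous landmarks and running Procrustes ANOVA on a single summary
number. `contourspm` implements the alternative: keep the whole outline,
register and correspond the contours algorithmically, evaluate a test
statistic at *every* contour point, and correct for the family of tests
through the distribution of the field maximum. The result is a
morphologically readable excursion set — the contour points where the
groups actually differ — with a defensible p value, for samples as small
as a handful of shapes per group.

It is aimed at morphometricians and image-analysis researchers who have
closed 2D outlines (from segmentation, tracing, or a shape database) with
group labels and optional covariates such as size.

## Method

For contours with arbitrary, unordered points the processing chain is

1. **Registration** — coherent point drift (CPD): the moving point set
   defines Gaussian-mixture centroids fitted to the fixed set by EM
   (similarity variant: rotation, isotropic scale, translation). Neither
   corresponding points nor equal point counts are required.
2. **Correspondence** — recover the cyclic point order, fit a periodic
   cubic spline parameterized by normalized arc position u ∈ [0, 1),
   resample all shapes to the template's point count at equally spaced u,
   and cyclically "roll" each shape to minimize the deformation energy
   Σᵢ ‖movingᵢ₊ₖ − templateᵢ‖².
3. **Mass-multivariate testing** — at each point i, Hotelling's

   T²ᵢ = (n₁n₂ / (n₁+n₂)) (r̄₁ᵢ − r̄₂ᵢ)ᵀ Wᵢ⁻¹ (r̄₁ᵢ − r̄₂ᵢ),

   with Wᵢ the pooled 2×2 covariance at point i. Significance is assessed
   on T²max = maxᵢ T²ᵢ, either parametrically (1D random-field theory:
   smoothness/FWHM estimated from residuals, critical threshold from the
   expected Euler characteristic of the excursion set, never exceeding the
   Bonferroni threshold) or nonparametrically (label permutation with
   exact enumeration when feasible). Arbitrary single-contrast designs
   (e.g. group effects with size modeled out, MANCOVA-style) are supported
   via pointwise multivariate linear models.

The univariate baseline (GPA + Goodall-style Procrustes ANOVA with
permutation inference) and a ground-truth synthetic generator (smooth
noisy circles with optional group- and size-dependent Gaussian pulse
deformations) are part of the package, as is a point-ordering sensitivity
utility that re-runs the whole chain under fresh random orderings.

## Worked example

Generate two groups of ten noisy circles where group B carries a radial
Gaussian pulse (amplitude 4× the point noise) centered at u₀ = 0.25, then
test for a group difference:

```python
import numpy as np
from contourspm import (SyntheticSpec, generate, t2_field,
                        two_sample_residuals, rft_inference, snpm_inference)

sample, truth = generate(SyntheticSpec(n_per_group=10, group_amp=0.2, seed=3))
field = t2_field(sample)                       # T² at each of 101 points
res = rft_inference(field, two_sample_residuals(sample))
print(f"T2max = {res.t2max:.2f}   critical threshold = {res.threshold:.2f}")
print(f"p = {res.p:.2e}   estimated FWHM = {res.fwhm:.1f} points")
print(f"excursion set: {len(res.supra_indices)} points, "
      f"argmax at index {int(np.argmax(field.values))} "
      f"(pulse was planted at index {truth['pulse_center_index']})")
perm = snpm_inference(sample, n_perm=10_000, seed=3)
print(f"permutation: threshold = {perm.threshold:.2f}, p = {perm.p:.4f}")
```

prints

```
T2max = 37.27   critical threshold = 16.82
p = 1.43e-03   estimated FWHM = 20.8 points
excursion set: 9 points, argmax at index 25 (pulse was planted at index 25)
permutation: threshold = 15.96, p = 0.0008
```

The field maximum (37.3) far exceeds the α = 0.05 critical value (16.8),
so the null hypothesis of equal mean contours is rejected (p ≈ 0.001); the
nine supra-threshold points sit exactly where the pulse was planted, and
the permutation threshold agrees with the parametric one to a few percent
— the two inference routes corroborate each other. Note the threshold is
far below the Bonferroni value for 101 separate tests: the estimated
smoothness (FWHM ≈ 21 points) means the field carries only ≈ 5
independent-information units, and the correction adapts accordingly.

For raw contour files the same analysis runs end to end (registration,
ordering, resampling, roll, inference) through the pipeline API or CLI:

```sh
contourspm simulate --preset pulse-circles --seed 3 -o dataset.json
contourspm pipeline --dataset dataset.json --branch contours-massmv -o out/
contourspm pipeline --dataset dataset.json --branch contours-massmv --sensitivity 20
```

The `--sensitivity` flag re-runs the chain under fresh random point
orderings and reports the spread of p values.

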