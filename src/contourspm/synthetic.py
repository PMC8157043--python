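"""Synthetic contour generator with known ground truth.

Shapes are noisy circles sampled at ``m`` equally spaced angles, the test
bed used throughout for error-rate calibration (all signal amplitudes zero:
the two groups are exchangeable) and for power/recovery experiments (a
Gaussian "pulse" deformation whose amplitude may depend on group membership
and/or on shape size, i.e. mean radius).

Point-location noise is smooth along the contour: white Gaussian noise is
circularly convolved with a Gaussian kernel of the requested FWHM (in
points) and rescaled to the requested standard deviation, so the generated
smoothness is exactly the quantity the random-field machinery estimates.
Noise is isotropic by default (independent smooth fields on both
coordinates), matching the bivariate-Gaussian point-variability model the
pointwise T² statistic assumes; a purely radial mode exists for univariate
experiments, but note it makes the pointwise 2×2 covariance rank-1
(variation confined to the radial direction) and therefore cannot feed T²
analyses.

Because points are sampled at fixed angles, generated samples are
corresponded by construction; :func:`shuffle_points` destroys the ordering
for experiments that exercise the registration/correspondence chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .io import Contour, ShapeSample, ValidationError

__all__ = ["SyntheticSpec", "generate", "shuffle_points"]


@dataclass
class SyntheticSpec:
    """Full parameterization of the synthetic circle generator.

    Parameters
    ----------
    n_per_group
        Shapes per group (two groups, "A" and "B").
    m
        Points per contour.
    base_radius
        Per-group mean radius (group A, group B), arbitrary units.
    radius_sd
        Between-shape standard deviation of the shape radius.
    noise_sd
        Per-point radial noise standard deviation.
    noise_fwhm
        Smoothness of the point noise along the contour, in points.
    pulse_center, pulse_width
        Center u₀ ∈ [0, 1) and Gaussian σ (in u) of the pulse deformation.
    group_amp
        Pulse amplitude added for group "B" only.
    size_coef
        Pulse amplitude per unit shape radius (size-dependent signal).
    noise_mode
        "isotropic" (default) or "radial".
    """

    n_per_group: int = 5
    m: int = 101
    base_radius: tuple = (1.0, 1.0)
    radius_sd: float = 0.05
    noise_sd: float = 0.05
    noise_fwhm: float = 20.0
    pulse_center: float = 0.25
    pulse_width: float = 0.05
    group_amp: float = 0.0
    size_coef: float = 0.0
    noise_mode: str = "isotropic"
    seed: int = 0

    def __post_init__(self):
        if self.m < 8:
            raise ValidationError(f"m must be >= 8, got {self.m}")
        if self.n_per_group < 2:
            raise ValidationError("need at least 2 shapes per group")
        for name in ("radius_sd", "noise_sd", "noise_fwhm", "pulse_width"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if self.noise_fwhm == 0 and self.noise_sd > 0:
            raise ValidationError("noise_fwhm must be positive when noise_sd > 0")
        if not 0.0 <= self.pulse_center < 1.0:
            raise ValidationError("pulse_center must lie in [0, 1)")
        if self.noise_mode not in ("radial", "isotropic"):
            raise ValidationError(f"unknown noise_mode {self.noise_mode!r}")


def _smooth_field(rng: np.random.Generator, m: int, fwhm: float) -> np.ndarray:
    """Unit-variance Gaussian field on the circle, smoothness ``fwhm`` points."""
    white = rng.standard_normal(m)
    sigma = fwhm / np.sqrt(8.0 * np.log(2.0))
    if sigma < 1e-6:
        return white
    half = min(int(np.ceil(4 * sigma)), m // 2)
    x = np.arange(-half, half + 1)
    kernel = np.exp(-x ** 2 / (2.0 * sigma ** 2))
    kernel /= kernel.sum()
    smoothed = ndimage.convolve1d(white, kernel, mode="wrap")
    return smoothed / np.sqrt((kernel ** 2).sum())


def generate(spec: SyntheticSpec):
    """Generate a corresponded two-group sample of noisy circles.

    Returns ``(sample, ground_truth)``; the sample carries a ``size``
    covariate (measured mean radius per shape) and the ground-truth record
    holds the drawn radii, pulse parameters and the pulse-center point index.
    """
    rng = np.random.default_rng(spec.seed)
    theta = 2.0 * np.pi * np.arange(spec.m) / spec.m
    u = np.arange(spec.m) / spec.m
    du = np.abs(u - spec.pulse_center)
    du = np.minimum(du, 1.0 - du)
    if spec.pulse_width > 0:
        pulse_shape = np.exp(-du ** 2 / (2.0 * spec.pulse_width ** 2))
    else:
        pulse_shape = (du == 0).astype(float)

    shapes, groups, radii, sizes = [], [], [], []
    for gi, gname in enumerate(("A", "B")):
        for j in range(spec.n_per_group):
            r_s = spec.base_radius[gi] + spec.radius_sd * rng.standard_normal()
            amp = spec.group_amp * (gname == "B") + spec.size_coef * r_s
            radius = r_s + amp * pulse_shape
            if spec.noise_mode == "radial":
                if spec.noise_sd > 0:
                    radius = radius + spec.noise_sd * _smooth_field(rng, spec.m, spec.noise_fwhm)
                pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
            else:
                pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
                if spec.noise_sd > 0:
                    pts = pts + spec.noise_sd * np.column_stack(
                        [_smooth_field(rng, spec.m, spec.noise_fwhm) for _ in range(2)]
                    )
            shapes.append(Contour(points=pts, shape_id=f"{gname}{j:02d}"))
            groups.append(gname)
            radii.append(float(r_s))
            sizes.append(float(np.linalg.norm(pts, axis=1).mean()))

    sample = ShapeSample(shapes=shapes, group=groups,
                         covariates={"size": np.asarray(sizes)})
    truth = {
        "spec": asdict(spec),
        "radii": radii,
        "pulse_center_index": int(round(spec.pulse_center * spec.m)) % spec.m,
        "pulse_shape": pulse_shape.tolist(),
    }
    return sample, truth


def shuffle_points(sample: ShapeSample, seed: int | None = None) -> list:
    """Return each shape's points in uniformly random order (new Contours)."""
    rng = np.random.default_rng(seed)
    out = []
    for s in sample.shapes:
        perm = rng.permutation(s.m)
        out.append(Contour(points=s.points[perm], shape_id=s.shape_id))
    return out
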