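"""Simulation experiments validating the inference machinery.

These are the package's standard self-checks: error-rate calibration of the
parametric (random-field) threshold, convergence of parametric and
permutation inference on shared nulls, the Bonferroni limit for rough
fields, power and localization for a planted pulse, MANCOVA consistency
between unscaled and registered inputs, whole-pipeline null uniformity, and
registration recovery. Each function generates its own synthetic data
(seeded) and returns plain numbers.

Conditions follow the running study setup: contours of m = 101 points,
smooth noise of FWHM 20 points, n = 10 shapes per group for inference
calibration (n = 5, the generator's small-sample default, where noted).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats

from .io import Contour, ShapeSample
from .correspondence import order_points, parameterize, resample
from .pipeline import PipelineConfig, run_pipeline
from .registration import SimilarityTransform, cpd_register, gpa_align
from .stats_massmv import (bonferroni_threshold, mancova_field,
                           mancova_residuals, rft_inference, snpm_inference,
                           t2_field, two_group_design, two_sample_residuals)
from .stats_uv import procrustes_distance
from .synthetic import SyntheticSpec, generate, shuffle_points

__all__ = [
    "type1_error_rft",
    "rft_perm_threshold_agreement",
    "bonferroni_limit",
    "signal_recovery",
    "mancova_consistency",
    "pipeline_null_pvalues",
    "registration_recovery",
]


def _scale_registered(sample: ShapeSample) -> ShapeSample:
    """Scale every shape to unit mean radius (size registration)."""
    X = sample.coords()
    scales = np.linalg.norm(X, axis=2).mean(axis=1)
    out = sample.with_coords(X / scales[:, None, None])
    out.covariates = dict(sample.covariates)
    return out


def type1_error_rft(n_rep: int = 1000, seed: int = 0, alpha: float = 0.05,
                    n_per_group: int = 10, noise_fwhm: float = 20.0) -> float:
    """Null rejection rate of parametric T²max inference."""
    rej = 0
    for i in range(n_rep):
        s, _ = generate(SyntheticSpec(n_per_group=n_per_group,
                                      noise_fwhm=noise_fwhm,
                                      seed=seed * 1_000_003 % 2**31 + i))
        res = rft_inference(t2_field(s), two_sample_residuals(s), alpha=alpha)
        rej += res.reject
    return rej / n_rep


def rft_perm_threshold_agreement(n_rep: int = 100, seed: int = 0,
                                 n_perm: int = 10_000) -> float:
    """Median relative difference between RFT and permutation thresholds
    on shared null datasets."""
    errs = []
    for i in range(n_rep):
        s, _ = generate(SyntheticSpec(n_per_group=10,
                                      seed=(seed * 7 + 1) % 2**31 + i))
        rft = rft_inference(t2_field(s), two_sample_residuals(s))
        perm = snpm_inference(s, n_perm=n_perm, seed=seed + i)
        errs.append(abs(rft.threshold - perm.threshold) / perm.threshold)
    return float(np.median(errs))


def bonferroni_limit(seed: int = 0) -> dict:
    """RFT vs Bonferroni thresholds for rough (FWHM ≈ 1) null fields, and
    the smooth-field (FWHM 20) threshold for comparison."""
    s, _ = generate(SyntheticSpec(n_per_group=10, noise_fwhm=1.0,
                                  radius_sd=0.0, seed=seed + 17))
    rough = rft_inference(t2_field(s), two_sample_residuals(s))
    s2, _ = generate(SyntheticSpec(n_per_group=10, noise_fwhm=20.0,
                                   radius_sd=0.0, seed=seed + 18))
    smooth = rft_inference(t2_field(s2), two_sample_residuals(s2))
    bonf = bonferroni_threshold(s.m, (2, 18), alpha=0.05)
    return {
        "rough_threshold": rough.threshold,
        "bonferroni": bonf,
        "ratio": rough.threshold / bonf,
        "smooth_threshold": smooth.threshold,
        "rough_fwhm": rough.fwhm,
    }


def signal_recovery(n_rep: int = 100, seed: int = 0, n_per_group: int = 10,
                    tol_points: int = 5) -> dict:
    """Power and pulse-localization for a group pulse of 4x the point noise.

    Shapes are size-registered (unit mean radius) before the two-sample
    test, mirroring the registered-data analysis; the pulse amplitude is
    four times ``noise_sd``.
    """
    rej = 0
    localized = 0
    for i in range(n_rep):
        spec = SyntheticSpec(n_per_group=n_per_group,
                             group_amp=4 * 0.05,
                             seed=(seed * 11 + 3) % 2**31 + i)
        s, truth = generate(spec)
        s = _scale_registered(s)
        field = t2_field(s)
        res = rft_inference(field, two_sample_residuals(s))
        if res.reject:
            rej += 1
            am = int(np.argmax(field.values))
            ci = truth["pulse_center_index"]
            d = min(abs(am - ci), spec.m - abs(am - ci))
            localized += d <= tol_points
    return {
        "power": rej / n_rep,
        "localization_given_rejection": localized / max(rej, 1),
        "n_rejections": rej,
    }


def mancova_consistency(n_rep: int = 40, seed: int = 0,
                        tol_points: int = 5) -> dict:
    """Group-effect MANCOVA fields on unscaled vs size-registered inputs.

    Generates size- and group-dependent pulses on circles with
    systematically different group radii, fits the intercept + group + size
    model to both the original and the registered coordinates, and measures
    how often the two supra-threshold excursion sets overlap with field
    maxima within ``tol_points`` of each other.
    """
    both = 0
    agree = 0
    for i in range(n_rep):
        spec = SyntheticSpec(n_per_group=10, group_amp=0.2, size_coef=0.2,
                             base_radius=(1.0, 1.25), radius_sd=0.1,
                             seed=(seed * 13 + 5) % 2**31 + i)
        s, truth = generate(spec)
        design = two_group_design(s, covariate_names=["size"])
        f_orig = mancova_field(s, design)
        r_orig = rft_inference(f_orig, mancova_residuals(s, design))
        reg = _scale_registered(s)
        design_reg = two_group_design(reg, covariate_names=["size"])
        f_reg = mancova_field(reg, design_reg)
        r_reg = rft_inference(f_reg, mancova_residuals(reg, design_reg))
        if r_orig.reject and r_reg.reject:
            both += 1
            overlap = set(r_orig.supra_indices) & set(r_reg.supra_indices)
            a1 = int(np.argmax(f_orig.values))
            a2 = int(np.argmax(f_reg.values))
            d = min(abs(a1 - a2), spec.m - abs(a1 - a2))
            agree += bool(overlap) and d <= tol_points
    return {
        "both_reject_rate": both / n_rep,
        "agreement_given_both_reject": agree / max(both, 1),
    }


def pipeline_null_pvalues(n_rep: int = 100, seed: int = 0) -> np.ndarray:
    """p values from the full contours mass-multivariate branch on null
    datasets with randomly ordered points (nonparametric inference)."""
    ps = np.empty(n_rep)
    for i in range(n_rep):
        s, _ = generate(SyntheticSpec(n_per_group=5,
                                      seed=(seed * 17 + 7) % 2**31 + i))
        shuffled = shuffle_points(s, seed=(seed * 19 + 11) % 2**31 + i)
        cfg = PipelineConfig(branch="contours-massmv", method="nonparametric",
                             seed=seed + i)
        ps[i] = run_pipeline(cfg, shuffled, s.group).p
    return ps


def registration_recovery(seed: int = 0) -> dict:
    """Planted-transform inversion (equal and unequal counts) and GPA
    collapse of similarity copies of one shape."""
    rng = np.random.default_rng(seed + 23)
    t = np.linspace(0, 2 * np.pi, 101, endpoint=False)
    base = np.column_stack([np.cos(t) * (1 + 0.3 * np.cos(3 * t)),
                            np.sin(t) * (1 + 0.2 * np.sin(2 * t))])
    T = SimilarityTransform.from_angle(rng.uniform(0, 2 * np.pi),
                                       rng.uniform(0.7, 1.5),
                                       rng.uniform(-2, 2, 2))
    res = cpd_register(Contour(T.apply(base), "m"), Contour(base, "f"))
    rms_equal = float(np.sqrt(((res.aligned - base) ** 2).sum(axis=1).mean()))

    t2 = np.linspace(0, 2 * np.pi, 120, endpoint=False)
    fixed = np.column_stack([np.cos(t2) * (1 + 0.3 * np.cos(3 * t2)),
                             np.sin(t2) * (1 + 0.2 * np.sin(2 * t2))])
    res2 = cpd_register(Contour(T.apply(base), "m"), Contour(fixed, "f"))
    rms_unequal = float(np.sqrt(((res2.aligned - base) ** 2).sum(axis=1).mean()))

    shapes = []
    for i in range(8):
        Ti = SimilarityTransform.from_angle(rng.uniform(0, 2 * np.pi),
                                            rng.uniform(0.5, 2.0),
                                            rng.uniform(-3, 3, 2))
        shapes.append(Contour(Ti.apply(base), f"s{i}"))
    aligned = gpa_align(ShapeSample(shapes=shapes, group=["A"] * 4 + ["B"] * 4))
    X = aligned.coords()
    dmax = max(procrustes_distance(X[0], X[i]) for i in range(1, len(X)))
    return {"rms_equal": rms_equal, "rms_unequal": rms_unequal,
            "gpa_max_procrustes_distance": float(dmax)}
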