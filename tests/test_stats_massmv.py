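import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from contourspm import (LinearDesign, ShapeSample, SingularCovarianceError,
                        SyntheticSpec, TSquaredField, ValidationError,
                        bonferroni_threshold, estimate_fwhm, expected_euler,
                        generate, mancova_field, mancova_residuals,
                        mancova_snpm_inference, rft_inference, snpm_inference,
                        t2_field, t2max, two_group_design,
                        two_sample_residuals)
from contourspm.io import Contour

from conftest import noise_sample


def brute_force_t2(sample):
    """Textbook two-sample Hotelling T² per point, written independently."""
    gi = sample.group_indices()
    (i1, i2) = list(gi.values())
    X = sample.coords()
    X1, X2 = X[i1], X[i2]
    n1, n2 = len(X1), len(X2)
    out = np.empty(sample.m)
    for i in range(sample.m):
        a, b = X1[:, i, :], X2[:, i, :]
        d = a.mean(axis=0) - b.mean(axis=0)
        S1 = np.cov(a, rowvar=False, ddof=1)
        S2 = np.cov(b, rowvar=False, ddof=1)
        W = ((n1 - 1) * S1 + (n2 - 1) * S2) / (n1 + n2 - 2)
        out[i] = n1 * n2 / (n1 + n2) * d @ np.linalg.solve(W, d)
    return out


class TestT2Field:
    def test_matches_pointwise_brute_force(self, rng):
        sample = noise_sample(rng, n_per_group=5, m=20)
        field = t2_field(sample)
        np.testing.assert_allclose(field.values, brute_force_t2(sample), atol=1e-10)
        assert field.df == (2, 8)

    def test_zero_difference_gives_zero(self, rng):
        sample = noise_sample(rng, n_per_group=3, m=8)
        X = sample.coords()
        X[3:] = X[:3]            # group B = group A exactly
        field = t2_field(sample.with_coords(X))
        np.testing.assert_allclose(field.values, 0.0, atol=1e-18)

    def test_invariant_to_common_affine_map(self, rng):
        sample = noise_sample(rng, n_per_group=4, m=10)
        f0 = t2_field(sample).values
        A = np.array([[2.0, 0.3], [-0.1, 1.5]])
        mapped = sample.with_coords(sample.coords() @ A.T + [4.0, -7.0])
        f1 = t2_field(mapped).values
        np.testing.assert_allclose(f1, f0, rtol=1e-8)

    def test_singular_covariance_names_point(self, rng):
        sample = noise_sample(rng, n_per_group=3, m=6)
        X = sample.coords()
        X[:, 2, 1] = 0.0          # kill all variation in y at point 2
        X[:, 2, 0] = np.arange(6) * 0.1
        with pytest.raises(SingularCovarianceError, match="point index 2"):
            t2_field(sample.with_coords(X))

    def test_t2max_is_exhaustive_max(self):
        f = TSquaredField(values=np.array([1.0, 5.0, 2.0]), df=(2, 10))
        assert t2max(f) == 5.0


class TestSmoothness:
    def test_generated_fwhm_recovered(self):
        # median estimate over replicates within 20% of the generating FWHM
        est = []
        for i in range(40):
            s, _ = generate(SyntheticSpec(n_per_group=5, noise_fwhm=15.0,
                                          radius_sd=0.0, seed=900 + i))
            est.append(estimate_fwhm(two_sample_residuals(s)))
        assert abs(np.median(est) - 15.0) / 15.0 < 0.2

    def test_white_noise_estimates_near_one(self, rng):
        R = rng.standard_normal((40, 200, 2))
        assert estimate_fwhm(R) < 1.5


class TestRFTInference:
    def _null_field(self, rng, fwhm=20.0, n=10, seed=0):
        s, _ = generate(SyntheticSpec(n_per_group=n, noise_fwhm=fwhm,
                                      seed=seed))
        return t2_field(s), two_sample_residuals(s)

    def test_infinite_smoothness_limit_is_pointwise_critical(self, rng):
        field, resid = self._null_field(rng, seed=3)
        res = rft_inference(field, resid, alpha=0.05, fwhm=1e9)
        p_comp, nu = field.df
        pointwise = stats.f.isf(0.05, p_comp, nu - p_comp + 1) * p_comp * nu / (nu - p_comp + 1)
        assert res.threshold == pytest.approx(pointwise, rel=1e-3)

    def test_threshold_decreases_with_smoothness(self, rng):
        field, resid = self._null_field(rng, seed=4)
        rough = rft_inference(field, resid, fwhm=1.0)
        smooth = rft_inference(field, resid, fwhm=20.0)
        assert rough.threshold > smooth.threshold

    def test_threshold_monotone_in_alpha(self, rng):
        field, resid = self._null_field(rng, seed=5)
        t1 = rft_inference(field, resid, alpha=0.01).threshold
        t2 = rft_inference(field, resid, alpha=0.05).threshold
        assert t1 > t2

    def test_p_monotone_decreasing_in_t2max(self):
        df, resels = (2, 18), 5.0
        u = np.linspace(5, 40, 50)
        ec = expected_euler(u, df, resels)
        assert np.all(np.diff(ec) < 0)

    def test_p_increases_with_fwhm_at_fixed_t2max(self, rng):
        field, resid = self._null_field(rng, seed=6)
        p_rough = rft_inference(field, resid, fwhm=2.0).p
        p_smooth = rft_inference(field, resid, fwhm=30.0).p
        assert p_smooth <= p_rough

    def test_p_alpha_threshold_consistency(self, rng):
        for seed in range(6):
            field, resid = self._null_field(rng, seed=100 + seed)
            res = rft_inference(field, resid)
            assert (res.p <= res.alpha) == (res.t2max > res.threshold)
            assert set(res.supra_indices) == {
                int(i) for i in np.flatnonzero(field.values > res.threshold)}

    def test_inference_invariant_to_cyclic_shift(self, rng):
        field, resid = self._null_field(rng, seed=7)
        k = 17
        shifted = TSquaredField(values=np.roll(field.values, k), df=field.df)
        res0 = rft_inference(field, resid)
        res1 = rft_inference(shifted, np.roll(resid, k, axis=1))
        assert res1.threshold == pytest.approx(res0.threshold, rel=1e-12)
        assert res1.p == pytest.approx(res0.p, rel=1e-12)

    def test_alpha_out_of_range_rejected(self, rng):
        field, resid = self._null_field(rng, seed=8)
        with pytest.raises(ValidationError):
            rft_inference(field, resid, alpha=0.9)


class TestSnPM:
    def test_label_swap_symmetry(self, rng):
        sample = noise_sample(rng, n_per_group=4, m=12)
        swapped = ShapeSample(shapes=sample.shapes,
                              group=["B" if g == "A" else "A" for g in sample.group])
        assert snpm_inference(sample).p == snpm_inference(swapped).p

    def test_sampled_permutations_reproducible(self, rng):
        sample = noise_sample(rng, n_per_group=8, m=12)
        r1 = snpm_inference(sample, n_perm=500, seed=11)
        r2 = snpm_inference(sample, n_perm=500, seed=11)
        assert not r1.metadata["exact"]
        assert r1.p == r2.p and r1.threshold == r2.threshold

    def test_low_n_perm_records_warning(self, rng):
        sample = noise_sample(rng, n_per_group=8, m=10)
        res = snpm_inference(sample, n_perm=50, seed=1)
        assert "warning" in res.metadata

    def test_batched_engine_agrees_with_direct_fields(self, rng):
        # sampled-permutation maxima must equal per-permutation recomputation
        sample = noise_sample(rng, n_per_group=8, m=15)
        from contourspm.stats_massmv import _batched_perm_maxima, _t2_values
        X = sample.coords()
        G = np.zeros((5, 16))
        gen = np.random.default_rng(0)
        for row in G:
            row[gen.choice(16, 8, replace=False)] = 1.0
        batched = _batched_perm_maxima(X, 8, G)
        for g, bval in zip(G, batched):
            idx1 = np.flatnonzero(g == 1)
            idx2 = np.flatnonzero(g == 0)
            direct = np.max(_t2_values(X, idx1, idx2, check=False))
            assert bval == pytest.approx(direct, rel=1e-10)

    def test_parametric_and_permutation_thresholds_agree_on_smooth_null(self):
        s, _ = generate(SyntheticSpec(n_per_group=10, seed=77))
        rft = rft_inference(t2_field(s), two_sample_residuals(s))
        perm = snpm_inference(s, n_perm=5000, seed=3)
        assert abs(rft.threshold - perm.threshold) / perm.threshold < 0.15


class TestMANCOVA:
    def test_reduces_to_two_sample_field(self):
        s, _ = generate(SyntheticSpec(n_per_group=6, seed=21, group_amp=0.1))
        design = two_group_design(s)
        np.testing.assert_allclose(mancova_field(s, design).values,
                                   t2_field(s).values, atol=1e-10)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(8), np.ones(8)])
        with pytest.raises(ValidationError):
            LinearDesign(matrix=X, contrast=np.array([0.0, 1.0]))

    def test_null_covariate_type_one_error(self, rng):
        # contrast on a regressor unrelated to the generated data
        rej = 0
        n_sims = 200
        for i in range(n_sims):
            s, _ = generate(SyntheticSpec(n_per_group=5, seed=5000 + i))
            z = rng.standard_normal(len(s))
            design = LinearDesign(
                matrix=np.column_stack([np.ones(len(s)), z]),
                contrast=np.array([0.0, 1.0]))
            field = mancova_field(s, design)
            res = rft_inference(field, mancova_residuals(s, design))
            rej += res.reject
        assert 0.01 <= rej / n_sims <= 0.09

    def test_freedman_lane_permutation_calibrated_p(self):
        s, _ = generate(SyntheticSpec(n_per_group=6, seed=31))
        design = two_group_design(s, covariate_names=["size"])
        res = mancova_snpm_inference(s, design, n_perm=300, seed=5)
        assert 0.0 < res.p <= 1.0
        assert res.metadata["scheme"] == "freedman-lane"


class TestBonferroni:
    def test_single_point_is_uncorrected_critical(self):
        df = (2, 18)
        expected = stats.f.isf(0.05, 2, 17) * 2 * 18 / 17
        assert bonferroni_threshold(1, df) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_m_points(self):
        df = (2, 18)
        thresholds = [bonferroni_threshold(m, df) for m in (1, 10, 101, 1000)]
        assert np.all(np.diff(thresholds) > 0)

    @given(st.integers(5, 60))
    def test_rft_threshold_never_exceeds_bonferroni(self, nu):
        field = TSquaredField(values=np.full(101, 1.0), df=(2, nu))
        res = rft_inference(field, np.zeros((2, 101, 2)), fwhm=1.0)
        assert res.threshold <= bonferroni_threshold(101, (2, nu)) * (1 + 1e-12)
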