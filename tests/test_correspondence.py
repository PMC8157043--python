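import numpy as np
import pytest
from hypothesis import given, strategies as st

from contourspm import (Contour, ValidationError, correspond_sample,
                        optimum_roll, order_points, parameterize, resample,
                        select_template)
from contourspm.correspondence import roll_energy

from conftest import bumpy_curve, circle, random_similarity


def cyclic_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """True if b equals a up to cyclic rotation and/or reversal."""
    m = len(a)
    for cand in (b, b[::-1]):
        for k in range(m):
            if np.allclose(np.roll(cand, -k, axis=0), a, atol=1e-12):
                return True
    return False


class TestOrderPoints:
    def test_shuffled_convex_polygon_recovered(self, rng):
        pts = circle(24)
        shuffled = pts[rng.permutation(24)]
        rec = order_points(Contour(shuffled, "c"))
        assert cyclic_equal(pts, rec.points)

    def test_output_is_permutation_of_input(self, rng):
        pts = bumpy_curve(50)[rng.permutation(50)]
        rec = order_points(Contour(pts, "c"))
        assert sorted(map(tuple, rec.points)) == sorted(map(tuple, pts))

    def test_idempotent_on_ordered_input(self):
        pts = bumpy_curve(40)
        rec = order_points(Contour(pts, "c"))
        again = order_points(rec)
        assert cyclic_equal(rec.points, again.points)

    def test_canonical_orientation_is_counter_clockwise(self, rng):
        pts = bumpy_curve(40)[::-1]          # clockwise input
        rec = order_points(Contour(pts, "c"))
        assert rec.signed_area() > 0

    def test_noisy_circle_tour_length(self, rng):
        pts = circle(101) * (1 + 0.05 * np.sin(6 * np.linspace(0, 2 * np.pi, 101,
                                                               endpoint=False)))[:, None]
        ordered = Contour(pts, "c")
        shuffled = Contour(pts[rng.permutation(101)], "c")
        rec = order_points(shuffled)
        assert rec.perimeter() <= 1.01 * ordered.perimeter()


class TestParameterize:
    def test_interpolation_reproduces_input_points(self):
        c = Contour(bumpy_curve(60), "c")
        pc = parameterize(c)
        np.testing.assert_allclose(pc.evaluate(pc.u_values), c.points, atol=1e-8)

    def test_periodicity_u0_equals_u1(self):
        pc = parameterize(Contour(bumpy_curve(30), "c"))
        np.testing.assert_allclose(pc.evaluate(0.0), pc.evaluate(1.0), atol=1e-12)

    def test_unit_circle_evaluates_on_circle(self):
        pc = parameterize(Contour(circle(64), "c"))
        u = np.linspace(0, 1, 1000, endpoint=False)
        r = np.linalg.norm(pc.evaluate(u), axis=1)
        assert np.abs(r - 1.0).max() < 1e-3

    def test_u_values_strictly_increasing_from_zero(self):
        pc = parameterize(Contour(bumpy_curve(25), "c"))
        assert pc.u_values[0] == 0.0
        assert np.all(np.diff(pc.u_values) > 0)
        assert pc.u_values[-1] < 1.0


class TestResample:
    def test_equally_spaced_input_recovered(self):
        # points equally spaced in chord length: resampling to own m is identity
        pts = circle(48)
        back = resample(parameterize(Contour(pts, "c")), 48)
        np.testing.assert_allclose(back.points, pts, atol=1e-8)

    def test_circle_resampling_gives_equal_arcs(self):
        pc = parameterize(Contour(circle(64), "c"))
        out = resample(pc, 101)
        seg = np.linalg.norm(np.roll(out.points, -1, axis=0) - out.points, axis=1)
        assert seg.max() / seg.min() < 1.01

    def test_square_corners_approximately_preserved(self):
        sq = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        out = resample(parameterize(Contour(sq, "sq")), 4)
        d = np.linalg.norm(out.points[:, None] - sq[None], axis=2).min(axis=1)
        assert d.max() < 0.2

    def test_m_below_four_rejected(self):
        pc = parameterize(Contour(circle(10), "c"))
        with pytest.raises(ValidationError):
            resample(pc, 3)


class TestOptimumRoll:
    def test_identity(self):
        t = Contour(bumpy_curve(30), "t")
        res = optimum_roll(t, t)
        assert res.roll == 0 and not res.reversed and res.energy == 0.0

    def test_planted_shift_recovered_with_zero_energy(self):
        pts = bumpy_curve(41)
        t = Contour(pts, "t")
        mv = Contour(np.roll(pts, 7, axis=0), "m")   # moving[i] = t[i-7]
        res = optimum_roll(mv, t)
        assert res.energy == 0.0 and not res.reversed and res.roll == 7
        np.testing.assert_array_equal(res.points, pts)

    def test_unequal_counts_rejected(self):
        with pytest.raises(ValidationError):
            optimum_roll(Contour(circle(10), "a"), Contour(circle(12), "b"))

    @given(st.integers(0, 2 ** 31 - 1))
    def test_reported_energy_is_brute_force_minimum(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(5, 25))
        a = Contour(rng.standard_normal((m, 2)), "a")
        b = Contour(rng.standard_normal((m, 2)), "b")
        res = optimum_roll(a, b)
        # exhaustive oracle over all 2m candidates, written independently
        energies = []
        for pts in (a.points, a.points[::-1]):
            for k in range(m):
                e = 0.0
                for i in range(m):
                    dx = pts[(i + k) % m] - b.points[i]
                    e += float(dx[0] * dx[0] + dx[1] * dx[1])
                energies.append(e)
        assert res.energy <= min(energies) + 1e-9 * max(min(energies), 1.0)


class TestCorrespondSample:
    def test_template_is_max_count_shape(self):
        shapes = [Contour(circle(100), "a"), Contour(circle(112), "b"),
                  Contour(circle(104), "c")]
        assert select_template(shapes) == 1

    def test_template_tie_broken_by_lowest_shape_id(self):
        shapes = [Contour(circle(50), "zebra"), Contour(circle(50), "apple")]
        assert select_template(shapes) == 1

    def test_identity_oracle_similarity_copies(self, rng):
        # equal-chord-spacing base so resampled grids coincide across shapes
        base = resample(parameterize(order_points(Contour(bumpy_curve(101), "b"))),
                        101).points
        shapes = []
        for i in range(6):
            T = random_similarity(rng)
            shapes.append(Contour(T.apply(base)[rng.permutation(101)], f"s{i}"))
        sample = correspond_sample(shapes)
        X = sample.coords()
        assert max(np.abs(X[i] - X[0]).max() for i in range(len(X))) < 1e-3

    def test_invariant_to_initial_point_ordering(self, rng):
        # the chain is deterministic in the point *multiset*, so two
        # different shuffles of the same shapes correspond identically
        base = bumpy_curve(60)
        shapes1, shapes2 = [], []
        for i in range(4):
            T = random_similarity(rng)
            pts = T.apply(base)
            shapes1.append(Contour(pts[rng.permutation(60)], f"s{i}"))
            shapes2.append(Contour(pts[rng.permutation(60)], f"s{i}"))
        X1 = correspond_sample(shapes1).coords()
        X2 = correspond_sample(shapes2).coords()
        np.testing.assert_allclose(X1, X2, atol=1e-6)

    def test_output_counts_equal_template_count(self, rng):
        shapes = [Contour(bumpy_curve(90), "a"), Contour(bumpy_curve(101), "b"),
                  Contour(bumpy_curve(95), "c")]
        sample = correspond_sample(shapes)
        assert sample.m == 101
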