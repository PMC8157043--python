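"""Contour correspondence: cyclic ordering, spline parameterization, resampling
and optimum-roll matching.

A registered contour whose points arrive in arbitrary order is turned into a
corresponded point set in four steps:

1. :func:`order_points` — recover a cyclic traversal order along the closed
   curve (nearest-neighbour tour refined by 2-opt, canonicalized to
   counter-clockwise orientation);
2. :func:`parameterize` — fit a periodic cubic spline through the ordered
   points, assigning each point a parametric position ``u`` in [0, 1) by
   normalized cumulative chord length (``u = 0`` and ``u = 1`` are the same
   location on the closed curve);
3. :func:`resample` — evaluate the spline at ``m`` equally spaced ``u``;
4. :func:`optimum_roll` — cyclically re-index (and possibly reverse) the
   resampled points to minimize the total squared distance to a template
   (the "deformation energy").

:func:`correspond_sample` chains these per shape against the template with
the maximum point count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .io import Contour, ShapeSample, ValidationError
from .registration import cpd_register

__all__ = [
    "ParameterizedContour",
    "CorrespondenceResult",
    "OrderingError",
    "order_points",
    "parameterize",
    "resample",
    "optimum_roll",
    "correspond_sample",
    "select_template",
]


class OrderingError(RuntimeError):
    """Point ordering produced an unresolvable self-intersecting traversal."""


# ----------------------------------------------------------------------------
# cyclic point ordering
# ----------------------------------------------------------------------------

def _nearest_neighbor_tour(pts: np.ndarray, start: int) -> np.ndarray:
    n = len(pts)
    D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    visited = np.zeros(n, dtype=bool)
    order = np.empty(n, dtype=int)
    order[0] = start
    visited[start] = True
    cur = start
    for k in range(1, n):
        d = D[cur].copy()
        d[visited] = np.inf
        cur = int(np.argmin(d))
        order[k] = cur
        visited[cur] = True
    return order


def _two_opt(pts: np.ndarray, order: np.ndarray, max_passes: int = 1000) -> np.ndarray:
    """Best-improvement 2-opt on a cyclic tour until no improving swap."""
    order = order.copy()
    n = len(order)
    for _ in range(max_passes):
        p = pts[order]
        nxt = np.roll(np.arange(n), -1)
        edge = np.linalg.norm(p[nxt] - p, axis=1)            # d(i, i+1)
        D = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=2)
        # delta(i, j) for replacing edges (i,i+1),(j,j+1) by (i,j),(i+1,j+1)
        delta = D + D[nxt][:, nxt] - edge[:, None] - edge[None, :]
        iu = np.triu_indices(n, k=2)
        dvals = delta[iu]
        best = int(np.argmin(dvals))
        if dvals[best] >= -1e-12:
            return order
        i, j = int(iu[0][best]), int(iu[1][best])
        if i == 0 and j == n - 1:       # same edge pair on the cycle
            d2 = dvals.copy()
            d2[best] = np.inf
            best = int(np.argmin(d2))
            if d2[best] >= -1e-12:
                return order
            i, j = int(iu[0][best]), int(iu[1][best])
        order[i + 1:j + 1] = order[i + 1:j + 1][::-1]
    return order


def _count_self_intersections(pts: np.ndarray) -> int:
    """Count proper crossings between non-adjacent segments of a closed tour."""
    n = len(pts)
    a = pts
    b = np.roll(pts, -1, axis=0)
    count = 0
    for i in range(n):
        js = np.arange(i + 2, n)
        js = js[(js - i) % n != n - 1]          # skip segments adjacent to i
        if len(js) == 0:
            continue
        p, r = a[i], b[i] - a[i]
        q, s = a[js], b[js] - a[js]
        rxs = r[0] * s[:, 1] - r[1] * s[:, 0]
        qp = q - p
        t = (qp[:, 0] * s[:, 1] - qp[:, 1] * s[:, 0]) / np.where(rxs == 0, np.nan, rxs)
        u = (qp[:, 0] * r[1] - qp[:, 1] * r[0]) / np.where(rxs == 0, np.nan, rxs)
        hit = (t > 1e-12) & (t < 1 - 1e-12) & (u > 1e-12) & (u < 1 - 1e-12)
        count += int(np.count_nonzero(hit & np.isfinite(t)))
    return count


def order_points(c: Contour) -> Contour:
    """Return the contour's points in counter-clockwise cyclic traversal order.

    The ordering is a permutation of the input points: a nearest-neighbour
    tour started from the point whose angle about the centroid is closest to
    zero, refined by 2-opt until no improving swap remains, then oriented
    counter-clockwise (positive signed area). Already-ordered input comes
    back cyclically equal to itself.
    """
    pts = c.points
    ang = np.arctan2(pts[:, 1] - pts[:, 1].mean(), pts[:, 0] - pts[:, 0].mean())
    start = int(np.argmin(np.abs(ang)))
    # two initial tours: angular sort about the centroid (exact for
    # star-shaped outlines) and a nearest-neighbour tour (robust when the
    # outline folds back over its centroid); 2-opt refines both and the
    # shorter tour wins.
    candidates = [np.argsort(ang), _nearest_neighbor_tour(pts, start)]
    best_order, best_len = None, np.inf
    for init in candidates:
        order = _two_opt(pts, init)
        q = pts[order]
        length = float(np.linalg.norm(np.roll(q, -1, axis=0) - q, axis=1).sum())
        if length < best_len:
            best_order, best_len = order, length
    ordered = pts[best_order]
    if _count_self_intersections(ordered) > 0:
        raise OrderingError(
            f"contour {c.shape_id!r}: ordered traversal still self-intersects; "
            "the point cloud may not describe a simple closed curve"
        )
    # canonical counter-clockwise orientation via the signed area
    x, y = ordered[:, 0], ordered[:, 1]
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area < 0:
        ordered = ordered[::-1]
    return c.with_points(ordered)


# ----------------------------------------------------------------------------
# parameterization and resampling
# ----------------------------------------------------------------------------

@dataclass
class ParameterizedContour:
    """Periodic cubic-spline representation of an ordered closed contour."""

    control: CubicSpline
    u_values: np.ndarray
    points: np.ndarray
    shape_id: str = ""

    def evaluate(self, u) -> np.ndarray:
        return self.control(np.mod(u, 1.0))


def parameterize(c: Contour) -> ParameterizedContour:
    """Fit a periodic cubic spline through an ordered contour.

    Knot positions ``u`` are assigned by normalized cumulative chord length,
    so ``u[0] = 0`` and the implicit closing point sits at ``u = 1`` (the
    same curve location as ``u = 0``). Evaluating at the stored ``u_values``
    reproduces the input points to interpolation accuracy.
    """
    pts = c.points
    seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    if np.any(seg == 0):
        raise ValidationError(f"contour {c.shape_id!r}: duplicate consecutive points")
    total = seg.sum()
    u = np.concatenate([[0.0], np.cumsum(seg)]) / total     # length m+1, ends at 1
    closed_pts = np.vstack([pts, pts[:1]])
    spline = CubicSpline(u, closed_pts, bc_type="periodic")
    return ParameterizedContour(control=spline, u_values=u[:-1], points=pts,
                                shape_id=c.shape_id)


def resample(pc: ParameterizedContour, m: int) -> Contour:
    """Sample the fitted curve at ``m`` equally spaced parametric positions."""
    if m < 4:
        raise ValidationError(f"resample: m must be >= 4, got {m}")
    u = np.arange(m) / m
    return Contour(points=pc.evaluate(u), shape_id=pc.shape_id)


# ----------------------------------------------------------------------------
# optimum roll
# ----------------------------------------------------------------------------

@dataclass
class CorrespondenceResult:
    points: np.ndarray      # moving points after roll (and optional reversal)
    roll: int
    reversed: bool
    energy: float
    log: dict = field(default_factory=dict)


def roll_energy(moving_pts: np.ndarray, template_pts: np.ndarray, k: int) -> float:
    """Deformation energy sum_i ||moving[(i+k) mod m] - template[i]||^2."""
    return float(np.sum((np.roll(moving_pts, -k, axis=0) - template_pts) ** 2))


def optimum_roll(moving: Contour, template: Contour) -> CorrespondenceResult:
    """Cyclically re-index ``moving`` to best match ``template``.

    All ``m`` cyclic shifts are evaluated for both traversal orientations
    (as-is and reversed) and the minimum-energy candidate is returned. Ties
    prefer the unreversed orientation, then the smallest shift.
    """
    a, t = moving.points, template.points
    if len(a) != len(t):
        raise ValidationError(
            f"optimum_roll: unequal point counts ({len(a)} vs {len(t)})"
        )
    m = len(a)
    best = None
    for rev in (False, True):
        pts = a[::-1] if rev else a
        for k in range(m):
            e = roll_energy(pts, t, k)
            if best is None or e < best[0]:
                best = (e, k, rev)
    e, k, rev = best
    pts = a[::-1] if rev else a
    return CorrespondenceResult(points=np.roll(pts, -k, axis=0), roll=k,
                                reversed=rev, energy=e)


# ----------------------------------------------------------------------------
# whole-sample correspondence
# ----------------------------------------------------------------------------

def select_template(shapes) -> int:
    """Index of the template: maximum point count, ties by lowest shape_id."""
    best = 0
    for i, s in enumerate(shapes[1:], start=1):
        b = shapes[best]
        if s.m > b.m or (s.m == b.m and str(s.shape_id) < str(b.shape_id)):
            best = i
    return best


def correspond_sample(shapes, group=None, covariates=None, w: float = 0.0,
                      tol: float = 1e-8, max_iter: int = 300,
                      return_log: bool = False):
    """Register, order, resample and roll a set of contours into correspondence.

    The shape with the maximum number of contour points serves as the
    template. Every other shape is CPD-registered onto it, ordered,
    spline-parameterized, resampled to the template's point count, and
    optimally rolled against the (ordered, resampled) template.
    """
    shapes = list(shapes)
    if len(shapes) < 2:
        raise ValidationError("correspond_sample needs at least 2 shapes")
    ti = select_template(shapes)
    template = shapes[ti]
    t_ordered = order_points(template)
    m = template.m
    t_final = resample(parameterize(t_ordered), m)

    out = [None] * len(shapes)
    logs = [None] * len(shapes)
    out[ti] = t_final
    logs[ti] = {"shape_id": template.shape_id, "template": True}
    for i, s in enumerate(shapes):
        if i == ti:
            continue
        try:
            reg = cpd_register(s, t_final, w=w, tol=tol, max_iter=max_iter)
            aligned = s.with_points(reg.aligned)
            ordered = order_points(aligned)
            res = resample(parameterize(ordered), m)
            rolled = optimum_roll(res, t_final)
        except Exception as e:
            raise type(e)(f"shape {s.shape_id!r}: {e}") from e
        out[i] = s.with_points(rolled.points)
        logs[i] = {"shape_id": s.shape_id, "template": False,
                   "cpd_iterations": reg.iterations, "cpd_converged": reg.converged,
                   "roll": rolled.roll, "reversed": rolled.reversed,
                   "energy": rolled.energy}
    if group is None:
        group = ["all"] * len(shapes)
    sample = ShapeSample(shapes=out, group=list(group),
                         covariates=dict(covariates or {}))
    if return_log:
        return sample, logs
    return sample
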