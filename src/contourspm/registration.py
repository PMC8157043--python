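"""Point-set registration: coherent point drift (CPD) and Procrustes alignment.

CPD treats the moving point set as centroids of a Gaussian mixture fitted to
the fixed set by expectation-maximization, so it requires neither
corresponding points nor an equal number of points. Only the similarity
(rigid + isotropic scale) variant is exposed by default: downstream analysis
interprets residual deformation as signal, and a nonrigid transform would
absorb it.

Generalized Procrustes Analysis (GPA) aligns *corresponded* point sets:
every shape is centered, scaled to unit centroid size, and rotated onto the
evolving mean shape until the mean stops moving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Contour, ShapeSample, ValidationError

__all__ = [
    "SimilarityTransform",
    "CPDResult",
    "cpd_register",
    "gpa_align",
    "procrustes_rotation",
    "centroid_size",
    "DegenerateInputError",
]


class DegenerateInputError(ValueError):
    """Numerically degenerate input (e.g. all points coincident)."""


@dataclass(frozen=True)
class SimilarityTransform:
    """x -> scale * rotation @ x + translation, with det(rotation) = +1."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (2, 2):
            raise ValidationError("rotation must be 2x2")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise ValidationError("rotation must be proper (det = +1)")
        if self.scale <= 0:
            raise ValidationError("scale must be positive")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * points @ self.rotation.T + self.translation

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        sinv = 1.0 / self.scale
        return SimilarityTransform(rotation=Rinv, scale=sinv,
                                   translation=-sinv * Rinv @ self.translation)

    @staticmethod
    def identity() -> "SimilarityTransform":
        return SimilarityTransform(rotation=np.eye(2), scale=1.0, translation=np.zeros(2))

    @staticmethod
    def from_angle(angle: float, scale: float = 1.0, translation=(0.0, 0.0)) -> "SimilarityTransform":
        c, s = np.cos(angle), np.sin(angle)
        return SimilarityTransform(rotation=np.array([[c, -s], [s, c]]), scale=scale,
                                   translation=np.asarray(translation, dtype=float))


@dataclass
class CPDResult:
    aligned: np.ndarray
    transform: SimilarityTransform
    iterations: int
    converged: bool
    final_objective: float


def _points_of(obj) -> np.ndarray:
    return obj.points if hasattr(obj, "points") else np.asarray(obj, dtype=float)


def cpd_register(moving, fixed, w: float = 0.0, tol: float = 1e-8,
                 max_iter: int = 300, n_starts: int = 8) -> CPDResult:
    """Register ``moving`` onto ``fixed`` with similarity-variant CPD.

    Parameters
    ----------
    moving, fixed
        Contours (or (n, 2) arrays). Point counts may differ and no
        correspondence is assumed.
    w
        Outlier weight in [0, 1); 0 for clean closed contours.
    tol
        Convergence tolerance on the relative change of the EM objective
        (negative log-likelihood).
    max_iter
        Iteration cap (per start).
    n_starts
        Number of evenly spaced initial rotations. The EM objective has
        local optima under large rotations; the best final likelihood over
        all starts is returned.

    Returns
    -------
    CPDResult
        With ``aligned = transform.apply(moving)``; ``converged`` is true iff
        the relative objective change fell below ``tol`` before ``max_iter``.
    """
    X = _points_of(fixed)    # data points, (N, 2)
    Y = _points_of(moving)   # GMM centroids, (M, 2)
    if not 0.0 <= w < 1.0:
        raise ValidationError(f"outlier weight w must be in [0, 1), got {w}")
    if np.allclose(X, X[0], atol=1e-15) or np.allclose(Y, Y[0], atol=1e-15):
        raise DegenerateInputError("all points coincident; cannot register")
    n_starts = max(1, n_starts)
    if n_starts == 1:
        return _cpd_em(X, Y, np.eye(2), w, tol, max_iter)
    # short EM probe from each initial rotation, then refine the best basin
    probes = []
    for k in range(n_starts):
        angle = 2.0 * np.pi * k / n_starts
        ca, sa = np.cos(angle), np.sin(angle)
        R0 = np.array([[ca, -sa], [sa, ca]])
        probes.append((_cpd_em(X, Y, R0, w, max(tol, 1e-5), 30), R0))
    best_probe = min(probes, key=lambda pr: pr[0].final_objective)
    return _cpd_em(X, Y, best_probe[0].transform.rotation, w, tol, max_iter,
                   init_scale=best_probe[0].transform.scale,
                   init_translation=best_probe[0].transform.translation)


def _cpd_em(X: np.ndarray, Y: np.ndarray, R_init: np.ndarray, w: float,
            tol: float, max_iter: int, init_scale: float = 1.0,
            init_translation: np.ndarray | None = None) -> CPDResult:
    N, M, D = len(X), len(Y), 2
    R = R_init
    s = init_scale
    if init_translation is None:
        t = X.mean(axis=0) - s * R @ Y.mean(axis=0)
    else:
        t = init_translation
    TY = s * Y @ R.T + t
    X2 = (X ** 2).sum(axis=1)                                          # (N,)
    d2 = X2[None, :] + (TY ** 2).sum(axis=1)[:, None] - 2.0 * TY @ X.T
    sigma2 = d2.sum() / (D * N * M)
    if sigma2 <= 0:
        raise DegenerateInputError("zero initial variance; degenerate input")

    prev_obj = np.inf
    obj = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: posterior P[m, n] that data point n was generated by centroid m
        d2 = X2[None, :] + (TY ** 2).sum(axis=1)[:, None] - 2.0 * TY @ X.T
        np.maximum(d2, 0.0, out=d2)
        num = np.exp(-d2 / (2.0 * sigma2))
        c = (2.0 * np.pi * sigma2) ** (D / 2.0) * (w / (1.0 - w)) * (M / N)
        den = num.sum(axis=0) + c
        den = np.where(den > 0, den, np.finfo(float).tiny)
        P = num / den

        Np = P.sum()
        if Np < 10 * np.finfo(float).tiny:
            break  # mixture collapsed onto the outlier class
        P1 = P.sum(axis=1)      # (M,)
        Pt1 = P.sum(axis=0)     # (N,)

        # negative log-likelihood of the current mixture (up to a constant)
        obj = float(-np.log(den).sum() + N * D / 2.0 * np.log(2.0 * np.pi * sigma2))

        # M-step: closed-form similarity update
        mu_x = (Pt1 @ X) / Np
        mu_y = (P1 @ Y) / Np
        Xh = X - mu_x
        Yh = Y - mu_y
        A = Xh.T @ (P.T @ Yh)                       # (2, 2)
        U, S, Vt = np.linalg.svd(A)
        Cdiag = np.ones(D)
        Cdiag[-1] = np.sign(np.linalg.det(U @ Vt))
        R = U @ np.diag(Cdiag) @ Vt
        denom = float(np.einsum("m,mi,mi->", P1, Yh, Yh))
        if denom <= 0:
            raise DegenerateInputError("degenerate moving set during CPD update")
        s = float((S * Cdiag).sum() / denom)
        t = mu_x - s * R @ mu_y
        TY = s * Y @ R.T + t

        trXPX = float(np.einsum("n,ni,ni->", Pt1, Xh, Xh))
        sigma2_new = (trXPX - s * float((S * Cdiag).sum())) / (Np * D)
        sigma2 = max(sigma2_new, 1e-12 * max(trXPX / (Np * D), 1e-30))

        if np.isfinite(prev_obj):
            rel = abs(prev_obj - obj) / max(abs(prev_obj), 1e-30)
            if rel < tol:
                converged = True
                prev_obj = obj
                break
        prev_obj = obj

    transform = SimilarityTransform(rotation=R, scale=s, translation=t)
    return CPDResult(aligned=transform.apply(Y), transform=transform,
                     iterations=it, converged=converged, final_objective=float(prev_obj))


# ----------------------------------------------------------------------------
# Procrustes alignment of corresponded point sets
# ----------------------------------------------------------------------------

def centroid_size(points: np.ndarray) -> float:
    """Root-sum-of-squares distance of points from their centroid."""
    c = points.mean(axis=0)
    return float(np.sqrt(((points - c) ** 2).sum()))


def procrustes_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||a - b R^T||_F (Kabsch, no reflection)."""
    A = a.T @ b
    U, S, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(U @ Vt))
    C = np.diag([1.0, d])
    return U @ C @ Vt


def gpa_align(sample: ShapeSample, tol: float = 1e-10, max_iter: int = 100) -> ShapeSample:
    """Generalized Procrustes Analysis with unit centroid-size scaling.

    Every shape is centered at the origin and scaled to centroid size 1,
    then iteratively rotated onto the evolving mean shape (itself
    renormalized to unit size each round). Stops when the mean shape moves
    less than ``tol`` in Frobenius norm. Idempotent to within ``tol``.
    """
    if len(sample) < 2:
        raise ValidationError("GPA needs at least 2 shapes")
    coords = sample.coords().astype(float)
    for i in range(len(coords)):
        coords[i] -= coords[i].mean(axis=0)
        size = np.sqrt((coords[i] ** 2).sum())
        if size == 0:
            raise DegenerateInputError(f"shape {i}: zero centroid size")
        coords[i] /= size

    mean = coords[0].copy()
    mean /= np.sqrt((mean ** 2).sum())
    for _ in range(max_iter):
        for i in range(len(coords)):
            R = procrustes_rotation(mean, coords[i])
            coords[i] = coords[i] @ R.T
        new_mean = coords.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        norm = np.sqrt((new_mean ** 2).sum())
        if norm == 0:
            raise DegenerateInputError("GPA mean shape collapsed to a point")
        new_mean /= norm
        if np.sqrt(((new_mean - mean) ** 2).sum()) < tol:
            mean = new_mean
            break
        mean = new_mean
    return sample.with_coords(coords)
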