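"""Hastie-Stuetzle principal curves.

A principal curve is a smooth one-dimensional curve through a point
cloud that is self-consistent: each point of the curve is the average
of the data that project onto it.  The fitting loop alternates

1. projection: each data point is assigned the arc-length position of
   its nearest point on the current curve (a polyline);
2. smoothing: each coordinate is smoothed as a function of the
   arc-length parameter with a local-regression (lowess) smoother;
3. re-parameterization: the smoothed vertices are re-indexed by
   cumulative Euclidean arc length,

starting from the segment of the first principal component, until the
total squared projection distance stops improving.  The recorded
criterion sequence is non-increasing by construction: an iteration that
would increase it terminates the loop and the previous curve is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = ["PrincipalCurve", "fit_principal_curve", "project_to_polyline"]


@dataclass
class PrincipalCurve:
    """Fitted curve: ordered vertices plus their cumulative arc length."""

    points: np.ndarray          # m x d curve vertices, ordered along the curve
    arc_length: np.ndarray      # m nonnegative, arc_length[0] == 0, increasing
    distances_per_iter: list[float] | None = None  # total squared projection distance

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def project(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Arc-length positions and squared distances of points projected on the curve."""
        return project_to_polyline(np.asarray(X, dtype=float), self.points, self.arc_length)


def project_to_polyline(
    X: np.ndarray, vertices: np.ndarray, arc_length: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto a polyline.

    Returns ``(lam, d2)``: the arc-length coordinate of each point's
    nearest polyline position, and the squared Euclidean projection
    distance.  Ties between equally distant positions resolve to the
    smaller arc length.
    """
    X = np.atleast_2d(X)
    n = X.shape[0]
    m = vertices.shape[0]
    if m == 1:
        d2 = np.sum((X - vertices[0]) ** 2, axis=1)
        return np.zeros(n), d2
    a = vertices[:-1]                      # (m-1, d) segment starts
    ab = vertices[1:] - a                  # segment vectors
    seg_len2 = np.sum(ab * ab, axis=1)
    seg_len2 = np.where(seg_len2 == 0, 1.0, seg_len2)
    # broadcast: for each point, projection parameter t on each segment
    ap = X[:, None, :] - a[None, :, :]     # (n, m-1, d)
    t = np.einsum("nmd,md->nm", ap, ab) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d2_all = np.sum((X[:, None, :] - proj) ** 2, axis=2)
    best = np.argmin(d2_all, axis=1)       # argmin takes the first (smaller arc) on ties
    idx = np.arange(n)
    seg_base = arc_length[:-1]
    seg_span = arc_length[1:] - arc_length[:-1]
    lam = seg_base[best] + t[idx, best] * seg_span[best]
    return lam, d2_all[idx, best]


def _arc_length_of(points: np.ndarray) -> np.ndarray:
    steps = np.sqrt(np.sum(np.diff(points, axis=0) ** 2, axis=1))
    return np.concatenate([[0.0], np.cumsum(steps)])


def _smooth_coordinates(lam: np.ndarray, X: np.ndarray, span: float) -> np.ndarray:
    """Lowess-smooth each coordinate against the arc-length parameter."""
    order = np.argsort(lam, kind="stable")
    lam_s = lam[order]
    smoothed = np.empty_like(X)
    for j in range(X.shape[1]):
        fit = lowess(
            X[order, j], lam_s, frac=span, it=0, return_sorted=False
        )
        smoothed[order, j] = fit
    return smoothed[order], order


def fit_principal_curve(
    points: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-4,
    smoother_span: float = 0.6,
) -> PrincipalCurve:
    """Fit a Hastie-Stuetzle principal curve to an n x d point cloud.

    Parameters
    ----------
    points : ndarray
        n x d data, n >= 3, no missing values.
    max_iter : int
        Maximum projection/smoothing iterations.
    tol : float
        Convergence threshold on the relative change of the total
        squared projection distance.
    smoother_span : float
        Lowess span (fraction of points in each local fit).
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("points must be an n x d matrix with d >= 1")
    n, d = X.shape
    if n < 3:
        raise ValueError("principal curve needs at least 3 points")
    if np.isnan(X).any():
        raise ValueError("points contain missing values")
    center = X.mean(axis=0)
    Xc = X - center
    if np.allclose(Xc, 0):
        raise ValueError("all points identical: degenerate cloud")

    # initialization: orthogonal projection on the first principal component
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    v1 = vt[0]
    lam = Xc @ v1
    order = np.argsort(lam, kind="stable")
    vertices = center + np.outer(lam[order], v1)
    arc = _arc_length_of(vertices)
    lam_cur, d2 = project_to_polyline(X, vertices, arc)
    dist = float(d2.sum())
    history = [dist]

    best = PrincipalCurve(vertices, arc, history)
    for _ in range(max_iter):
        smoothed_sorted, order = _smooth_coordinates(lam_cur, X, smoother_span)
        # drop duplicate consecutive vertices (ties in lambda collapse)
        keep = np.ones(len(smoothed_sorted), dtype=bool)
        keep[1:] = np.any(np.diff(smoothed_sorted, axis=0) != 0, axis=1)
        vertices = smoothed_sorted[keep]
        if vertices.shape[0] < 2:
            break
        arc = _arc_length_of(vertices)
        lam_new, d2 = project_to_polyline(X, vertices, arc)
        new_dist = float(d2.sum())
        if new_dist > dist:
            break  # keep the previous (better) curve
        history.append(new_dist)
        best = PrincipalCurve(vertices, arc, history)
        improvement = (dist - new_dist) / dist if dist > 0 else 0.0
        lam_cur = lam_new
        dist = new_dist
        if improvement < tol:
            break
    return best
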