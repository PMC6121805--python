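"""Reduce 2D shore coordinates to a 1D transect axis.

A piecewise-linear path (11 segments in the study shore) is fitted through
the cloud of snail coordinates by minimizing the mean squared orthogonal
distance of the points to the path.  Every sample is then projected onto
the path and its cumulative distance from the northern (Crab) end is the
1D position used by all cline models.  Habitat survey points are projected
the same way to locate the habitat transitions on the axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import InvalidGeometryError, MissingDataError

__all__ = [
    "TransectPath",
    "HabitatSurvey",
    "TransectPathFitter",
    "fit_polyline",
    "project_to_path",
    "detect_habitat_transitions",
]


@dataclass
class TransectPath:
    """Ordered polyline with cumulative distances from the Crab end."""

    vertices: np.ndarray  # (n_segments + 1, 2) metres

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise InvalidGeometryError("vertices must be an (m, 2) array")
        if self.vertices.shape[0] < 2:
            raise InvalidGeometryError("a path needs at least two vertices")

    @property
    def n_segments(self) -> int:
        return self.vertices.shape[0] - 1

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)

    @property
    def cumulative_length(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths)])

    @property
    def total_length(self) -> float:
        return float(self.cumulative_length[-1])


@dataclass
class HabitatSurvey:
    """Habitat labels recorded at surveyed (x, y) points."""

    points_xy: np.ndarray  # (n, 2)
    labels: np.ndarray  # (n,) str

    def __post_init__(self) -> None:
        self.points_xy = np.asarray(self.points_xy, dtype=float)
        self.labels = np.asarray(self.labels)
        if len(self.points_xy) != len(self.labels):
            raise InvalidGeometryError("points and labels must align")


def _point_segment_data(path: TransectPath, pts: np.ndarray):
    """Distances and arc positions of pts w.r.t. every path segment."""
    v0 = path.vertices[:-1]  # (S, 2)
    dv = np.diff(path.vertices, axis=0)  # (S, 2)
    seg_len2 = np.maximum(np.sum(dv * dv, axis=1), 1e-300)
    rel = pts[:, None, :] - v0[None, :, :]  # (n, S, 2)
    t = np.clip(np.sum(rel * dv[None], axis=2) / seg_len2[None], 0.0, 1.0)
    foot = v0[None] + t[..., None] * dv[None]
    dist = np.linalg.norm(pts[:, None, :] - foot, axis=2)  # (n, S)
    arc = path.cumulative_length[:-1][None] + t * np.sqrt(seg_len2)[None]
    return dist, arc


def project_to_path(path: TransectPath, points):
    """Project point(s) onto the path.

    Returns (path_position, distance); positions are cumulative metres from
    the path start.  A point equidistant from two segments takes the
    smaller cumulative distance (deterministic, order-independent).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dist, arc = _point_segment_data(path, pts)
    # tie-break: among segments within 1e-9 of the minimum pick smallest arc
    dmin = dist.min(axis=1, keepdims=True)
    tied = dist <= dmin + 1e-9
    arc_masked = np.where(tied, arc, np.inf)
    pos = arc_masked.min(axis=1)
    d = dmin[:, 0]
    if np.ndim(points) == 1:
        return float(pos[0]), float(d[0])
    return pos, d


def _objective(flat_vertices: np.ndarray, pts: np.ndarray, m: int) -> float:
    path = TransectPath(flat_vertices.reshape(m, 2))
    dist, _ = _point_segment_data(path, pts)
    return float(np.mean(dist.min(axis=1) ** 2))


def fit_polyline(points_xy, n_segments: int = 11, maxiter: int = 400,
                 refine: bool = True) -> TransectPath:
    """Fit an ``n_segments``-piece polyline minimizing mean squared distance.

    Vertices are initialized at quantile centroids of the points ordered
    along the first principal axis, then all vertex coordinates are refined
    with bounded quasi-Newton search.  The result is a local optimum of the
    mean squared orthogonal point-to-path distance.
    """
    pts = np.asarray(points_xy, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidGeometryError("points must be an (n, 2) array")
    uniq = np.unique(pts, axis=0)
    if len(uniq) < n_segments + 1:
        raise InvalidGeometryError(
            f"need at least {n_segments + 1} distinct points, got {len(uniq)}"
        )
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered
    if np.linalg.matrix_rank(cov, tol=1e-12) == 0:
        raise InvalidGeometryError("all points identical")
    _, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]
    proj = centered @ axis
    order = np.argsort(proj)
    groups = np.array_split(order, n_segments + 1)
    verts = np.array([pts[g].mean(axis=0) for g in groups])
    if n_segments == 1:
        # closed-form special case: the total-least-squares (principal-axis)
        # line, extended to cover the projections of all points
        lo, hi = proj.min(), proj.max()
        return TransectPath(np.stack([pts.mean(axis=0) + lo * axis,
                                      pts.mean(axis=0) + hi * axis]))
    if not refine:
        return TransectPath(verts)
    m = n_segments + 1
    res = minimize(
        _objective, verts.ravel(), args=(pts, m), method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-12},
    )
    fitted = TransectPath(res.x.reshape(m, 2))
    # keep the refined path only if it did not degrade the start
    if _objective(res.x, pts, m) <= _objective(verts.ravel(), pts, m):
        return fitted
    return TransectPath(verts)


def polyline_objective(path: TransectPath, points_xy) -> float:
    """Mean squared orthogonal distance of points to the path."""
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    dist, _ = _point_segment_data(path, pts)
    return float(np.mean(dist.min(axis=1) ** 2))


def _majority_smooth(labels: np.ndarray, window: int = 5) -> np.ndarray:
    """Sliding-window majority vote over an ordered categorical sequence."""
    n = len(labels)
    half = window // 2
    out = labels.copy()
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        vals, counts = np.unique(labels[lo:hi], return_counts=True)
        top = counts.max()
        winners = vals[counts == top]
        out[i] = labels[i] if labels[i] in winners else winners[0]
    return out


def detect_habitat_transitions(survey: HabitatSurvey, path: TransectPath,
                               smooth_window: int = 5) -> np.ndarray:
    """Positions (metres along path) where the smoothed habitat changes.

    Survey points are projected onto the path, ordered, majority-smoothed
    over ``smooth_window`` points, and each transition is placed at the
    midpoint between the flanking survey points.
    """
    if len(survey.labels) == 0:
        raise MissingDataError("habitat survey is empty")
    pos, _ = project_to_path(path, survey.points_xy)
    pos = np.atleast_1d(pos)
    order = np.argsort(pos, kind="stable")
    pos, labels = pos[order], survey.labels[order]
    smoothed = _majority_smooth(labels, smooth_window)
    change = smoothed[1:] != smoothed[:-1]
    return 0.5 * (pos[1:][change] + pos[:-1][change])


class TransectPathFitter(BaseEstimator, TransformerMixin):
    """Transformer reducing 2D coordinates to 1D transect positions.

    ``fit(X)`` fits the polyline through the (n, 2) coordinates;
    ``transform(X)`` returns an (n, 2) array of (path position, orthogonal
    distance).  Fitted attributes: ``path_``, ``objective_``.
    """

    def __init__(self, n_segments: int = 11, maxiter: int = 400):
        self.n_segments = n_segments
        self.maxiter = maxiter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.path_ = fit_polyline(X, self.n_segments, self.maxiter)
        self.objective_ = polyline_objective(self.path_, X)
        self.n_features_in_ = 2
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "path_")
        pos, dist = project_to_path(self.path_, np.asarray(X, dtype=float))
        return np.column_stack([pos, dist])
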