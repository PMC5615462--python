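"""Shared polyline geometry helpers (mm-plane computations).

Coordinate convention used everywhere in the package: origin at the top-left,
x rightward, y downward, pixel centers at integer coordinates.  Points are
``(x, y)`` pairs; arrays of points have shape ``(n, 2)``.
"""

from __future__ import annotations

import numpy as np


def polyline_length(points: np.ndarray) -> float:
    """Total arc length of an open polyline given as (m, 2) vertices."""
    pts = np.asarray(points, dtype=float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def dist_to_polyline(pts: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Euclidean distance from each query point to an open polyline.

    Parameters
    ----------
    pts : (n, 2) array of query points.
    vertices : (m, 2) array of polyline vertices, m >= 2.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    v = np.asarray(vertices, dtype=float)
    d = np.full(pts.shape[0], np.inf)
    for a, b in zip(v[:-1], v[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            seg_d = np.linalg.norm(pts - a, axis=1)
        else:
            t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
            seg_d = np.linalg.norm(pts - proj, axis=1)
        np.minimum(d, seg_d, out=d)
    return d


def point_at_arclength(vertices: np.ndarray, s: np.ndarray):
    """Point(s) and unit tangent(s) on a polyline at arc length(s) ``s``.

    ``s`` is clipped to [0, L].  Returns ``(points (n,2), tangents (n,2))``.
    At a vertex the tangent of the following segment is used (the final
    vertex keeps the last segment's tangent).
    """
    v = np.asarray(vertices, dtype=float)
    seg = np.diff(v, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, total)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    local = (s - cum[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
    pts = v[idx] + local[:, None] * seg[idx]
    tangents = seg[idx] / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)[:, None]
    return pts, tangents


def diagonal_extremes(points: np.ndarray) -> np.ndarray:
    """The four diagonal-extreme points of a point set.

    Returns a (4, 2) array ordered up-left, up-right, down-left, down-right,
    selected as argmin(x+y), argmax(x-y), argmax(y-x), argmax(x+y).
    """
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return np.stack([
        p[np.argmin(x + y)],
        p[np.argmax(x - y)],
        p[np.argmax(y - x)],
        p[np.argmax(x + y)],
    ])


def quad_area(corners: np.ndarray) -> float:
    """Shoelace area of the quadrilateral up-left, up-right, down-right, down-left."""
    c = np.asarray(corners, dtype=float)
    ordered = c[[0, 1, 3, 2]]  # ul, ur, dr, dl -> boundary order
    x, y = ordered[:, 0], ordered[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def estimate_projective(src: np.ndarray, dst: np.ndarray) -> np.ndarray | None:
    """3x3 projective map taking src points to dst points, or None on failure.

    Wraps the skimage estimator across its API change (``from_estimate``
    vs the older ``estimate`` method).
    """
    from skimage.transform import ProjectiveTransform

    if hasattr(ProjectiveTransform, "from_estimate"):
        tf = ProjectiveTransform.from_estimate(src, dst)
        if not tf:
            return None
        params = tf.params
    else:
        tf = ProjectiveTransform()
        if not tf.estimate(src, dst):
            return None
        params = tf.params
    if not np.all(np.isfinite(params)):
        return None
    return params


def apply_homography(h: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Apply a 3x3 projective map to (n, 2) points."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    hom = np.column_stack([pts, np.ones(len(pts))]) @ np.asarray(h, dtype=float).T
    return hom[:, :2] / hom[:, 2:3]
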