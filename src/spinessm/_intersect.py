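"""Triangle-triangle intersection testing (vectorized Möller–Trumbore edge tests).

Two non-coplanar triangles intersect iff an edge of one pierces the
interior of the other; coplanar pairs are handled separately by a 2D
overlap test (vertex containment or edge crossing) in the shared plane.
"""

from __future__ import annotations

import numpy as np

__all__ = ["any_triangles_intersect"]

_EPS = 1e-12


def _segments_hit_triangles(orig, vec, tri):
    """Boolean per row: does segment orig→orig+vec cross triangle tri?"""
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    h = np.cross(vec, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > _EPS
    f = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
    s = orig - v0
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * np.einsum("ij,ij->i", vec, q)
    t = f * np.einsum("ij,ij->i", e2, q)
    return (
        ok
        & (u >= -_EPS)
        & (v >= -_EPS)
        & (u + v <= 1.0 + _EPS)
        & (t >= -_EPS)
        & (t <= 1.0 + _EPS)
    )


def _cross2(u, v) -> float:
    return u[0] * v[1] - u[1] * v[0]


def _point_in_tri_2d(p, a, b, c) -> bool:
    d1 = _cross2(b - a, p - a)
    d2 = _cross2(c - b, p - b)
    d3 = _cross2(a - c, p - c)
    return (d1 >= -_EPS and d2 >= -_EPS and d3 >= -_EPS) or (
        d1 <= _EPS and d2 <= _EPS and d3 <= _EPS
    )


def _segments_cross_2d(p1, p2, q1, q2) -> bool:
    def d(a, b, c):
        return _cross2(b - a, c - a)

    return (
        d(p1, p2, q1) * d(p1, p2, q2) < -_EPS
        and d(q1, q2, p1) * d(q1, q2, p2) < -_EPS
    )


def _coplanar_overlap(t1: np.ndarray, t2: np.ndarray, tol: float) -> bool:
    """2D overlap of two triangles known to lie in (nearly) the same plane."""
    n = np.cross(t1[1] - t1[0], t1[2] - t1[0])
    nn = np.linalg.norm(n)
    if nn < _EPS:
        return False  # degenerate triangle
    n /= nn
    if np.abs((t2 - t1[0]) @ n).max() > tol:
        return False  # not actually coplanar
    u = t1[1] - t1[0]
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    a = (t1 - t1[0]) @ np.column_stack([u, v])
    b = (t2 - t1[0]) @ np.column_stack([u, v])
    for p in b:
        if _point_in_tri_2d(p, *a):
            return True
    for p in a:
        if _point_in_tri_2d(p, *b):
            return True
    for i in range(3):
        for j in range(3):
            if _segments_cross_2d(a[i], a[(i + 1) % 3], b[j], b[(j + 1) % 3]):
                return True
    return False


def any_triangles_intersect(
    tris_a: np.ndarray, tris_b: np.ndarray, coplanar_tol: float = 1e-9
) -> bool:
    """True if any triangle of ``tris_a`` (Na,3,3) intersects any of ``tris_b``."""
    tris_a = np.asarray(tris_a, float)
    tris_b = np.asarray(tris_b, float)
    if len(tris_a) == 0 or len(tris_b) == 0:
        return False
    # AABB prefilter on all pairs
    lo_a, hi_a = tris_a.min(axis=1), tris_a.max(axis=1)
    lo_b, hi_b = tris_b.min(axis=1), tris_b.max(axis=1)
    overlap = np.all(
        (lo_a[:, None, :] <= hi_b[None, :, :] + _EPS)
        & (lo_b[None, :, :] <= hi_a[:, None, :] + _EPS),
        axis=2,
    )
    ia, ib = np.nonzero(overlap)
    if len(ia) == 0:
        return False
    A, B = tris_a[ia], tris_b[ib]
    for tri_from, tri_to in ((A, B), (B, A)):
        for i, j in ((0, 1), (1, 2), (2, 0)):
            orig = tri_from[:, i]
            vec = tri_from[:, j] - orig
            if _segments_hit_triangles(orig, vec, tri_to).any():
                return True
    # coplanar pairs elude the piercing test; check 2D overlap per pair
    for t1, t2 in zip(A, B):
        if _coplanar_overlap(t1, t2, coplanar_tol):
            return True
    return False
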