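"""Low-level triangle geometry: triangle-triangle intersection segments and
point-to-triangle closest points."""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

__all__ = ["tri_tri_segment", "tri_tri_segments_batch", "point_triangle_closest"]

_EPS = 1e-12


def _cross(u, v):
    """Manual cross product (avoids numpy.cross overhead on small arrays)."""
    return np.stack([u[..., 1] * v[..., 2] - u[..., 2] * v[..., 1],
                     u[..., 2] * v[..., 0] - u[..., 0] * v[..., 2],
                     u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]], axis=-1)


def _plane(tri: np.ndarray):
    n = _cross(tri[1] - tri[0], tri[2] - tri[0])
    return n, -float(n @ tri[0])


def _cross_points(tri: np.ndarray, dv: np.ndarray):
    """Two points where the triangle's edges cross the other plane.

    ``dv`` are the signed distances of the triangle's vertices to that
    plane (not all of the same sign)."""
    pts = []
    for i, j in ((0, 1), (1, 2), (2, 0)):
        di, dj = dv[i], dv[j]
        if (di > 0) == (dj > 0):
            continue
        t = di / (di - dj)
        pts.append(tri[i] + t * (tri[j] - tri[i]))
        if len(pts) == 2:
            break
    return pts


def tri_tri_segment(triA: np.ndarray, triB: np.ndarray,
                    eps: float = _EPS) -> Optional[Tuple[np.ndarray, np.ndarray]]:
    """Intersection segment of two triangles, or None.

    Returns the 3D endpoints of the segment where the triangle interiors
    cross.  Near-coplanar pairs (within ``eps`` of the plane) are resolved
    by a deterministic 1e-9 m jitter of triangle B along its normal.
    """
    nA, dA = _plane(triA)
    nB, dB = _plane(triB)

    dvB = triB @ nA + dA        # signed dist (scaled by |nA|) of B's verts to plane A
    dvA = triA @ nB + dB
    sA = np.linalg.norm(nA)
    sB = np.linalg.norm(nB)
    if sA < eps or sB < eps:
        return None             # degenerate triangle
    tolB = eps * sA
    tolA = eps * sB
    if np.all(np.abs(dvB) < tolB) or np.all(np.abs(dvA) < tolA):
        # coplanar: jitter B along its normal (deterministic perturbation)
        return tri_tri_segment(triA, triB + 1e-9 * nB / sB, eps)
    dvB = np.where(np.abs(dvB) < tolB, tolB, dvB)
    dvA = np.where(np.abs(dvA) < tolA, tolA, dvA)
    if np.all(dvB > 0) or np.all(dvB < 0):
        return None
    if np.all(dvA > 0) or np.all(dvA < 0):
        return None

    ptsA = _cross_points(triA, dvA)   # A's edge crossings of plane B
    ptsB = _cross_points(triB, dvB)   # B's edge crossings of plane A
    if len(ptsA) < 2 or len(ptsB) < 2:
        return None

    D = np.cross(nA, nB)
    axis = int(np.argmax(np.abs(D)))
    sign = 1.0 if D[axis] >= 0 else -1.0
    ta = sorted([(sign * p[axis], p) for p in ptsA], key=lambda x: x[0])
    tb = sorted([(sign * p[axis], p) for p in ptsB], key=lambda x: x[0])
    lo_t, lo_p = max(ta[0], tb[0], key=lambda x: x[0])
    hi_t, hi_p = min(ta[1], tb[1], key=lambda x: x[0])
    if hi_t - lo_t <= 0:
        return None
    return lo_p, hi_p


def _odd_vertex_points(tri, dv):
    """Vectorized edge-plane crossings: for each triangle (row), the vertex
    whose ``dv`` sign differs from the other two, and the two crossing
    points of its incident edges.  tri: (m,3,3), dv: (m,3) with no zeros."""
    pos = dv > 0
    npos = pos.sum(axis=1)
    odd = np.where(npos == 1, np.argmax(pos, axis=1), np.argmax(~pos, axis=1))
    rows = np.arange(len(tri))
    o1 = (odd + 1) % 3
    o2 = (odd + 2) % 3
    Vo = tri[rows, odd]
    d0 = dv[rows, odd]
    out = []
    for oth in (o1, o2):
        Vx = tri[rows, oth]
        dx = dv[rows, oth]
        t = d0 / (d0 - dx)
        out.append(Vo + t[:, None] * (Vx - Vo))
    return out[0], out[1]


def tri_tri_segments_batch(triA: np.ndarray, triB: np.ndarray,
                           eps: float = _EPS):
    """Intersection segments for a batch of triangle pairs.

    Parameters: ``triA``, ``triB`` of shape (m, 3, 3).  Returns
    ``(p0, p1, idx)`` — segment endpoints and the indices of the pairs that
    intersect.  Near-coplanar pairs are delegated to the scalar routine.
    """
    triA = np.asarray(triA, float)
    triB = np.asarray(triB, float)
    m = len(triA)
    if m == 0:
        return (np.empty((0, 3)), np.empty((0, 3)), np.empty(0, np.int64))

    nA = _cross(triA[:, 1] - triA[:, 0], triA[:, 2] - triA[:, 0])
    nB = _cross(triB[:, 1] - triB[:, 0], triB[:, 2] - triB[:, 0])
    sA = np.linalg.norm(nA, axis=1)
    sB = np.linalg.norm(nB, axis=1)
    ok = (sA > eps) & (sB > eps)

    dA = -np.sum(nA * triA[:, 0], axis=1)
    dB = -np.sum(nB * triB[:, 0], axis=1)
    dvB = np.einsum("mij,mj->mi", triB, nA) + dA[:, None]   # B verts vs plane A
    dvA = np.einsum("mij,mj->mi", triA, nB) + dB[:, None]
    tolB = (eps * sA)[:, None]
    tolA = (eps * sB)[:, None]
    coplanar = np.all(np.abs(dvB) < tolB, axis=1) | np.all(np.abs(dvA) < tolA, axis=1)
    dvB = np.where(np.abs(dvB) < tolB, tolB, dvB)
    dvA = np.where(np.abs(dvA) < tolA, tolA, dvA)
    strB = ~(np.all(dvB > 0, axis=1) | np.all(dvB < 0, axis=1))
    strA = ~(np.all(dvA > 0, axis=1) | np.all(dvA < 0, axis=1))

    live = ok & strA & strB & ~coplanar
    idx = np.nonzero(live)[0]
    p0 = np.empty((0, 3))
    p1 = np.empty((0, 3))
    if len(idx):
        a1, a2 = _odd_vertex_points(triA[idx], dvA[idx])
        b1, b2 = _odd_vertex_points(triB[idx], dvB[idx])
        D = _cross(nA[idx], nB[idx])
        axis = np.argmax(np.abs(D), axis=1)
        rows = np.arange(len(idx))
        sgn = np.where(D[rows, axis] >= 0, 1.0, -1.0)
        ta1 = sgn * a1[rows, axis]
        ta2 = sgn * a2[rows, axis]
        tb1 = sgn * b1[rows, axis]
        tb2 = sgn * b2[rows, axis]
        # order each pair
        swapA = ta1 > ta2
        ta_lo = np.where(swapA, ta2, ta1); ta_hi = np.where(swapA, ta1, ta2)
        pa_lo = np.where(swapA[:, None], a2, a1); pa_hi = np.where(swapA[:, None], a1, a2)
        swapB = tb1 > tb2
        tb_lo = np.where(swapB, tb2, tb1); tb_hi = np.where(swapB, tb1, tb2)
        pb_lo = np.where(swapB[:, None], b2, b1); pb_hi = np.where(swapB[:, None], b1, b2)
        lo_t = np.maximum(ta_lo, tb_lo)
        hi_t = np.minimum(ta_hi, tb_hi)
        keep = hi_t - lo_t > 0
        lo_p = np.where((ta_lo >= tb_lo)[:, None], pa_lo, pb_lo)
        hi_p = np.where((ta_hi <= tb_hi)[:, None], pa_hi, pb_hi)
        p0 = lo_p[keep]
        p1 = hi_p[keep]
        idx = idx[keep]

    cop_idx = np.nonzero(ok & coplanar)[0]
    if len(cop_idx):
        extra0, extra1, extraidx = [], [], []
        for k in cop_idx:
            seg = tri_tri_segment(triA[k], triB[k], eps)
            if seg is not None:
                extra0.append(seg[0]); extra1.append(seg[1]); extraidx.append(k)
        if extraidx:
            p0 = np.vstack([p0, np.asarray(extra0)])
            p1 = np.vstack([p1, np.asarray(extra1)])
            idx = np.concatenate([idx, np.asarray(extraidx, np.int64)])
    return p0, p1, idx


def point_triangle_closest(points: np.ndarray, tris: np.ndarray):
    """Closest points on triangles for a set of query points (vectorized).

    Parameters
    ----------
    points : (n, 3)
    tris : (m, 3, 3)

    Returns
    -------
    dist : (n, m) distances
    closest : (n, m, 3) closest points on each triangle
    """
    P = np.asarray(points, float)[:, None, :]           # (n,1,3)
    A = tris[None, :, 0, :]
    B = tris[None, :, 1, :]
    C = tris[None, :, 2, :]
    AB = B - A
    AC = C - A
    BC = C - B
    AP = P - A

    def _edge_point(orig, edge, p):
        ee = np.sum(edge * edge, axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(ee > 0, np.sum((p - orig) * edge, axis=-1) / ee, 0.0)
        return orig + np.clip(t, 0.0, 1.0)[..., None] * edge

    # candidates: three clamped edge projections + in-plane projection (if interior)
    cand = [_edge_point(A, AB, P), _edge_point(A, AC, P), _edge_point(B, BC, P)]
    n = np.cross(AB, AC)
    nn = np.sum(n * n, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dist_plane = np.where(nn > 0, np.sum(AP * n, axis=-1) / np.sqrt(nn), 0.0)
    F = P - dist_plane[..., None] * n / np.where(nn > 0, np.sqrt(nn), 1.0)[..., None]
    # barycentric test for the projection
    v0, v1, v2 = AC, AB, F - A
    d00 = np.sum(v0 * v0, axis=-1)
    d01 = np.sum(v0 * v1, axis=-1)
    d11 = np.sum(v1 * v1, axis=-1)
    d20 = np.sum(v2 * v0, axis=-1)
    d21 = np.sum(v2 * v1, axis=-1)
    denom = d00 * d11 - d01 * d01
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(denom != 0, (d11 * d20 - d01 * d21) / denom, -1.0)
        v = np.where(denom != 0, (d00 * d21 - d01 * d20) / denom, -1.0)
    inside = (u >= 0) & (v >= 0) & (u + v <= 1)
    cand.append(np.where(inside[..., None], F, cand[0]))

    cand = np.stack(cand, axis=0)                       # (4, n, m, 3)
    d = np.linalg.norm(P[None] - cand, axis=-1)         # (4, n, m)
    pick = np.argmin(d, axis=0)
    dist = np.take_along_axis(d, pick[None], axis=0)[0]
    closest = np.take_along_axis(cand, pick[None, ..., None], axis=0)[0]
    return dist, closest
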