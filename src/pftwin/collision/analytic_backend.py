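"""Analytic contact backend: sphere primitive vs fitted polynomial surface.

The patellar button is a sphere; the femoral implant is a
:class:`~pftwin.surface_fit.PolynomialSurface` height field in the femur
body frame.  Contact exists when the distance from the sphere center to
the surface is smaller than the sphere radius; the closed-form geometry of
the foot point supplies the contact point, normal and indentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from ..surface_fit import PolynomialSurface
from .contact import ContactPatch, EpisodeTracker

__all__ = ["SpherePrimitive", "closest_point", "sphere_surface_contact",
           "AnalyticContactBackend"]

log = logging.getLogger(__name__)

Pose = Tuple[np.ndarray, np.ndarray]


@dataclass
class SpherePrimitive:
    """Spherical contact primitive of the patellar button."""

    center: np.ndarray = None      # patella body frame, m
    radius: float = 0.015

    def __post_init__(self):
        self.center = (np.zeros(3) if self.center is None
                       else np.asarray(self.center, float))
        if self.radius <= 0:
            raise ValueError("sphere radius must be > 0")


@dataclass
class ClosestPointResult:
    point: np.ndarray              # (x, y, f(x, y)) in surface frame
    distance: float                # unsigned
    signed_distance: float         # positive on the +z side of the surface
    normal: np.ndarray             # unit upward surface normal at the foot point
    clamped: bool                  # foot point pinned to the domain boundary
    residual: float                # stationarity residual of the foot point


def _newton_foot(surface: PolynomialSurface, c: np.ndarray, x0: float, y0: float,
                 tol: float = 1e-12, maxit: int = 60):
    """Newton iteration on the foot-point stationarity system.

    Stationarity of 0.5*||(x, y, f) - c||^2:
        F1 = (x - cx) + f_x (f - cz) = 0
        F2 = (y - cy) + f_y (f - cz) = 0
    """
    x, y = float(x0), float(y0)
    cx, cy, cz = float(c[0]), float(c[1]), float(c[2])
    cap = 0.1 * max(surface.fit_domain[0][1] - surface.fit_domain[0][0],
                    surface.fit_domain[1][1] - surface.fit_domain[1][0])
    for _ in range(maxit):
        z, fx, fy, fxx, fxy, fyy = surface.eval_all(x, y)
        w = z - cz
        F1 = (x - cx) + fx * w
        F2 = (y - cy) + fy * w
        res = max(abs(F1), abs(F2))
        if res < tol:
            return x, y, res, z, fx, fy
        J11 = 1.0 + fxx * w + fx * fx
        J12 = fxy * w + fx * fy
        J22 = 1.0 + fyy * w + fy * fy
        det = J11 * J22 - J12 * J12
        if abs(det) < 1e-300:
            break
        dx = (-F1 * J22 + F2 * J12) / det
        dy = (-F2 * J11 + F1 * J12) / det
        step = max(abs(dx), abs(dy))
        if step > cap:
            dx *= cap / step
            dy *= cap / step
        x += dx
        y += dy
    z, fx, fy, _, _, _ = surface.eval_all(x, y)
    w = z - cz
    return (x, y, max(abs((x - cx) + fx * w), abs((y - cy) + fy * w)), z, fx, fy)


def closest_point(surface: PolynomialSurface, c, inflate: float = 0.1,
                  n_boundary: int = 64, seed_hint=None) -> ClosestPointResult:
    """Globally closest point on ``z = f(x, y)`` to a center ``c``.

    Multi-start Newton on the stationarity system, seeded from the vertical
    projection of ``c`` plus a 3x3 pattern around it (guards against the
    multiple local minima either side of the groove ridges).  Converged
    interior stationary points are compared and the global minimum kept;
    if none converges inside the (inflated) domain the result is clamped
    to the domain boundary and flagged.
    """
    c = np.asarray(c, float)
    (x0d, x1d), (y0d, y1d) = surface.fit_domain
    hx, hy = 0.5 * (x1d - x0d), 0.5 * (y1d - y0d)
    ix0, ix1 = x0d - inflate * (x1d - x0d), x1d + inflate * (x1d - x0d)
    iy0, iy1 = y0d - inflate * (y1d - y0d), y1d + inflate * (y1d - y0d)
    sx = min(max(float(c[0]), x0d), x1d)
    sy = min(max(float(c[1]), y0d), y1d)

    # warm path: the previous foot point plus the vertical projection.  The
    # global 5x5 seeding is only needed on cold starts or when both fail —
    # the two warm seeds already bracket the ridge bifurcation in practice.
    warm = [(sx, sy)]
    if seed_hint is not None:
        warm.insert(0, (float(seed_hint[0]), float(seed_hint[1])))
    gx = np.linspace(x0d + 0.08 * hx, x1d - 0.08 * hx, 5)
    gy = np.linspace(y0d + 0.08 * hy, y1d - 0.08 * hy, 5)
    pattern = [(float(a), float(b)) for a in gx for b in gy]

    best = None

    def try_seeds(seeds):
        nonlocal best
        for (xs, ys) in seeds:
            x, y, res, z, fx, fy = _newton_foot(surface, c, xs, ys)
            if res > 1e-10:
                continue
            if not (ix0 <= x <= ix1 and iy0 <= y <= iy1):
                continue
            d = ((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) ** 0.5
            if best is None or d < best[3]:
                best = (x, y, z, d, res, False, fx, fy)

    try_seeds(warm)
    if best is None or seed_hint is None:
        try_seeds(pattern)

    if best is None:
        # boundary-clamped fallback: sample the rectangle boundary densely
        ts = np.linspace(0.0, 1.0, n_boundary)
        bx = np.concatenate([x0d + ts * (x1d - x0d), np.full_like(ts, x1d),
                             x1d - ts * (x1d - x0d), np.full_like(ts, x0d)])
        by = np.concatenate([np.full_like(ts, y0d), y0d + ts * (y1d - y0d),
                             np.full_like(ts, y1d), y1d - ts * (y1d - y0d)])
        bz = surface.evaluate(bx, by)
        d2 = (bx - c[0]) ** 2 + (by - c[1]) ** 2 + (bz - c[2]) ** 2
        k = int(np.argmin(d2))
        gx, gy = (float(v) for v in surface.gradient(bx[k], by[k]))
        best = (float(bx[k]), float(by[k]), float(bz[k]),
                float(np.sqrt(d2[k])), np.inf, True, gx, gy)

    x, y, z, d, res, clamped, fx, fy = best
    nn = (fx * fx + fy * fy + 1.0) ** 0.5
    n = np.array([-fx / nn, -fy / nn, 1.0 / nn])
    signed = float(n @ (c - np.array([x, y, z])))
    return ClosestPointResult(point=np.array([x, y, z]), distance=d,
                              signed_distance=signed, normal=n,
                              clamped=clamped, residual=res)


def sphere_surface_contact(sphere: SpherePrimitive, pose_patella: Pose,
                           surface: PolynomialSurface, pose_femur: Pose,
                           vel_femur=None, vel_patella=None,
                           domain_inflate: float = 0.0, seed_hint=None,
                           ) -> Optional[ContactPatch]:
    """Contact patch (world frame) between the posed sphere and surface.

    Contact iff the center-to-surface distance is below the sphere radius.
    A center on the far (-z) side of the surface is treated as deep
    penetration ``delta = radius + |signed distance|`` with a warning.  A
    foot point outside the fit domain ends the contact (the surface is not
    extrapolated); the caller sees ``None`` and the episode closes — a
    candidate dislocation marker.
    """
    Rf, rf = (np.asarray(a, float) for a in pose_femur)
    Rp, rp = (np.asarray(a, float) for a in pose_patella)
    c_world = Rp @ sphere.center + rp
    c_local = Rf.T @ (c_world - rf)

    res = closest_point(surface, c_local, inflate=max(domain_inflate, 0.05),
                        seed_hint=seed_hint)
    if res.clamped or not surface.in_domain(res.point[0], res.point[1],
                                            inflate=domain_inflate):
        return None
    s = res.signed_distance
    if s >= sphere.radius:
        return None
    deep = s <= 0.0
    if deep:
        log.debug("sphere center below the femoral surface "
                  "(signed distance %.3g m): deep penetration", s)
        delta = sphere.radius + abs(s)
    else:
        delta = sphere.radius - s

    n_local = res.normal if not deep else -res.normal
    point = Rf @ res.point + rf
    normal = Rf @ n_local

    delta_dot = 0.0
    if vel_femur is not None or vel_patella is not None:
        vf = np.zeros(3) if vel_femur is None else (
            np.asarray(vel_femur[0], float)
            + np.cross(np.asarray(vel_femur[1], float), point - rf))
        vp = np.zeros(3) if vel_patella is None else (
            np.asarray(vel_patella[0], float)
            + np.cross(np.asarray(vel_patella[1], float), c_world - rp))
        delta_dot = float(normal @ (vf - vp))

    return ContactPatch(point=point, normal=normal, delta=float(delta),
                        delta_dot=delta_dot, deep=deep)


class AnalyticContactBackend:
    """Stateful sphere-vs-polynomial-surface detector with episode latching.

    Mirrors :class:`~pftwin.collision.mesh_backend.MeshContactBackend` so the
    integrator can treat both backends interchangeably.
    """

    default_timestep = 1e-3

    def __init__(self, surface: PolynomialSurface, sphere: SpherePrimitive,
                 match_radius: float = 0.01):
        self.surface = surface
        self.sphere = sphere
        self.episodes = EpisodeTracker(match_radius=match_radius)
        self.left_domain_events: List[dict] = []
        self._was_in_contact = False

    def reset(self) -> None:
        self.episodes.reset()
        self.left_domain_events.clear()
        self._was_in_contact = False
        self._hint = None

    def contacts(self, pose_femur: Pose, pose_patella: Pose,
                 vel_femur=None, vel_patella=None, t: float = 0.0,
                 track_episodes: bool = True) -> List[ContactPatch]:
        patch = sphere_surface_contact(self.sphere, pose_patella,
                                       self.surface, pose_femur,
                                       vel_femur, vel_patella,
                                       seed_hint=getattr(self, "_hint", None))
        patches = [patch] if patch is not None else []
        if patch is not None:
            Rf, rf = (np.asarray(a, float) for a in pose_femur)
            p_local = Rf.T @ (patch.point - rf)
            self._hint = (float(p_local[0]), float(p_local[1]))
        else:
            self._hint = None
        deep = patch is not None and patch.deep
        if deep and not getattr(self, "_was_deep", False):
            log.warning("t=%.4f: sphere center passed below the femoral "
                        "surface (deep penetration)", t)
        self._was_deep = deep
        if patch is None and self._was_in_contact:
            # distinguish a clean lift-off from sliding out of the domain
            Rf, rf = (np.asarray(a, float) for a in pose_femur)
            Rp, rp = (np.asarray(a, float) for a in pose_patella)
            c_local = Rf.T @ (Rp @ self.sphere.center + rp - rf)
            if not surface_contains(self.surface, c_local):
                self.left_domain_events.append({"t": t, "center": c_local.copy()})
        self._was_in_contact = patch is not None
        if track_episodes:
            self.episodes.update(patches, t)
        return patches


def surface_contains(surface: PolynomialSurface, c_local) -> bool:
    return bool(surface.in_domain(c_local[0], c_local[1]))
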