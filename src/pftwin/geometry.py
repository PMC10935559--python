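"""Synthetic test-bench geometry: trochlear groove surface and patellar button.

The physical bench uses commercial implants whose CAD is not distributed, so
the femoral contact surface is generated here as a smooth analytic height
field ``z = f(x, y)`` in the femoral body frame:

* ``x`` — sagittal direction (positive toward the hip / superior); the
  patella glides along ``x`` as the knee flexes and extends,
* ``y`` — medial-lateral direction (medial positive),
* ``z`` — height off the groove floor (positive toward the patella).

The sagittal profile is a parabolic approximation of a circular condylar
arc (convex, so tendon tension presses the patella onto the surface) and
the medial-lateral cross-section is a quintic double-ridge well.  The full
height field is a bivariate polynomial of total degree five, so an
order-5 polynomial fit of the vertex cloud is exact by construction.

The patellar button is an icosphere (regular triangulation; no pole vertex
touching many triangles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import trimesh

from .errors import DomainError, MeshError, ToleranceError

__all__ = [
    "TriMesh",
    "MeshQuality",
    "GrooveParams",
    "HeightFieldReference",
    "SphereReference",
    "make_trochlear_surface",
    "make_icosphere",
    "mesh_quality",
    "save_mesh",
    "load_mesh",
]

_MAX_GRID = 1400          # per-axis vertex cap for the groove surface
_MAX_SUBDIVISIONS = 7     # icosphere memory guard (20 * 4**7 = 327k faces)


@dataclass
class TriMesh:
    """Posed triangle surface mesh (SI units, meters).

    ``faces`` are CCW-wound index triples; ``outward`` records whether the
    face normals point out of the solid / toward the contacting body.
    """

    vertices: np.ndarray
    faces: np.ndarray
    outward: bool = True
    _face_normals: Optional[np.ndarray] = field(default=None, repr=False)
    _triangles: Optional[np.ndarray] = field(default=None, repr=False)
    _areas: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be (m, 3)")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise MeshError("face index out of range")
        if self.faces.size and self.faces.min() < 0:
            raise MeshError("negative face index")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates (cached)."""
        if self._triangles is None:
            self._triangles = self.vertices[self.faces]
        return self._triangles

    @property
    def face_normals(self) -> np.ndarray:
        if self._face_normals is None:
            tri = self.triangles
            n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            norms = np.linalg.norm(n, axis=1)
            if np.any(norms <= 0):
                raise MeshError("degenerate face (zero area)")
            self._face_normals = n / norms[:, None]
        return self._face_normals

    @property
    def face_areas(self) -> np.ndarray:
        if self._areas is None:
            tri = self.triangles
            n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            self._areas = 0.5 * np.linalg.norm(n, axis=1)
        return self._areas

    @property
    def face_centroids(self) -> np.ndarray:
        return self.triangles.mean(axis=1)

    def validate(self) -> None:
        """Raise :class:`MeshError` if any invariant is violated."""
        areas = self.face_areas
        if np.any(areas <= 0.0):
            raise MeshError(f"{int(np.sum(areas <= 0))} degenerate faces")
        norms = np.linalg.norm(self.face_normals, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise MeshError("face normals not unit length")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriMesh":
        """Rigidly transform: ``v -> R v + t``."""
        v = self.vertices @ np.asarray(rotation, float).T + np.asarray(translation, float)
        return TriMesh(v, self.faces.copy(), outward=self.outward)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


@dataclass
class MeshQuality:
    """Deviation of a mesh from its analytic reference surface."""

    max_chordal_deviation: float   # m
    max_normal_deviation: float    # degrees

    def __post_init__(self):
        if self.max_chordal_deviation < 0 or self.max_normal_deviation < 0:
            raise ValueError("mesh quality measures must be >= 0")

    def within(self, target: "MeshQuality") -> bool:
        return (self.max_chordal_deviation <= target.max_chordal_deviation
                and self.max_normal_deviation <= target.max_normal_deviation)


# --------------------------------------------------------------------------
# Trochlear groove height field
# --------------------------------------------------------------------------

@dataclass
class GrooveParams:
    """Parameters of the synthetic trochlear groove height field.

    The medial-lateral cross-section (``s = y / groove_halfwidth``) is

        g(s) = depth * (a s^2 + b s^3 + c s^4 + e s^5)

    with coefficients chosen so both ridges are stationary points at
    ``s = +-1`` with heights ``medial_ridge_gain * depth`` (medial, s=+1)
    and ``lateral_ridge_gain * depth`` (lateral, s=-1).  Beyond the ridges
    the wall falls off, which is what permits lateral dislocation.  The
    sagittal profile is ``-x^2 / (2 sagittal_radius)`` (convex condylar arc).
    """

    sagittal_radius: float = 0.10       # m
    groove_halfwidth: float = 0.024     # m, ridge line at |y| = halfwidth
    groove_depth: float = 0.0045        # m, ridge height scale
    lateral_ridge_gain: float = 1.15    # lateral >= medial (spec of the bench)
    medial_ridge_gain: float = 1.0
    arc_extent: float = 0.8             # rad, sagittal arc spanned by the surface
    overhang: float = 1.3               # domain extends to overhang * halfwidth in |y|

    def __post_init__(self):
        if min(self.sagittal_radius, self.groove_halfwidth, self.groove_depth) <= 0:
            raise ValueError("all groove lengths must be > 0")
        if not (0.0 < self.arc_extent <= np.pi):
            raise ValueError("arc_extent must lie in (0, pi]")
        if self.lateral_ridge_gain < self.medial_ridge_gain:
            raise ValueError("lateral_ridge_gain must be >= medial_ridge_gain")

    # cross-section coefficients (divided by depth)
    @property
    def cross_coeffs(self) -> np.ndarray:
        gm, gl = self.medial_ridge_gain, self.lateral_ridge_gain
        a = gm + gl
        c = -(gm + gl) / 2.0
        b = 1.25 * (gm - gl)
        e = -0.75 * (gm - gl)
        return np.array([a, b, c, e])

    @property
    def x_halfwidth(self) -> float:
        """Sagittal half-extent of the surface domain (m)."""
        return self.sagittal_radius * np.sin(self.arc_extent / 2.0)

    @property
    def y_halfwidth(self) -> float:
        return self.overhang * self.groove_halfwidth

    @property
    def domain(self) -> tuple:
        """((xmin, xmax), (ymin, ymax)) of the height-field domain."""
        return ((-self.x_halfwidth, self.x_halfwidth),
                (-self.y_halfwidth, self.y_halfwidth))

    def height(self, x, y):
        """Analytic ground-truth height field z = f(x, y)."""
        x = np.asarray(x, float)
        s = np.asarray(y, float) / self.groove_halfwidth
        a, b, c, e = self.cross_coeffs
        g = self.groove_depth * (s * s * (a + b * s + c * s * s + e * s ** 3))
        return -x * x / (2.0 * self.sagittal_radius) + g

    def gradient(self, x, y):
        """(df/dx, df/dy) of the height field."""
        x = np.asarray(x, float)
        s = np.asarray(y, float) / self.groove_halfwidth
        a, b, c, e = self.cross_coeffs
        dg_ds = self.groove_depth * (2 * a * s + 3 * b * s ** 2
                                     + 4 * c * s ** 3 + 5 * e * s ** 4)
        return (-x / self.sagittal_radius, dg_ds / self.groove_halfwidth)

    @property
    def analytic_form(self) -> Callable:
        return self.height

    @property
    def lateral_ridge_height(self) -> float:
        return float(self.height(0.0, -self.groove_halfwidth))

    @property
    def medial_ridge_height(self) -> float:
        return float(self.height(0.0, self.groove_halfwidth))

    def polynomial_coefficients(self) -> dict:
        """Exact monomial coefficients c[(i, j)] of x^i y^j (degree <= 5)."""
        a, b, c, e = self.cross_coeffs
        d, w = self.groove_depth, self.groove_halfwidth
        return {
            (2, 0): -1.0 / (2.0 * self.sagittal_radius),
            (0, 2): d * a / w ** 2,
            (0, 3): d * b / w ** 3,
            (0, 4): d * c / w ** 4,
            (0, 5): d * e / w ** 5,
        }


# --------------------------------------------------------------------------
# Analytic references for mesh-quality measurement
# --------------------------------------------------------------------------

class HeightFieldReference:
    """Reference surface z = f(x, y) with an optional rectangular domain."""

    def __init__(self, height: Callable, gradient: Optional[Callable] = None,
                 domain: Optional[tuple] = None, h_fd: float = 1e-6):
        self._height = height
        self._gradient = gradient
        self.domain = domain
        self._h = h_fd

    def contains(self, points: np.ndarray) -> np.ndarray:
        if self.domain is None:
            return np.ones(len(points), bool)
        (x0, x1), (y0, y1) = self.domain
        x, y = points[:, 0], points[:, 1]
        tol = 1e-9
        return ((x >= x0 - tol) & (x <= x1 + tol)
                & (y >= y0 - tol) & (y <= y1 + tol))

    def _grad(self, x, y):
        if self._gradient is not None:
            return self._gradient(x, y)
        h = self._h
        fx = (self._height(x + h, y) - self._height(x - h, y)) / (2 * h)
        fy = (self._height(x, y + h) - self._height(x, y - h)) / (2 * h)
        return fx, fy

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Perpendicular distance of points to the surface (first order)."""
        x, y, z = points[:, 0], points[:, 1], points[:, 2]
        dz = z - self._height(x, y)
        fx, fy = self._grad(x, y)
        return np.abs(dz) / np.sqrt(1.0 + fx * fx + fy * fy)

    def normal(self, points: np.ndarray) -> np.ndarray:
        """Unit upward surface normal under each point."""
        x, y = points[:, 0], points[:, 1]
        fx, fy = self._grad(x, y)
        n = np.stack([-np.broadcast_to(fx, x.shape),
                      -np.broadcast_to(fy, x.shape),
                      np.ones_like(x)], axis=-1)
        return n / np.linalg.norm(n, axis=-1, keepdims=True)

    @classmethod
    def from_groove(cls, params: GrooveParams) -> "HeightFieldReference":
        return cls(params.height, params.gradient, params.domain)


class SphereReference:
    """Reference sphere for icosphere quality measurement."""

    def __init__(self, radius: float, center=(0.0, 0.0, 0.0)):
        self.radius = float(radius)
        self.center = np.asarray(center, float)

    def contains(self, points: np.ndarray) -> np.ndarray:
        return np.ones(len(points), bool)

    def distance(self, points: np.ndarray) -> np.ndarray:
        return np.abs(np.linalg.norm(points - self.center, axis=1) - self.radius)

    def normal(self, points: np.ndarray) -> np.ndarray:
        d = points - self.center
        return d / np.linalg.norm(d, axis=1, keepdims=True)


def mesh_quality(mesh: TriMesh, reference) -> MeshQuality:
    """Measure max chordal deviation (m) and normal deviation (deg) of a mesh
    against its analytic reference, evaluated at face centroids.

    ``reference`` must expose ``contains``, ``distance`` and ``normal``
    (see :class:`HeightFieldReference`, :class:`SphereReference`); a plain
    ``f(x, y)`` callable is wrapped as an unbounded height field.
    """
    if callable(reference):
        reference = HeightFieldReference(reference)
    cent = mesh.face_centroids
    inside = reference.contains(cent)
    if not np.all(inside):
        bad = np.nonzero(~inside)[0]
        raise DomainError(
            f"{len(bad)} face centroids outside reference domain: {bad[:10].tolist()}")
    dev = reference.distance(cent)
    ref_n = reference.normal(cent)
    cosang = np.clip(np.abs(np.sum(mesh.face_normals * ref_n, axis=1)), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    return MeshQuality(float(dev.max()), float(ang.max()))


# --------------------------------------------------------------------------
# Generators
# --------------------------------------------------------------------------

def _symmetric_grid(half: float, n_half: int) -> np.ndarray:
    """Grid on [-half, half] that is exactly mirror-symmetric in FP."""
    pos = np.linspace(0.0, half, n_half + 1)
    return np.concatenate([-pos[:0:-1], pos])


def _adaptive_ys(params: GrooveParams, ny: int, weight) -> np.ndarray:
    """y grid lines equidistributed in curvature-weighted arc measure.

    ``weight`` is an optional extra density multiplier (used to refine,
    e.g., the dislocation-critical lateral ridge).  The grid is exactly
    antisymmetrized so mirror-symmetric grooves give mirror-symmetric
    meshes.
    """
    yh = params.y_halfwidth
    yy = np.linspace(-yh, yh, 4096)
    h = 1e-6
    kappa = np.abs(params.gradient(0.0, yy + h)[1]
                   - params.gradient(0.0, yy - h)[1]) / (2 * h)
    dens = np.sqrt(kappa + 1.0 / yh ** 2)   # floor keeps flat parts meshed
    if weight is not None:
        dens = dens * np.maximum(np.asarray(weight(yy), float), 1e-12)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(yy))])
    cdf /= cdf[-1]
    ys = np.interp(np.linspace(0.0, 1.0, ny + 1), cdf, yy)
    ys[0], ys[-1] = -yh, yh
    if np.allclose(dens, dens[::-1], rtol=1e-12, atol=0.0):
        # symmetric density: enforce exact mirror antisymmetry of the grid
        ys = 0.5 * (ys - ys[::-1])
        ys[0], ys[-1] = -yh, yh
    return ys


def _grid_mesh(params: GrooveParams, nx: int, ny: int,
               density: Optional[Callable] = None) -> TriMesh:
    """Grid mesh on the height field: uniform in x, curvature-adaptive in y."""
    xh = params.x_halfwidth
    xs = _symmetric_grid(xh, nx // 2)
    ys = _adaptive_ys(params, ny, density)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = params.height(X, Y)
    verts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    nrow, ncol = X.shape
    i, j = np.meshgrid(np.arange(nrow - 1), np.arange(ncol - 1), indexing="ij")
    v00 = (i * ncol + j).ravel()
    v10 = ((i + 1) * ncol + j).ravel()
    v01 = (i * ncol + j + 1).ravel()
    v11 = ((i + 1) * ncol + j + 1).ravel()
    # CCW in the xy-plane so normals point +z (toward the patella)
    faces = np.concatenate([np.stack([v00, v10, v11], axis=1),
                            np.stack([v00, v11, v01], axis=1)])
    return TriMesh(verts, faces, outward=True)


def make_trochlear_surface(params: GrooveParams, resolution: MeshQuality,
                           density: Optional[Callable] = None) -> TriMesh:
    """Triangulate the groove height field to a requested quality target.

    Every emitted vertex lies exactly on ``params.height``.  The grid is
    sized from the field's curvature bound and then verified with
    :func:`mesh_quality`; refinement doubles the grid until the target is
    met or the grid cap is reached (:class:`ToleranceError`).

    ``density`` is an optional weight function of ``y`` used to concentrate
    grid lines (e.g. near the dislocation-critical lateral ridge).
    """
    if resolution.max_chordal_deviation <= 0 or resolution.max_normal_deviation <= 0:
        raise ValueError("resolution targets must be positive")
    ref = HeightFieldReference.from_groove(params)

    # size the grid from the curvature field (0.6 safety factor: the split
    # quads' diagonal edges are sqrt(2) longer than the grid spacing)
    yy = np.linspace(-params.y_halfwidth, params.y_halfwidth, 2048)
    h = 1e-6
    gyy = np.abs(params.gradient(0.0, yy + h)[1]
                 - params.gradient(0.0, yy - h)[1]) / (2 * h)
    kx = 1.0 / params.sagittal_radius
    tol_c = resolution.max_chordal_deviation
    tol_a = np.radians(resolution.max_normal_deviation)

    def edge_for(kappa):
        kappa = np.maximum(kappa, 1e-9)
        return 0.6 * np.minimum(np.sqrt(8.0 * tol_c / kappa), 2.0 * tol_a / kappa)

    nx = max(4, int(np.ceil(2 * params.x_halfwidth / float(edge_for(kx)))))
    ny = max(4, int(np.ceil(np.trapezoid(1.0 / edge_for(gyy), yy))))
    nx += nx % 2
    ny += ny % 2
    while True:
        if nx > _MAX_GRID or ny > _MAX_GRID:
            raise ToleranceError(
                f"cannot reach tolerance {tol_c} m / "
                f"{resolution.max_normal_deviation} deg within grid cap {_MAX_GRID}")
        mesh = _grid_mesh(params, nx, ny, density)
        q = mesh_quality(mesh, ref)
        if q.within(resolution):
            return mesh
        nx *= 2
        ny *= 2


def make_icosphere(radius: float, subdivisions: int) -> TriMesh:
    """Icosphere patellar button: 20 * 4**subdivisions faces, all vertices at
    ``radius`` from the origin."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    if subdivisions > _MAX_SUBDIVISIONS:
        raise MeshError(f"subdivisions > {_MAX_SUBDIVISIONS} (memory guard)")
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    v = np.asarray(tm.vertices, float)
    # re-project exactly onto the sphere (guard against FP drift in the library)
    v = v * (radius / np.linalg.norm(v, axis=1))[:, None]
    return TriMesh(v, np.asarray(tm.faces, np.int64), outward=True)


# --------------------------------------------------------------------------
# Mesh IO (OBJ / STL via trimesh; vertex order preserved for OBJ)
# --------------------------------------------------------------------------

def save_mesh(mesh: TriMesh, path) -> None:
    """Write OBJ / STL (format from extension; ``.stl`` binary, ``.stl_ascii``
    not needed — pass ``file_type='stl_ascii'`` via trimesh if required)."""
    mesh.to_trimesh().export(str(path))


def load_mesh(path) -> TriMesh:
    """Read OBJ / STL.  OBJ round-trips vertex order exactly; STL stores a
    triangle soup, so vertices are welded back in first-use order."""
    tm = trimesh.load_mesh(str(path), process=False)
    v = np.asarray(tm.vertices, float)
    f = np.asarray(tm.faces, np.int64)
    if str(path).lower().endswith((".stl",)):
        v, f = _weld(v, f)
    return TriMesh(v, f)


def _weld(vertices: np.ndarray, faces: np.ndarray, tol: float = 0.0):
    """Merge duplicate vertices (exact match), keeping first-use order."""
    key = {}
    remap = np.empty(len(vertices), np.int64)
    out = []
    for i, vv in enumerate(vertices):
        k = (vv[0], vv[1], vv[2])
        if k not in key:
            key[k] = len(out)
            out.append(vv)
        remap[i] = key[k]
    return np.asarray(out), remap[faces]
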