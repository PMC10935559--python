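"""Bivariate polynomial approximation of the femoral contact surface.

The analytic collision backend replaces the triangulated implant surface by
a height field ``z = sum c_ij x^i y^j`` (total degree ``i + j <= n``) fitted
to the mesh vertex cloud by weighted least squares.  Orders 2, 4 and 5 are
the resolutions compared throughout the package (labelled P2/P4/P5).

Numerics: the monomial basis is centered and scaled to the fit-domain
midpoint/half-width before solving (conditioning at order 5), and the
least-squares problem is solved by orthogonal decomposition
(``numpy.linalg.lstsq``, SVD based, rank revealing) — never by normal
equations.  Coefficients are mapped back to the original frame so
``evaluate`` works on raw coordinates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import FitError

__all__ = ["PolynomialSurface", "fit_polynomial", "n_coefficients"]


def n_coefficients(order: int) -> int:
    return (order + 1) * (order + 2) // 2


def _exponents(order: int) -> np.ndarray:
    """(n_terms, 2) exponent pairs (i, j) with i + j <= order, graded order."""
    return np.array([(i, j)
                     for total in range(order + 1)
                     for i in range(total + 1)
                     for j in [total - i]], dtype=np.int64)


class ExtrapolationWarning(UserWarning):
    """Surface evaluated outside its fit domain."""


@dataclass
class PolynomialSurface:
    """Bivariate polynomial height field with fit diagnostics.

    ``coefficients[k]`` multiplies ``x**exponents[k,0] * y**exponents[k,1]``
    in the *original* (uncentered) frame.  ``r_squared`` is clipped to
    [0, 1]; the unclipped value is kept in ``r_squared_raw``.
    """

    order: int
    coefficients: np.ndarray
    fit_domain: tuple              # ((xmin, xmax), (ymin, ymax))
    r_squared: float = 1.0
    r_squared_raw: float = 1.0
    rmse_fit: float = 0.0
    exponents: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.exponents is None:
            self.exponents = _exponents(self.order)
        self.coefficients = np.asarray(self.coefficients, float)
        if len(self.coefficients) != n_coefficients(self.order):
            raise FitError(
                f"order {self.order} needs {n_coefficients(self.order)} "
                f"coefficients, got {len(self.coefficients)}")
        (x0, x1), (y0, y1) = self.fit_domain
        if not (x1 > x0 and y1 > y0):
            raise FitError("fit_domain must be a non-empty rectangle")

    # ---- evaluation -------------------------------------------------------

    def in_domain(self, x, y, inflate: float = 0.0) -> np.ndarray:
        (x0, x1), (y0, y1) = self.fit_domain
        dx = inflate * (x1 - x0)
        dy = inflate * (y1 - y0)
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return ((x >= x0 - dx) & (x <= x1 + dx)
                & (y >= y0 - dy) & (y <= y1 + dy))

    def evaluate(self, x, y, warn_extrapolation: bool = False):
        """Height ``z`` at (x, y).  Vectorized."""
        if warn_extrapolation and not np.all(self.in_domain(x, y)):
            warnings.warn("evaluation outside fit domain", ExtrapolationWarning,
                          stacklevel=2)
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        i = self.exponents[:, 0]
        j = self.exponents[:, 1]
        terms = (x[..., None] ** i) * (y[..., None] ** j)
        return terms @ self.coefficients

    def gradient(self, x, y):
        """(dz/dx, dz/dy) at (x, y)."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        i = self.exponents[:, 0].astype(float)
        j = self.exponents[:, 1].astype(float)
        xi = x[..., None] ** np.maximum(self.exponents[:, 0] - 1, 0)
        yj = y[..., None] ** np.maximum(self.exponents[:, 1] - 1, 0)
        xpow = x[..., None] ** self.exponents[:, 0]
        ypow = y[..., None] ** self.exponents[:, 1]
        fx = (i * xi * ypow) @ self.coefficients
        fy = (j * xpow * yj) @ self.coefficients
        return fx, fy

    def hessian(self, x, y):
        """Second derivatives (fxx, fxy, fyy)."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        i = self.exponents[:, 0].astype(float)
        j = self.exponents[:, 1].astype(float)
        xim2 = x[..., None] ** np.maximum(self.exponents[:, 0] - 2, 0)
        yjm2 = y[..., None] ** np.maximum(self.exponents[:, 1] - 2, 0)
        xim1 = x[..., None] ** np.maximum(self.exponents[:, 0] - 1, 0)
        yjm1 = y[..., None] ** np.maximum(self.exponents[:, 1] - 1, 0)
        xpow = x[..., None] ** self.exponents[:, 0]
        ypow = y[..., None] ** self.exponents[:, 1]
        fxx = (i * (i - 1) * xim2 * ypow) @ self.coefficients
        fxy = (i * j * xim1 * yjm1) @ self.coefficients
        fyy = (j * (j - 1) * xpow * yjm2) @ self.coefficients
        return fxx, fxy, fyy

    def normal(self, x, y):
        """Unit upward surface normal ~ (-df/dx, -df/dy, 1)."""
        fx, fy = self.gradient(x, y)
        fx = np.asarray(fx, float)
        n = np.stack([-fx, -np.asarray(fy, float), np.ones_like(fx)], axis=-1)
        return n / np.linalg.norm(n, axis=-1, keepdims=True)

    def evaluate_with_normal(self, x, y, warn_extrapolation: bool = True):
        """(z, unit normal) — the backend-facing evaluation contract."""
        z = self.evaluate(x, y, warn_extrapolation=warn_extrapolation)
        return z, self.normal(x, y)

    def _eval_cache(self):
        if getattr(self, "_ec", None) is None:
            i = self.exponents[:, 0]
            j = self.exponents[:, 1]
            fi = i.astype(float)
            fj = j.astype(float)
            c = self.coefficients
            self._ec = {
                "i": i, "j": j,
                "i1": np.maximum(i - 1, 0), "j1": np.maximum(j - 1, 0),
                "i2": np.maximum(i - 2, 0), "j2": np.maximum(j - 2, 0),
                "c": c, "cfi": c * fi, "cfj": c * fj,
                "cfii": c * fi * (fi - 1), "cfij": c * fi * fj,
                "cfjj": c * fj * (fj - 1),
                "nmax": int(self.exponents.max()),
            }
        return self._ec

    def eval_all(self, x: float, y: float):
        """Scalar fused evaluation: (z, fx, fy, fxx, fxy, fyy).

        One pass over the monomial terms; used by the closest-point Newton
        iteration where per-call overhead dominates.
        """
        ec = self._eval_cache()
        nmax = ec["nmax"]
        xp = np.empty(nmax + 1)
        yp = np.empty(nmax + 1)
        xp[0] = yp[0] = 1.0
        for k in range(1, nmax + 1):
            xp[k] = xp[k - 1] * x
            yp[k] = yp[k - 1] * y
        xi = xp[ec["i"]]
        yj = yp[ec["j"]]
        xi1 = xp[ec["i1"]]
        yj1 = yp[ec["j1"]]
        z = float(ec["c"] @ (xi * yj))
        fx = float(ec["cfi"] @ (xi1 * yj))
        fy = float(ec["cfj"] @ (xi * yj1))
        fxx = float(ec["cfii"] @ (xp[ec["i2"]] * yj))
        fxy = float(ec["cfij"] @ (xi1 * yj1))
        fyy = float(ec["cfjj"] @ (xi * yp[ec["j2"]]))
        return z, fx, fy, fxx, fxy, fyy

    # ---- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "order": int(self.order),
            "coefficients": self.coefficients.tolist(),
            "exponents": self.exponents.tolist(),
            "fit_domain": [list(self.fit_domain[0]), list(self.fit_domain[1])],
            "r_squared": float(self.r_squared),
            "r_squared_raw": float(self.r_squared_raw),
            "rmse_fit": float(self.rmse_fit),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolynomialSurface":
        return cls(order=int(d["order"]),
                   coefficients=np.asarray(d["coefficients"], float),
                   fit_domain=(tuple(d["fit_domain"][0]), tuple(d["fit_domain"][1])),
                   r_squared=float(d["r_squared"]),
                   r_squared_raw=float(d.get("r_squared_raw", d["r_squared"])),
                   rmse_fit=float(d["rmse_fit"]),
                   exponents=np.asarray(d["exponents"], np.int64))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "PolynomialSurface":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_polynomial(points: np.ndarray, order: int,
                   weights: Optional[np.ndarray] = None) -> PolynomialSurface:
    """Weighted least-squares fit of ``z = f(x, y)`` to a vertex cloud.

    Parameters
    ----------
    points : (n, 3) array — vertex cloud of the contact surface.
    order : total polynomial degree (2, 4 and 5 are the standard choices).
    weights : optional per-point non-negative weights.  Mesh-refinement
        style emphasis near the dislocation-critical ridge is expressed
        here directly as larger weights on those vertices.

    Returns a :class:`PolynomialSurface` whose ``r_squared`` is computed on
    the fitting cloud: ``1 - SS_res / SS_tot`` with ``SS_tot`` about the
    weighted mean of ``z``.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise FitError("points must be (n, 3)")
    nterms = n_coefficients(order)
    if len(pts) < nterms:
        raise FitError(f"need >= {nterms} points for order {order}, got {len(pts)}")
    if weights is None:
        w = np.ones(len(pts))
    else:
        w = np.asarray(weights, float)
        if w.shape != (len(pts),):
            raise FitError("weights must be one per point")
        if np.any(w < 0):
            raise FitError("weights must be >= 0")
        if not np.any(w > 0):
            raise FitError("all weights are zero")

    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    x0, x1 = float(x.min()), float(x.max())
    y0, y1 = float(y.min()), float(y.max())
    if x1 <= x0 or y1 <= y0:
        raise FitError("degenerate point cloud: zero extent in x or y")
    cx, hx = 0.5 * (x0 + x1), 0.5 * (x1 - x0)
    cy, hy = 0.5 * (y0 + y1), 0.5 * (y1 - y0)
    u = (x - cx) / hx
    v = (y - cy) / hy

    exps = _exponents(order)
    A = (u[:, None] ** exps[:, 0]) * (v[:, None] ** exps[:, 1])
    sw = np.sqrt(w)
    coef_scaled, _, rank, _ = np.linalg.lstsq(A * sw[:, None], z * sw, rcond=None)
    if rank < nterms:
        raise FitError(
            f"rank-deficient design: rank {rank} < {nterms} unknowns "
            "(points collinear or insufficient spread)")

    zhat = A @ coef_scaled
    res = z - zhat
    ss_res = float(np.sum(w * res * res))
    zbar = float(np.sum(w * z) / np.sum(w))
    ss_tot = float(np.sum(w * (z - zbar) ** 2))
    r2_raw = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rmse = float(np.sqrt(ss_res / np.sum(w)))

    coefs = _uncenter(coef_scaled, exps, cx, hx, cy, hy, order)
    return PolynomialSurface(order=order, coefficients=coefs,
                             fit_domain=((x0, x1), (y0, y1)),
                             r_squared=float(np.clip(r2_raw, 0.0, 1.0)),
                             r_squared_raw=r2_raw, rmse_fit=rmse,
                             exponents=exps)


def _uncenter(coef_scaled, exps, cx, hx, cy, hy, order):
    """Expand coefficients of ((x-cx)/hx)^i ((y-cy)/hy)^j into raw x^i y^j."""
    from math import comb
    out = np.zeros(len(exps))
    index = {(int(i), int(j)): k for k, (i, j) in enumerate(exps)}
    for k, (i, j) in enumerate(exps):
        c = coef_scaled[k] / (hx ** i * hy ** j)
        for a in range(i + 1):
            ca = comb(i, a) * (-cx) ** (i - a)
            for b in range(j + 1):
                cb = comb(j, b) * (-cy) ** (j - b)
                out[index[(a, b)]] += c * ca * cb
    return out
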