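"""Marker-trajectory handling: filtering, rigid-body pose reconstruction,
and spline guidance for the integrator.

The processing chain mirrors a typical optical-capture pipeline: marker
positions at 100 Hz, a zero-phase second-order Butterworth low-pass at
12 Hz on the trajectories, singular-spectrum analysis (window 30) for
force channels, and pose reconstruction from three non-collinear entities
per segment (markers or known joint locations) via an orthogonal frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import hankel
from scipy.signal import butter, filtfilt

from .errors import ConfigError, PftwinError
from .quat import quat_from_matrix, slerp_sign

__all__ = [
    "MarkerTrajectories", "BodyPoseSeries", "FrameRecipe", "SplineGuidance",
    "butterworth_filter", "ssa_filter", "vaughan_frames",
    "read_marker_csv", "write_marker_csv",
]


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class MarkerTrajectories:
    """Marker positions (m) sampled uniformly at ``fs`` Hz.

    ``positions``: (n_frames, n_markers, 3); gaps are NaN rows flagged in
    ``gap_mask``.
    """

    ids: List[str]
    positions: np.ndarray
    fs: float = 100.0
    gap_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        if self.fs <= 0:
            raise ConfigError("sampling frequency must be > 0")
        if self.positions.ndim != 3 or self.positions.shape[1] != len(self.ids):
            raise ConfigError("positions must be (n_frames, n_markers, 3)")
        if self.gap_mask is None:
            self.gap_mask = np.any(~np.isfinite(self.positions), axis=2)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs

    def marker(self, mid: str) -> np.ndarray:
        return self.positions[:, self.ids.index(mid), :]

    def fill_gaps(self, max_gap: int = 5) -> "MarkerTrajectories":
        """Linear interpolation of gaps up to ``max_gap`` frames."""
        pos = self.positions.copy()
        t = np.arange(self.n_frames)
        for m in range(pos.shape[1]):
            bad = self.gap_mask[:, m]
            if not bad.any():
                continue
            runs = _runs(bad)
            for a, b in runs:
                if b - a > max_gap or a == 0 or b == self.n_frames:
                    raise PftwinError(
                        f"marker {self.ids[m]}: gap of {b - a} frames at "
                        f"{a} exceeds fillable length {max_gap}")
            good = ~bad
            for k in range(3):
                pos[bad, m, k] = np.interp(t[bad], t[good], pos[good, m, k])
        return MarkerTrajectories(self.ids, pos, self.fs,
                                  np.zeros_like(self.gap_mask))

    def filtered(self, cutoff: float = 12.0, order: int = 2) -> "MarkerTrajectories":
        if self.gap_mask.any():
            raise PftwinError("fill gaps before filtering")
        flat = self.positions.reshape(self.n_frames, -1)
        out = butterworth_filter(flat, self.fs, cutoff=cutoff, order=order)
        return MarkerTrajectories(self.ids, out.reshape(self.positions.shape),
                                  self.fs, np.zeros_like(self.gap_mask))


def _runs(mask: np.ndarray):
    """Contiguous True runs as (start, stop) pairs."""
    idx = np.nonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))[0]
    return list(zip(idx[0::2], idx[1::2]))


@dataclass
class BodyPoseSeries:
    """Per-frame pose (position + unit quaternion) of one rigid body."""

    body: str
    t: np.ndarray
    r: np.ndarray            # (n, 3)
    e: np.ndarray            # (n, 4), sign-continuous
    source_markers: List[str] = field(default_factory=list)

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.r = np.asarray(self.r, float)
        e = np.asarray(self.e, float)
        e = e / np.linalg.norm(e, axis=1, keepdims=True)
        self.e = slerp_sign(e)

    def spline(self) -> "SplineGuidance":
        return SplineGuidance(self)


class SplineGuidance:
    """Cubic-spline interpolation of a pose series onto the integration
    grid, with analytic first/second derivatives for the guided bodies."""

    def __init__(self, series: BodyPoseSeries):
        self._sr = CubicSpline(series.t, series.r, axis=0)
        self._se = CubicSpline(series.t, series.e, axis=0)
        self._t0 = float(series.t[0])
        self._t1 = float(series.t[-1])

    def _clamp(self, t):
        return min(max(t, self._t0), self._t1)

    def pose(self, t):
        t = self._clamp(t)
        e = self._se(t)
        return self._sr(t), e / np.linalg.norm(e)

    def velocity(self, t):
        t = self._clamp(t)
        return self._sr(t, 1), self._se(t, 1)

    def acceleration(self, t):
        t = self._clamp(t)
        return self._sr(t, 2), self._se(t, 2)


# --------------------------------------------------------------------------
# Filters
# --------------------------------------------------------------------------

def butterworth_filter(signal: np.ndarray, fs: float, cutoff: float = 12.0,
                       order: int = 2) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass along axis 0.

    The two-pass application squares the magnitude response and cancels
    phase, which matters because the filtered trajectories drive rheonomic
    constraints.  DC gain is exactly one; constant signals pass unchanged.
    """
    signal = np.asarray(signal, float)
    if fs <= 2.0 * cutoff:
        raise ConfigError(f"fs = {fs} must exceed twice the cutoff {cutoff}")
    b, a = butter(order, cutoff / (fs / 2.0))
    padlen = 3 * (max(len(a), len(b)) - 1)
    if signal.shape[0] <= padlen:
        raise PftwinError(
            f"signal length {signal.shape[0]} too short for filter warm-up "
            f"({padlen})")
    return filtfilt(b, a, signal, axis=0)


def ssa_filter(signal: np.ndarray, window: int = 30,
               rank: Optional[int] = None,
               var_target: Optional[float] = None,
               noise_factor: float = 3.0) -> np.ndarray:
    """Singular-spectrum-analysis smoothing of a 1-D series.

    Embedding into the trajectory (Hankel) matrix with the given window,
    SVD, component grouping, diagonal averaging back to a series of the
    original length.  Component selection, in order of precedence: a
    fixed ``rank``; the smallest rank capturing ``var_target`` of the
    trajectory-matrix variance; or (default) all components whose singular
    value exceeds ``noise_factor`` times the median singular value — the
    median estimates the flat noise floor, so broadband noise components
    are dropped while narrowband structure is kept.
    """
    x = np.asarray(signal, float)
    if x.ndim != 1:
        return np.stack([ssa_filter(col, window, rank, var_target,
                                    noise_factor)
                         for col in x.T], axis=1)
    n = len(x)
    if window < 2:
        raise ConfigError("SSA window must be >= 2")
    if n <= 2 * window:
        raise PftwinError(f"signal length {n} must exceed twice the window")
    X = hankel(x[:window], x[window - 1:])       # (window, n - window + 1)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if rank is None and var_target is not None:
        frac = np.cumsum(s ** 2) / np.sum(s ** 2)
        rank = int(np.searchsorted(frac, var_target) + 1)
    elif rank is None:
        floor = float(np.median(s))
        rank = max(1, int(np.sum(s > noise_factor * floor)))
    rank = min(rank, len(s))
    Xr = (U[:, :rank] * s[:rank]) @ Vt[:rank]
    # diagonal averaging (Hankelization)
    out = np.zeros(n)
    cnt = np.zeros(n)
    idx = np.arange(window)[:, None] + np.arange(X.shape[1])[None, :]
    np.add.at(out, idx, Xr)
    np.add.at(cnt, idx, 1.0)
    return out / cnt


# --------------------------------------------------------------------------
# Pose reconstruction (three-entity orthogonal frames)
# --------------------------------------------------------------------------

@dataclass
class FrameRecipe:
    """Three non-collinear entities defining a segment frame.

    Each entity is a marker id or a named joint location; ``local`` maps
    entity name -> coordinates in the body frame.  The orthogonal frame is
    built from (origin, axis, plane): x along origin->axis, z along
    x cross (origin->plane), y completing the right-handed triad.
    """

    origin: str
    axis: str
    plane: str
    local: Dict[str, Sequence[float]]

    def entity_names(self) -> List[str]:
        return [self.origin, self.axis, self.plane]


def _frame_from_points(o, a, p, min_area: float = 1e-10):
    u = a - o
    nu = np.linalg.norm(u)
    w = np.cross(u, p - o)
    area = 0.5 * np.linalg.norm(w)
    if area < min_area or nu == 0:
        raise PftwinError(f"collinear entities (triangle area {area:.2e} m^2)")
    x = u / nu
    z = w / np.linalg.norm(w)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def vaughan_frames(markers: Dict[str, np.ndarray], recipe: FrameRecipe,
                   t: Optional[np.ndarray] = None, fs: float = 100.0,
                   body: str = "body") -> BodyPoseSeries:
    """Reconstruct a rigid body's pose series from three tracked entities.

    ``markers`` maps entity name -> (n_frames, 3) world positions.  The
    same orthogonal-frame construction applied to the entities' body-frame
    coordinates gives the constant local frame, so the pose follows as
    ``R = F_world F_local^T``, ``r = o_world - R o_local``.
    """
    names = recipe.entity_names()
    for nm in names:
        if nm not in markers:
            raise ConfigError(f"entity '{nm}' missing from marker data")
        if nm not in recipe.local:
            raise ConfigError(f"entity '{nm}' missing local coordinates")
    O = np.asarray(markers[recipe.origin], float)
    A = np.asarray(markers[recipe.axis], float)
    P = np.asarray(markers[recipe.plane], float)
    n = len(O)
    lo = np.asarray(recipe.local[recipe.origin], float)
    la = np.asarray(recipe.local[recipe.axis], float)
    lp = np.asarray(recipe.local[recipe.plane], float)
    F_loc = _frame_from_points(lo, la, lp)

    r = np.empty((n, 3))
    e = np.empty((n, 4))
    for k in range(n):
        try:
            Fw = _frame_from_points(O[k], A[k], P[k])
        except PftwinError as exc:
            raise PftwinError(f"frame {k}: {exc}") from exc
        R = Fw @ F_loc.T
        r[k] = O[k] - R @ lo
        e[k] = quat_from_matrix(R)
    if t is None:
        t = np.arange(n) / fs
    return BodyPoseSeries(body=body, t=t, r=r, e=e, source_markers=names)


# --------------------------------------------------------------------------
# Marker CSV dialect: header frame,time,id,x,y,z ; gaps as empty cells
# --------------------------------------------------------------------------

def write_marker_csv(traj: MarkerTrajectories, path) -> None:
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "time", "id", "x", "y", "z"])
        for f in range(traj.n_frames):
            t = f / traj.fs
            for m, mid in enumerate(traj.ids):
                p = traj.positions[f, m]
                if traj.gap_mask[f, m]:
                    w.writerow([f, f"{t:.6f}", mid, "", "", ""])
                else:
                    w.writerow([f, f"{t:.6f}", mid,
                                f"{p[0]:.9f}", f"{p[1]:.9f}", f"{p[2]:.9f}"])


def read_marker_csv(path) -> MarkerTrajectories:
    import csv
    rows = []
    with open(path) as fh:
        rd = csv.DictReader(fh)
        for row in rd:
            rows.append(row)
    if not rows:
        raise PftwinError(f"empty marker file {path}")
    ids = sorted({r["id"] for r in rows},
                 key=[r["id"] for r in rows].index)
    frames = sorted({int(r["frame"]) for r in rows})
    n = frames[-1] + 1
    pos = np.full((n, len(ids), 3), np.nan)
    times = {}
    for r in rows:
        f = int(r["frame"])
        times[f] = float(r["time"])
        m = ids.index(r["id"])
        if r["x"] != "":
            pos[f, m] = [float(r["x"]), float(r["y"]), float(r["z"])]
    ts = np.array([times.get(f, np.nan) for f in range(n)])
    dt = np.diff(ts[np.isfinite(ts)])
    fs = 1.0 / np.median(dt) if len(dt) else 100.0
    return MarkerTrajectories(list(ids), pos, fs=float(round(fs, 6)))
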