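"""Validation metrics and clinical-event detection.

Patellar kinematics are expressed in the femoral body frame (avoiding
error accumulation from absolute coordinates): the sphere-center position
plus a tilt/flexion/rotation angle triple.  The Euler sequence is fixed
as intrinsic Y-X-Z — flexion about the medial-lateral Y axis first, tilt
about the patellar long (X) axis second, rotation about the
anterior-posterior Z axis last; axis names follow the anatomical
convention, so "tilt" is the X-axis angle even though it is the middle
factor.

Event detection flags the two instability phenomena the bench can
produce: lateral dislocation (sustained loss of groove contact with the
sphere center beyond the lateral ridge line while the knee extends) and
a high-riding patella (during flexion the center stays superior to the
groove entrance without engaging).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .dynamics import Trajectory
from .errors import ConfigError
from .quat import rotmat

__all__ = ["ValidationReport", "PatellarKinematics", "patellar_kinematics",
           "rmse_report", "detect_events", "Event", "EventThresholds",
           "kinematics_from_trajectory"]


# --------------------------------------------------------------------------
# Kinematics in the femur frame
# --------------------------------------------------------------------------

@dataclass
class PatellarKinematics:
    """Sphere-center position (m) and angles (rad) in the femoral frame."""

    t: np.ndarray
    position: np.ndarray          # (n, 3)
    tilt: np.ndarray              # about patellar X (long axis)
    flexion: np.ndarray           # about Y (medial-lateral)
    rotation: np.ndarray          # about Z (anterior-posterior)


def patellar_kinematics(patella_r, patella_e, femur_r, femur_e,
                        sphere_center_offset=(0.0, 0.0, 0.0),
                        t: Optional[np.ndarray] = None) -> PatellarKinematics:
    """Relative patellar kinematics from synchronized pose series.

    Angles come from the intrinsic Y-X-Z factorization of the relative
    rotation ``R_rel = R_femur^T R_patella``.
    """
    patella_r = np.asarray(patella_r, float)
    femur_r = np.asarray(femur_r, float)
    if len(patella_r) != len(femur_r):
        raise ConfigError("pose series lengths differ")
    n = len(patella_r)
    off = np.asarray(sphere_center_offset, float)
    pos = np.empty((n, 3))
    ang = np.empty((n, 3))
    for k in range(n):
        Rf = rotmat(femur_e[k])
        Rp = rotmat(patella_e[k])
        center_w = patella_r[k] + Rp @ off
        pos[k] = Rf.T @ (center_w - femur_r[k])
        rel = Rf.T @ Rp
        ang[k] = Rotation.from_matrix(rel).as_euler("YXZ")
    return PatellarKinematics(
        t=np.arange(n, dtype=float) if t is None else np.asarray(t, float),
        position=pos, tilt=ang[:, 1], flexion=ang[:, 0], rotation=ang[:, 2])


def kinematics_from_trajectory(traj: Trajectory,
                               sphere_center_offset=(0.0, 0.0, 0.0)
                               ) -> PatellarKinematics:
    return patellar_kinematics(traj.body_r("patella"), traj.body_e("patella"),
                               traj.body_r("femur"), traj.body_e("femur"),
                               sphere_center_offset, t=traj.t)


# --------------------------------------------------------------------------
# RMSE report
# --------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Channel-wise RMSE between a simulated and a reference run.

    Units follow the bench instrumentation: forces in N, angles in
    degrees, coordinates and the mean distance error in mm.
    """

    contact_force: float
    tibial_spring_force: float
    femoral_spring_force: float
    int_rotation: float
    flexion: float
    tilt: float
    x_coord: float
    y_coord: float
    z_coord: float
    mean_distance: float
    runtime_ratio: float = float("nan")

    def __post_init__(self):
        for name in ("contact_force", "tibial_spring_force",
                     "femoral_spring_force", "int_rotation", "flexion",
                     "tilt", "x_coord", "y_coord", "z_coord",
                     "mean_distance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in self.__dataclass_fields__}


def _rmse(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _resample(t_src, y_src, t_dst):
    y_src = np.asarray(y_src, float)
    if y_src.ndim == 1:
        return np.interp(t_dst, t_src, y_src)
    return np.stack([np.interp(t_dst, t_src, y_src[:, k])
                     for k in range(y_src.shape[1])], axis=1)


def rmse_report(sim: Trajectory, ref: Trajectory,
                sphere_center_offset=(0.0, 0.0, 0.0)) -> ValidationReport:
    """Channel-wise RMSE of a simulated trajectory against a reference.

    The simulated channels are linearly resampled onto the reference time
    base over the common window; kinematic channels are compared in the
    femur frame.  Symmetric in its arguments up to the (shared) time base.
    """
    from .bench import grouped_tensions
    t0 = max(sim.t[0], ref.t[0])
    t1 = min(sim.t[-1], ref.t[-1])
    if t1 <= t0:
        raise ConfigError("no overlapping time window")
    t = ref.t[(ref.t >= t0) & (ref.t <= t1)]

    kin_s = kinematics_from_trajectory(sim, sphere_center_offset)
    kin_r = kinematics_from_trajectory(ref, sphere_center_offset)
    pos_s = _resample(sim.t, kin_s.position, t)
    pos_r = _resample(ref.t, kin_r.position, t)
    ang_s = np.stack([_resample(sim.t, a, t) for a in
                      (kin_s.rotation, kin_s.flexion, kin_s.tilt)], axis=1)
    ang_r = np.stack([_resample(ref.t, a, t) for a in
                      (kin_r.rotation, kin_r.flexion, kin_r.tilt)], axis=1)

    ten_s = grouped_tensions(sim)
    ten_r = grouped_tensions(ref)
    dist = np.linalg.norm(pos_s - pos_r, axis=1)
    rt = sim.stats.get("realtime_ratio", float("nan")) if sim.stats else float("nan")
    return ValidationReport(
        contact_force=_rmse(_resample(sim.t, sim.contact_force, t),
                            _resample(ref.t, ref.contact_force, t)),
        tibial_spring_force=_rmse(_resample(sim.t, ten_s["tibial"], t),
                                  _resample(ref.t, ten_r["tibial"], t)),
        femoral_spring_force=_rmse(_resample(sim.t, ten_s["femoral"], t),
                                   _resample(ref.t, ten_r["femoral"], t)),
        int_rotation=np.degrees(_rmse(ang_s[:, 0], ang_r[:, 0])),
        flexion=np.degrees(_rmse(ang_s[:, 1], ang_r[:, 1])),
        tilt=np.degrees(_rmse(ang_s[:, 2], ang_r[:, 2])),
        x_coord=1000.0 * _rmse(pos_s[:, 0], pos_r[:, 0]),
        y_coord=1000.0 * _rmse(pos_s[:, 1], pos_r[:, 1]),
        z_coord=1000.0 * _rmse(pos_s[:, 2], pos_r[:, 2]),
        mean_distance=1000.0 * float(np.mean(dist)),
        runtime_ratio=rt,
    )


# --------------------------------------------------------------------------
# Event detection
# --------------------------------------------------------------------------

@dataclass
class EventThresholds:
    """Fixture-calibrated detection constants (logged in every report)."""

    persistence: float = 0.050        # s of sustained disengagement
    ridge_fraction: float = 1.0       # |y| beyond ridge_fraction * halfwidth
    entrance_fraction: float = 0.75   # groove entrance at this * x_halfwidth
    flexion_threshold: float = np.radians(30.0)  # high-riding needs flexion past this


@dataclass
class Event:
    kind: str                         # "dislocation" | "high_riding"
    t_start: float
    t_end: float
    detail: dict = field(default_factory=dict)


def detect_events(traj: Trajectory, groove, flexion_angle: np.ndarray,
                  thresholds: Optional[EventThresholds] = None,
                  sphere_center_offset=(0.0, 0.0, 0.0)) -> List[Event]:
    """Scan a trajectory for dislocation / high-riding events.

    Parameters
    ----------
    traj : simulated trajectory (femur + patella poses, contact log).
    groove : :class:`~pftwin.geometry.GrooveParams` of the femoral surface.
    flexion_angle : knee flexion angle per recorded frame (rad).
    """
    th = thresholds or EventThresholds()
    kin = kinematics_from_trajectory(traj, sphere_center_offset)
    y = kin.position[:, 1]
    x = kin.position[:, 0]
    t = traj.t
    theta = np.asarray(flexion_angle, float)
    dtheta = np.gradient(theta, t)
    engaged = (traj.n_patches > 0) & (np.abs(y) <= groove.groove_halfwidth)

    events: List[Event] = []

    # dislocation: sustained loss of groove engagement with the center past
    # the lateral ridge line while the knee keeps extending
    lateral_out = (~engaged) & (y < -th.ridge_fraction * groove.groove_halfwidth)
    extending = dtheta < 1e-3
    for a, b in _runs(lateral_out & extending):
        if t[b - 1] - t[a] >= th.persistence:
            events.append(Event("dislocation", float(t[a]), float(t[b - 1]),
                                {"y_min_mm": float(1000 * y[a:b].min()),
                                 "thresholds": vars(th)}))
            break

    # high-riding: during flexion past the threshold the center stays
    # superior to the groove entrance with no engagement
    entrance_x = th.entrance_fraction * groove.x_halfwidth
    flexing = dtheta > 1e-3
    high = (~engaged) & (x > entrance_x) & (theta > th.flexion_threshold)
    for a, b in _runs(high & flexing):
        if t[b - 1] - t[a] >= th.persistence:
            events.append(Event("high_riding", float(t[a]), float(t[b - 1]),
                                {"x_max_mm": float(1000 * x[a:b].max()),
                                 "thresholds": vars(th)}))
            break
    return events


def _runs(mask: np.ndarray):
    idx = np.nonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))[0]
    return list(zip(idx[0::2], idx[1::2]))
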