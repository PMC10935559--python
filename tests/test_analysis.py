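"""Validation metrics, patellar kinematics, event detection."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pftwin.analysis import (EventThresholds, PatellarKinematics,
                             ValidationReport, detect_events,
                             patellar_kinematics, rmse_report)
from pftwin.bench import ScenarioConfig, grouped_tensions
from pftwin.dynamics import SimConfig, Trajectory
from pftwin.quat import quat_from_axis_angle, quat_from_matrix, rotmat


def make_traj(t, pat_r, pat_e, fem_r=None, fem_e=None, forces=None,
              tensions=None, n_patches=None):
    """Assemble a Trajectory container from arrays (kinematic fixture)."""

    class _M:
        body_names = ["femur", "tibia", "patella"]

    traj = Trajectory.__new__(Trajectory)
    n = len(t)
    fem_r = np.zeros((n, 3)) if fem_r is None else fem_r
    fem_e = (np.tile([1.0, 0, 0, 0], (n, 1)) if fem_e is None else fem_e)
    traj.body_names = ["femur", "tibia", "patella"]
    traj.spring_count = 4
    traj.config = SimConfig()
    traj.t = np.asarray(t, float)
    traj.poses = {
        "femur": np.column_stack([fem_r, fem_e]),
        "tibia": np.column_stack([fem_r, fem_e]),
        "patella": np.column_stack([pat_r, pat_e]),
    }
    traj.vels = {b: np.zeros((n, 6)) for b in traj.body_names}
    traj.spring_tensions = (np.zeros((n, 4)) if tensions is None else tensions)
    traj.contact_force = np.zeros(n) if forces is None else forces
    traj.contact_delta = np.zeros(n)
    traj.contact_point = np.full((n, 3), np.nan)
    traj.n_patches = (np.ones(n, int) if n_patches is None else n_patches)
    traj.max_phi = np.zeros(n)
    traj.max_vel_res = np.zeros(n)
    traj.events = []
    traj.stats = {"realtime_ratio": 1.0}
    return traj


def quat_series(n, e=None):
    e = np.array([1.0, 0, 0, 0]) if e is None else e
    return np.tile(e, (n, 1))


class TestPatellarKinematics:
    def test_constant_relative_pose_gives_constant_outputs(self):
        n = 10
        kin = patellar_kinematics(np.tile([0.1, 0.2, 0.3], (n, 1)),
                                  quat_series(n),
                                  np.zeros((n, 3)), quat_series(n))
        assert np.ptp(kin.position, axis=0).max() == 0
        assert np.ptp(kin.flexion) == 0

    def test_pure_y_rotation_reads_as_flexion(self):
        n = 3
        e = quat_from_axis_angle([0, 1, 0], np.radians(30))
        kin = patellar_kinematics(np.zeros((n, 3)), quat_series(n, e),
                                  np.zeros((n, 3)), quat_series(n))
        assert np.degrees(kin.flexion[0]) == pytest.approx(30.0, abs=1e-9)
        assert abs(np.degrees(kin.tilt[0])) < 1e-9
        assert abs(np.degrees(kin.rotation[0])) < 1e-9

    def test_random_poses_match_scipy_decomposition(self, rng):
        for _ in range(200):
            Rf = Rotation.random(random_state=rng).as_matrix()
            Rp = Rotation.random(random_state=rng).as_matrix()
            kin = patellar_kinematics(
                np.zeros((1, 3)), quat_series(1, quat_from_matrix(Rp)),
                np.zeros((1, 3)), quat_series(1, quat_from_matrix(Rf)))
            y, x, z = Rotation.from_matrix(Rf.T @ Rp).as_euler("YXZ")
            assert kin.flexion[0] == pytest.approx(y, abs=1e-9)
            assert kin.tilt[0] == pytest.approx(x, abs=1e-9)
            assert kin.rotation[0] == pytest.approx(z, abs=1e-9)

    def test_positions_expressed_in_femur_frame(self):
        n = 2
        e_f = quat_from_axis_angle([0, 0, 1], np.pi / 2)
        kin = patellar_kinematics(np.tile([0.0, 0.1, 0.0], (n, 1)),
                                  quat_series(n),
                                  np.zeros((n, 3)), quat_series(n, e_f))
        assert np.allclose(kin.position[0], [0.1, 0.0, 0.0], atol=1e-12)


class TestRMSEReport:
    def test_self_comparison_is_zero(self):
        t = np.linspace(0, 1, 101)
        r = np.stack([0.01 * np.sin(t), 0.002 * t, 0.02 + 0 * t], axis=1)
        tr = make_traj(t, r, quat_series(len(t)))
        rep = rmse_report(tr, tr)
        for name in ("contact_force", "x_coord", "tilt", "mean_distance"):
            assert getattr(rep, name) == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_reads_in_mm(self):
        t = np.linspace(0, 1, 101)
        r = np.zeros((len(t), 3))
        a = make_traj(t, r, quat_series(len(t)))
        b = make_traj(t, r + np.array([0.002, 0, 0]), quat_series(len(t)))
        rep = rmse_report(a, b)
        assert rep.x_coord == pytest.approx(2.0, abs=1e-9)
        assert rep.mean_distance == pytest.approx(2.0, abs=1e-9)

    def test_symmetry(self, rng):
        t = np.linspace(0, 1, 51)
        ra = 0.01 * rng.normal(size=(len(t), 3))
        rb = 0.01 * rng.normal(size=(len(t), 3))
        a = make_traj(t, ra, quat_series(len(t)),
                      forces=rng.normal(size=len(t)))
        b = make_traj(t, rb, quat_series(len(t)),
                      forces=rng.normal(size=len(t)))
        ab, ba = rmse_report(a, b), rmse_report(b, a)
        for name in ("contact_force", "x_coord", "y_coord", "z_coord",
                     "tilt", "flexion", "int_rotation", "mean_distance"):
            assert getattr(ab, name) == pytest.approx(getattr(ba, name),
                                                      rel=1e-12)

    def test_matches_naive_recomputation(self, rng):
        t = np.linspace(0, 1, 41)
        fa = rng.normal(size=len(t))
        fb = rng.normal(size=len(t))
        a = make_traj(t, np.zeros((len(t), 3)), quat_series(len(t)), forces=fa)
        b = make_traj(t, np.zeros((len(t), 3)), quat_series(len(t)), forces=fb)
        rep = rmse_report(a, b)
        assert rep.contact_force == pytest.approx(
            np.sqrt(np.mean((fa - fb) ** 2)), rel=1e-12)

    def test_negative_channel_rejected(self):
        with pytest.raises(ValueError):
            ValidationReport(contact_force=-1, tibial_spring_force=0,
                             femoral_spring_force=0, int_rotation=0,
                             flexion=0, tilt=0, x_coord=0, y_coord=0,
                             z_coord=0, mean_distance=0)


class TestDetectEvents:
    def groove(self):
        return ScenarioConfig().groove

    def _flexion(self, t, kind):
        if kind == "extend":
            return np.radians(60.0) * (1 - t / t[-1])
        return np.radians(60.0) * t / t[-1]

    def test_tracking_inside_groove_yields_no_events(self):
        g = self.groove()
        t = np.linspace(0, 2, 201)
        r = np.stack([0.002 * np.sin(t), 0.001 * np.cos(t),
                      np.full(len(t), 0.018)], axis=1)
        tr = make_traj(t, r, quat_series(len(t)))
        assert detect_events(tr, g, self._flexion(t, "extend")) == []

    def test_lateral_excursion_during_extension_is_dislocation(self):
        g = self.groove()
        t = np.linspace(0, 2, 201)
        y = np.where(t > 1.0, -1.3 * g.groove_halfwidth, 0.0)
        r = np.stack([np.zeros(len(t)), y, np.full(len(t), 0.02)], axis=1)
        npatch = (t <= 1.0).astype(int)
        tr = make_traj(t, r, quat_series(len(t)), n_patches=npatch)
        ev = detect_events(tr, g, self._flexion(t, "extend"))
        assert [e.kind for e in ev] == ["dislocation"]
        assert ev[0].t_start >= 1.0

    def test_short_excursion_below_persistence_ignored(self):
        g = self.groove()
        t = np.linspace(0, 2, 201)   # 10 ms per frame
        y = np.zeros(len(t))
        y[100:103] = -1.3 * g.groove_halfwidth   # 30 ms < 50 ms
        r = np.stack([np.zeros(len(t)), y, np.full(len(t), 0.02)], axis=1)
        npatch = np.ones(len(t), int)
        npatch[100:103] = 0
        tr = make_traj(t, r, quat_series(len(t)), n_patches=npatch)
        assert detect_events(tr, g, self._flexion(t, "extend")) == []

    def test_superior_hold_during_flexion_is_high_riding(self):
        g = self.groove()
        t = np.linspace(0, 2, 201)
        x = np.full(len(t), 0.9 * g.x_halfwidth)   # stuck superior
        r = np.stack([x, np.zeros(len(t)), np.full(len(t), 0.025)], axis=1)
        tr = make_traj(t, r, quat_series(len(t)),
                       n_patches=np.zeros(len(t), int))
        ev = detect_events(tr, g, self._flexion(t, "flex"))
        assert [e.kind for e in ev] == ["high_riding"]

    def test_thresholds_are_logged_in_the_event(self):
        g = self.groove()
        t = np.linspace(0, 2, 201)
        y = np.where(t > 0.5, -1.5 * g.groove_halfwidth, 0.0)
        r = np.stack([np.zeros(len(t)), y, np.full(len(t), 0.02)], axis=1)
        tr = make_traj(t, r, quat_series(len(t)),
                       n_patches=np.zeros(len(t), int))
        ev = detect_events(tr, g, self._flexion(t, "extend"),
                           thresholds=EventThresholds(persistence=0.1))
        assert ev[0].detail["thresholds"]["persistence"] == 0.1
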