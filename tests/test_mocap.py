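"""Marker filtering, SSA, pose reconstruction, synthetic capture."""

import numpy as np
import pytest

from pftwin.bench import ScenarioConfig, flexion_profile, synth_motion
from pftwin.errors import ConfigError, PftwinError
from pftwin.mocap import (BodyPoseSeries, FrameRecipe, MarkerTrajectories,
                          butterworth_filter, read_marker_csv, ssa_filter,
                          vaughan_frames, write_marker_csv)
from pftwin.quat import quat_from_axis_angle, rotmat


class TestButterworth:
    def test_constant_signal_unchanged(self):
        x = np.full(500, 3.7)
        y = butterworth_filter(x, fs=100.0)
        assert np.abs(y - x).max() < 1e-12

    def test_passband_tone_preserved(self):
        t = np.arange(1000) / 100.0
        x = np.sin(2 * np.pi * 2.0 * t)
        y = butterworth_filter(x, fs=100.0)
        core = slice(100, -100)
        assert np.abs(y[core]).max() == pytest.approx(1.0, rel=0.01)

    def test_stopband_tone_attenuated_20db(self):
        t = np.arange(2000) / 100.0
        x = np.sin(2 * np.pi * 40.0 * t)
        y = butterworth_filter(x, fs=100.0)
        assert np.abs(y[200:-200]).max() < 0.1   # > 20 dB down

    def test_zero_phase(self):
        t = np.arange(1000) / 100.0
        x = np.sin(2 * np.pi * 1.0 * t)
        y = butterworth_filter(x, fs=100.0)
        # zero crossings unshifted
        k = np.argmin(np.abs(t - 0.5))
        assert abs(y[k]) < 1e-3

    def test_idempotent_on_band_limited_signal(self):
        t = np.arange(2000) / 100.0
        x = (np.sin(2 * np.pi * 1.5 * t) + 0.5 * np.sin(2 * np.pi * 4.0 * t))
        once = butterworth_filter(x, fs=100.0)
        twice = butterworth_filter(once, fs=100.0)
        core = slice(200, -200)
        rms = np.sqrt(np.mean((twice[core] - once[core]) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(once[core] ** 2))

    def test_guards(self):
        with pytest.raises(ConfigError):
            butterworth_filter(np.zeros(100), fs=20.0, cutoff=12.0)
        with pytest.raises(PftwinError):
            butterworth_filter(np.zeros(5), fs=100.0)


class TestSSA:
    def test_constant_signal_unchanged(self):
        x = np.full(200, 2.5)
        assert np.abs(ssa_filter(x, window=30) - x).max() < 1e-10

    def test_pure_sinusoid_two_components(self):
        t = np.arange(400)
        x = np.sin(2 * np.pi * t / 20.0)
        y = ssa_filter(x, window=30, rank=2)
        assert np.sqrt(np.mean((y - x) ** 2)) < 0.01

    def test_noise_power_reduced(self):
        rng = np.random.default_rng(7)
        t = np.arange(600)
        clean = np.sin(2 * np.pi * t / 25.0)
        noise = rng.normal(0, np.sqrt(np.mean(clean ** 2) / 10), len(t))
        y = ssa_filter(clean + noise, window=30)
        residual = y - clean
        assert np.mean(residual ** 2) < 0.2 * np.mean(noise ** 2)

    def test_window_guards(self):
        with pytest.raises(ConfigError):
            ssa_filter(np.zeros(100), window=1)
        with pytest.raises(PftwinError):
            ssa_filter(np.zeros(50), window=30)


class TestVaughan:
    def recipe(self):
        local = {"a": [0.0, 0, 0], "b": [0.1, 0, 0], "c": [0.0, 0.12, 0.03]}
        return FrameRecipe("a", "b", "c", local)

    def test_rigid_transform_recovered_exactly(self, rng):
        rec = self.recipe()
        n = 40
        rs = rng.normal(0, 0.3, (n, 3))
        es = np.array([quat_from_axis_angle(rng.normal(size=3), a)
                       for a in rng.uniform(-2, 2, n)])
        markers = {k: np.array([rs[i] + rotmat(es[i]) @ rec.local[k]
                                for i in range(n)])
                   for k in rec.local}
        ps = vaughan_frames(markers, rec)
        assert np.abs(ps.r - rs).max() < 1e-12
        dots = np.abs(np.sum(ps.e * np.array([e / np.linalg.norm(e) for e in es]),
                             axis=1))
        assert (1 - dots).max() < 1e-12

    def test_collinear_markers_rejected(self):
        rec = FrameRecipe("a", "b", "c",
                          {"a": [0, 0, 0], "b": [1, 0, 0], "c": [2, 0, 0]})
        markers = {k: np.tile(rec.local[k], (5, 1)).astype(float)
                   for k in rec.local}
        with pytest.raises(PftwinError, match="collinear"):
            vaughan_frames(markers, rec)

    def test_noise_robustness_wide_cluster(self, rng):
        # 0.5 mm iid noise on a >= 10 cm cluster: < 1 deg / < 1 mm errors
        local = {"a": [0.0, 0, 0], "b": [0.12, 0, 0], "c": [0.0, 0.11, 0.02]}
        rec = FrameRecipe("a", "b", "c", local)
        n = 100
        r_true = np.array([0.2, -0.1, 0.05])
        e_true = quat_from_axis_angle([0.3, 1, 0.2], 0.7)
        R = rotmat(e_true)
        markers = {k: np.tile(r_true + R @ np.asarray(v), (n, 1))
                   + rng.normal(0, 5e-4, (n, 3))
                   for k, v in local.items()}
        ps = vaughan_frames(markers, rec)
        pos_err = np.linalg.norm(ps.r.mean(axis=0) - r_true)
        assert pos_err < 1e-3
        ang = []
        for e in ps.e:
            d = abs(float(e @ e_true))
            ang.append(2 * np.arccos(min(d, 1.0)))
        assert np.degrees(np.mean(ang)) < 1.0


class TestSynthMotion:
    def test_noiseless_closure_through_vaughan(self, scenario):
        markers, truth = synth_motion(scenario)
        lay = scenario.layout
        for body in ("tibia", "patella"):
            rec = lay.recipe(body)
            mk = {m: markers.marker(m) for m in rec.entity_names()}
            ps = vaughan_frames(mk, rec, body=body)
            assert np.abs(ps.r - truth[body].r).max() < 1e-10
            dots = np.abs(np.sum(ps.e * truth[body].e, axis=1))
            assert (1 - dots).max() < 1e-10

    def test_femur_uses_hip_joint_entity(self, scenario):
        markers, truth = synth_motion(scenario)
        rec = scenario.layout.recipe("femur")
        mk = {"F1": markers.marker("F1"), "F2": markers.marker("F2"),
              "HIP": np.tile(scenario.layout.hip_local, (markers.n_frames, 1))}
        ps = vaughan_frames(mk, rec, body="femur")
        assert np.abs(ps.r - truth["femur"].r).max() < 1e-10

    def test_flexion_profile_has_two_maxima(self, scenario):
        theta = flexion_profile(scenario.motion)
        t = np.linspace(0, scenario.motion.duration, 3001)
        v = theta(t)
        maxima = np.sum((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:]))
        assert maxima == 2

    def test_frame_count_at_100hz(self, scenario):
        markers, _ = synth_motion(scenario, fs=100.0)
        assert markers.n_frames == int(scenario.motion.duration * 100) + 1
        assert markers.fs == 100.0
        assert len(markers.ids) == 8

    def test_noise_is_seeded_and_reproducible(self):
        cfg = ScenarioConfig(marker_noise_std=5e-4, seed=3)
        a, _ = synth_motion(cfg)
        b, _ = synth_motion(cfg)
        assert np.array_equal(a.positions, b.positions)


class TestMarkerCSV:
    def test_roundtrip_with_gaps(self, tmp_path, rng):
        pos = rng.normal(size=(20, 3, 3))
        pos[5, 1] = np.nan
        traj = MarkerTrajectories(["m1", "m2", "m3"], pos, fs=100.0)
        write_marker_csv(traj, tmp_path / "m.csv")
        back = read_marker_csv(tmp_path / "m.csv")
        assert back.ids == ["m1", "m2", "m3"]
        assert back.fs == pytest.approx(100.0)
        assert back.gap_mask[5, 1]
        good = ~traj.gap_mask
        assert np.allclose(back.positions[good], pos[good], atol=1e-9)

    def test_gap_filling_short_gaps_only(self, rng):
        pos = np.cumsum(rng.normal(size=(30, 2, 3)), axis=0)
        pos[10:13, 0] = np.nan
        traj = MarkerTrajectories(["a", "b"], pos)
        filled = traj.fill_gaps(max_gap=5)
        assert not filled.gap_mask.any()
        pos2 = pos.copy()
        pos2[5:15, 1] = np.nan
        with pytest.raises(PftwinError, match="gap"):
            MarkerTrajectories(["a", "b"], pos2).fill_gaps(max_gap=5)
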