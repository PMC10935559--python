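"""Constrained rigid-body dynamics: integrator, constraints, equilibrium."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pftwin.collision import AnalyticContactBackend, SpherePrimitive
from pftwin.dynamics import (CallableGuidance, ContactPair, FrozenGuidance,
                             Model, RigidBody, SimConfig, SphericalJoint,
                             assemble, simulate, static_equilibrium, step)
from pftwin.errors import ConfigError
from pftwin.forces import FloresParams, SpringDamperParams
from pftwin.quat import rotmat
from pftwin.surface_fit import PolynomialSurface

G = 9.81
IDENTITY_GUIDE = CallableGuidance(
    lambda t: (np.zeros(3), np.array([1.0, 0, 0, 0])))


def plane_surface():
    return PolynomialSurface(order=2, coefficients=np.zeros(6),
                             fit_domain=((-1, 1), (-1, 1)))


def pendulum_model(L=1.0, theta0=0.05):
    r0 = np.array([L * np.sin(theta0), 0.0, -L * np.cos(theta0)])
    b = RigidBody("p", 1.0, np.eye(3) * 1e-4, r=r0)
    return assemble([b], constraints=[SphericalJoint("p", local_point=-r0)])


def pendulum_phase(h, T=4.0):
    m = pendulum_model()
    tr = simulate(m, (0.0, T), SimConfig(h=h))
    r = tr.body_r("p")[-1]
    return np.arctan2(r[0], -r[2]), tr


class TestAssembly:
    def test_free_body_dof(self):
        m = assemble([RigidBody("b", 1.0, np.eye(3) * 1e-3)])
        assert m.dof == 6

    def test_guided_bench_leaves_only_the_patella(self):
        fem = RigidBody("femur", 0.4, np.eye(3) * 1e-3, guided=True)
        tib = RigidBody("tibia", 0.5, np.eye(3) * 1e-3, guided=True)
        pat = RigidBody("patella", 0.03, np.eye(3) * 1e-6)
        m = Model([fem, tib, pat],
                  constraints=[SphericalJoint("femur", [0.3, 0, 0])],
                  guidance={"femur": IDENTITY_GUIDE, "tibia": IDENTITY_GUIDE})
        assert m.dof == 6

    def test_unguiding_the_tibia_adds_six(self):
        fem = RigidBody("femur", 0.4, np.eye(3) * 1e-3, guided=True)
        tib = RigidBody("tibia", 0.5, np.eye(3) * 1e-3)
        pat = RigidBody("patella", 0.03, np.eye(3) * 1e-6)
        m = Model([fem, tib, pat],
                  constraints=[SphericalJoint("femur", [0.3, 0, 0])],
                  guidance={"femur": IDENTITY_GUIDE})
        assert m.dof == 12

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ConfigError):
            assemble([RigidBody("a", 1, np.eye(3) * 1e-3),
                      RigidBody("a", 1, np.eye(3) * 1e-3)])

    def test_guided_body_requires_guidance(self):
        with pytest.raises(ConfigError):
            assemble([RigidBody("a", 1, np.eye(3) * 1e-3, guided=True)])


class TestIntegrator:
    def test_free_fall_is_exact(self):
        m = assemble([RigidBody("m", 1.0, np.eye(3) * 1e-3)])
        tr = simulate(m, (0.0, 1.0), SimConfig(h=1e-3))
        assert tr.body_r("m")[-1, 2] == pytest.approx(-0.5 * G, abs=1e-6)

    def test_pendulum_period_matches_small_angle_formula(self):
        L = 1.0
        T = 2 * np.pi * np.sqrt(L / G)
        m = pendulum_model(L)
        tr = simulate(m, (0.0, 5 * T), SimConfig(h=1e-3))
        x = tr.body_r("p")[:, 0]
        s = np.sign(x)
        idx = np.nonzero(np.diff(s) > 0)[0]
        tz = tr.t[idx] - x[idx] * (tr.t[idx + 1] - tr.t[idx]) / (x[idx + 1] - x[idx])
        period = np.mean(np.diff(tz))
        assert period == pytest.approx(T, rel=5e-3)

    def test_newmark_is_second_order(self):
        ref, _ = pendulum_phase(1.25e-4, T=3.0)
        e1 = abs(pendulum_phase(2e-3, T=3.0)[0] - ref)
        e2 = abs(pendulum_phase(1e-3, T=3.0)[0] - ref)
        e3 = abs(pendulum_phase(5e-4, T=3.0)[0] - ref)
        assert 3.0 < e1 / e2 < 5.5
        assert 3.0 < e2 / e3 < 5.5

    def test_constraint_residuals_stay_within_tolerance(self):
        _, tr = pendulum_phase(1e-3, T=2.0)
        cfg = SimConfig()
        assert tr.max_phi.max() <= cfg.pos_tol
        assert tr.max_vel_res.max() <= cfg.vel_tol

    def test_guided_body_follows_prescription(self):
        def pose(t):
            return (np.array([0.1 * np.sin(t), 0.0, 0.0]),
                    np.array([np.cos(0.2 * t), np.sin(0.2 * t), 0, 0]))
        g = CallableGuidance(pose)
        b = RigidBody("g", 1.0, np.eye(3) * 1e-3, guided=True)
        m = assemble([b], guidance={"g": g})
        tr = simulate(m, (0.0, 1.0), SimConfig(h=1e-3))
        for k in (100, 500, 1000):
            r, e = pose(tr.t[k])
            assert np.allclose(tr.body_r("g")[k], r, atol=1e-12)

    def test_torque_free_top_matches_euler_equations(self):
        J = np.diag([0.01, 0.02, 0.03])
        w0 = np.array([2.0, 0.5, -1.0])
        b = RigidBody("t", 1.0, J, omega=w0)
        m = assemble([b], gravity=(0, 0, 0))
        tr = simulate(m, (0.0, 1.0), SimConfig(h=5e-4))
        A = rotmat(tr.body_e("t")[-1])
        w_body = A.T @ tr.vels["t"][-1][3:]
        sol = solve_ivp(lambda t, w: np.linalg.solve(J, -np.cross(w, J @ w)),
                        (0, 1.0), w0, rtol=1e-11, atol=1e-12)
        assert np.allclose(w_body, sol.y[:, -1], atol=1e-5)

    def test_conservative_energy_drift_below_one_permille(self):
        gnd = RigidBody("gnd", 1.0, np.eye(3) * 1e-3, guided=True)
        mass = RigidBody("m", 0.5, np.eye(3) * 1e-4,
                         r=[0.3, 0.05, -0.2], v=[0.1, 0, 0.2])
        sp = SpringDamperParams(K=200.0, L0=0.25, c=0.0,
                                attach_A=("gnd", [0, 0, 0]),
                                attach_B=("m", [0, 0, 0]))
        m = Model([gnd, mass], [sp], guidance={"gnd": IDENTITY_GUIDE})
        tr = simulate(m, (0.0, 2.0), SimConfig(h=1e-3))
        E = []
        for k in range(len(tr.t)):
            v = tr.vels["m"][k][:3]
            r = tr.poses["m"][k][:3]
            L = np.linalg.norm(r)
            E.append(0.5 * 0.5 * v @ v + 0.5 * 200 * (L - 0.25) ** 2
                     + 0.5 * G * r[2])
        E = np.asarray(E)
        assert np.abs(E - E[0]).max() / abs(E[0]) < 1e-3

    def test_null_dynamics_stays_at_rest(self):
        b = RigidBody("p", 0.03, np.eye(3) * 1e-6, r=[0.01, 0.02, 0.03])
        m = assemble([b], gravity=(0, 0, 0))
        tr = simulate(m, (0.0, 0.3), SimConfig(h=1e-3))
        assert np.abs(tr.body_r("p") - tr.body_r("p")[0]).max() < 1e-12

    def test_bitwise_determinism(self):
        m1 = pendulum_model()
        m2 = pendulum_model()
        tr1 = simulate(m1, (0.0, 0.5), SimConfig(h=1e-3))
        tr2 = simulate(m2, (0.0, 0.5), SimConfig(h=1e-3))
        assert np.array_equal(tr1.body_r("p"), tr2.body_r("p"))
        assert np.array_equal(tr1.body_e("p"), tr2.body_e("p"))


class TestStaticEquilibrium:
    def test_hanging_mass_elongation(self):
        gnd = RigidBody("gnd", 1.0, np.eye(3) * 1e-3, guided=True)
        mass = RigidBody("m", 1.0, np.eye(3) * 1e-4, r=[0, 0, -0.5])
        sp = SpringDamperParams(K=100.0, L0=0.4,
                                attach_A=("gnd", [0, 0, 0]),
                                attach_B=("m", [0, 0, 0]))
        m = Model([gnd, mass], [sp], guidance={"gnd": IDENTITY_GUIDE})
        res = static_equilibrium(m)
        assert res.converged
        z = res.state.q[m.r_slice("m")][2]
        assert -z - 0.4 == pytest.approx(1.0 * G / 100.0, abs=1e-8)

    def test_flores_resting_depth_closed_form(self):
        fem = RigidBody("fem", 1.0, np.eye(3) * 1e-3, guided=True)
        pat = RigidBody("pat", 0.03, np.eye(3) * 2.7e-6, r=[0, 0, 0.0149])
        be = AnalyticContactBackend(plane_surface(), SpherePrimitive(radius=0.015))
        cp = ContactPair("fem", "pat", be, FloresParams(k_n=1e7, p=1.5, eps=0.9))
        m = Model([fem, pat], [], [cp], guidance={"fem": IDENTITY_GUIDE})
        res = static_equilibrium(m, require_contact=True)
        assert res.converged and res.contacting
        delta = 0.015 - res.state.q[m.r_slice("pat")][2]
        assert delta == pytest.approx((0.03 * G / 1e7) ** (2 / 3), rel=1e-6)

    def test_separated_scene_flags_no_contacting_equilibrium(self):
        fem = RigidBody("fem", 1.0, np.eye(3) * 1e-3, guided=True)
        # spring holds the sphere well above the plane
        pat = RigidBody("pat", 0.03, np.eye(3) * 2.7e-6, r=[0, 0, 0.1])
        be = AnalyticContactBackend(plane_surface(), SpherePrimitive(radius=0.015))
        cp = ContactPair("fem", "pat", be, FloresParams())
        sp = SpringDamperParams(K=50.0, L0=0.1,
                                attach_A=("fem", [0, 0, 0.2]),
                                attach_B=("pat", [0, 0, 0]))
        m = Model([fem, pat], [sp], [cp], guidance={"fem": IDENTITY_GUIDE})
        res = static_equilibrium(m, require_contact=True)
        assert not res.contacting or not res.converged
        if not res.converged:
            assert res.message


class TestBenchEquilibrium:
    @pytest.fixture(scope="class")
    def equilibrated(self):
        from pftwin.bench import ScenarioConfig, prepare_run
        cfg = ScenarioConfig()
        model, state, truth, _ = prepare_run(cfg)
        return cfg, model, state, truth

    def test_converges_from_recorded_patella_pose(self, equilibrated):
        cfg, model, state, truth = equilibrated
        Q, _, patches = model.applied_forces(state.q, np.zeros_like(state.q), 0.0)
        assert np.abs(Q[model.free_idx]).max() < 1e-6
        assert any(p.delta > 0 for p in patches)

    def test_restart_drift_below_tenth_of_mm(self, equilibrated):
        from pftwin.bench import build_model
        cfg, model, state, truth = equilibrated
        frozen = {k: FrozenGuidance(v, 0.0) for k, v in model.guidance.items()}
        m2 = build_model(cfg, frozen)
        tr = simulate(m2, (0.0, 1.0), SimConfig(h=1e-3), state=state.copy())
        drift = np.linalg.norm(tr.body_r("patella")[-1] - tr.body_r("patella")[0])
        assert drift < 1e-4
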