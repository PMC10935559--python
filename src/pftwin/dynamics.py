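"""Constrained rigid-body dynamics.

The mechanical model is a small set of rigid bodies in Euler-parameter
coordinates (7 per body: position + unit quaternion).  Constraints
(quaternion normalization, the spherical hip joint) are enforced with an
augmented-Lagrangian index-3 scheme: the Newmark-discretized equations of
motion are iterated with penalized constraint forces and multiplier
updates until the position-level residual meets tolerance, after which
velocities and accelerations are projected onto the constraint subspace.
Bodies whose motion is measured (femur, tibia) are *guided*: their
coordinates are rheonomic prescriptions and are eliminated from the
unknowns, so the guided bench leaves only the patella's coordinates free.

Default integrator settings follow standard practice for this
formulation: Newmark average acceleration (gamma = 1/2, beta = 1/4,
unconditionally stable, second order), a 1 ms step for the analytic
contact backend and 0.1 ms (0.05 ms for the most demanding case) for the
mesh backend.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError, ConvergenceError
from .forces import FloresParams, SpringDamperParams, flores_magnitude
from .quat import dAs_de, gmat, rotmat

__all__ = [
    "RigidBody", "SimConfig", "SystemState", "Model", "ContactPair",
    "UnitQuaternion", "SphericalJoint", "CallableGuidance", "FrozenGuidance",
    "assemble", "step", "simulate", "static_equilibrium", "Trajectory",
    "StaticEquilibriumResult",
]



def _cr(a, b):
    """3-vector cross product without numpy.cross overhead."""
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])

# --------------------------------------------------------------------------
# Bodies, guidance, constraints
# --------------------------------------------------------------------------

@dataclass
class RigidBody:
    """Rigid body with mass properties and an initial pose/twist.

    ``inertia`` is the body-frame inertia tensor about the body origin
    (which is also taken as the center of mass).
    """

    name: str
    mass: float
    inertia: np.ndarray
    r: np.ndarray = None
    e: np.ndarray = None            # unit quaternion, scalar first
    v: np.ndarray = None            # linear velocity, world
    omega: np.ndarray = None        # angular velocity, body frame
    guided: bool = False

    def __post_init__(self):
        if self.mass <= 0:
            raise ConfigError(f"body {self.name}: mass must be > 0")
        self.inertia = np.asarray(self.inertia, float)
        if self.inertia.shape == (3,):
            self.inertia = np.diag(self.inertia)
        if not np.allclose(self.inertia, self.inertia.T, atol=1e-12):
            raise ConfigError(f"body {self.name}: inertia must be symmetric")
        if np.any(np.linalg.eigvalsh(self.inertia) <= 0):
            raise ConfigError(f"body {self.name}: inertia must be positive definite")
        self.r = np.zeros(3) if self.r is None else np.asarray(self.r, float)
        if self.e is None:
            self.e = np.array([1.0, 0.0, 0.0, 0.0])
        else:
            self.e = np.asarray(self.e, float)
            self.e = self.e / np.linalg.norm(self.e)
        self.v = np.zeros(3) if self.v is None else np.asarray(self.v, float)
        self.omega = np.zeros(3) if self.omega is None else np.asarray(self.omega, float)


class CallableGuidance:
    """Rheonomic pose prescription from a callable ``t -> (r, e)``.

    Velocities and accelerations are central finite differences of the
    prescription unless explicit callables are supplied.
    """

    def __init__(self, pose_fn: Callable, vel_fn: Optional[Callable] = None,
                 acc_fn: Optional[Callable] = None, h_fd: float = 1e-6):
        self._pose = pose_fn
        self._vel = vel_fn
        self._acc = acc_fn
        self._h = h_fd

    def pose(self, t: float):
        r, e = self._pose(t)
        return np.asarray(r, float), np.asarray(e, float)

    def velocity(self, t: float):
        if self._vel is not None:
            rd, ed = self._vel(t)
            return np.asarray(rd, float), np.asarray(ed, float)
        h = self._h
        (r1, e1), (r0, e0) = self.pose(t + h), self.pose(t - h)
        if e1 @ e0 < 0:
            e0 = -e0
        return (r1 - r0) / (2 * h), (e1 - e0) / (2 * h)

    def acceleration(self, t: float):
        if self._acc is not None:
            rdd, edd = self._acc(t)
            return np.asarray(rdd, float), np.asarray(edd, float)
        h = self._h
        (r1, e1), (rm, em), (r0, e0) = (self.pose(t + h), self.pose(t),
                                        self.pose(t - h))
        for eo in (e1, e0):
            if eo @ em < 0:
                eo *= -1
        return (r1 - 2 * rm + r0) / h ** 2, (e1 - 2 * em + e0) / h ** 2


class FrozenGuidance:
    """Guidance pinned at a fixed time (used for equilibrium-drift checks)."""

    def __init__(self, inner, t0: float):
        self._inner = inner
        self._t0 = float(t0)

    def pose(self, t):
        return self._inner.pose(self._t0)

    def velocity(self, t):
        r, e = self._inner.pose(self._t0)
        return np.zeros(3), np.zeros(4)

    def acceleration(self, t):
        return np.zeros(3), np.zeros(4)


class UnitQuaternion:
    """e . e = 1 for one body."""

    rows = 1

    def __init__(self, body: str):
        self.body = body

    def phi(self, model, q, t):
        e = model.body_e(q, self.body)
        return np.array([e @ e - 1.0])

    def jac(self, model, q, t):
        J = np.zeros((1, model.n_coords))
        sl = model.e_slice(self.body)
        J[0, sl] = 2.0 * model.body_e(q, self.body)
        return J

    def phi_t(self, model, q, t):
        return np.zeros(1)


class SphericalJoint:
    """Body-fixed point coincides with a (possibly moving) world point."""

    rows = 3

    def __init__(self, body: str, local_point, world_point=(0.0, 0.0, 0.0),
                 world_point_fn: Optional[Callable] = None):
        self.body = body
        self.local_point = np.asarray(local_point, float)
        self.world_point = np.asarray(world_point, float)
        self.world_point_fn = world_point_fn

    def _target(self, t):
        if self.world_point_fn is not None:
            return np.asarray(self.world_point_fn(t), float)
        return self.world_point

    def phi(self, model, q, t):
        r = model.body_r(q, self.body)
        e = model.body_e(q, self.body)
        return r + rotmat(e) @ self.local_point - self._target(t)

    def jac(self, model, q, t):
        J = np.zeros((3, model.n_coords))
        J[:, model.r_slice(self.body)] = np.eye(3)
        J[:, model.e_slice(self.body)] = dAs_de(model.body_e(q, self.body),
                                                self.local_point)
        return J

    def phi_t(self, model, q, t):
        if self.world_point_fn is None:
            return np.zeros(3)
        h = 1e-6
        return -(self._target(t + h) - self._target(t - h)) / (2 * h)


@dataclass
class ContactPair:
    """A contact interaction between two bodies via a collision backend."""

    body_surface: str      # the body carrying the surface / mesh A (femur)
    body_sphere: str       # the body carrying the button (patella)
    backend: object        # AnalyticContactBackend or MeshContactBackend
    flores: FloresParams = field(default_factory=FloresParams)


# --------------------------------------------------------------------------
# Model
# --------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Integrator and solver settings."""

    h: float = 1e-3
    newmark_gamma: float = 0.5
    newmark_beta: float = 0.25
    alpha: Optional[float] = None     # AL penalty; default 1e7 * leading mass
    max_iter: int = 60
    jac_refresh: int = 5              # steps between FD force-Jacobian rebuilds
    contact_mode: str = "iteration"   # "iteration" | "per_step" (linearized)
    pos_tol: float = 1e-9
    vel_tol: float = 1e-9
    dq_tol: float = 1e-11
    force_tol: float = 1e-8
    backend: str = "analytic:5"
    seed: int = 0

    def __post_init__(self):
        if self.h <= 0:
            raise ConfigError("time step must be > 0")
        if self.newmark_gamma == 0.5 and not (0.25 <= self.newmark_beta <= 0.5):
            raise ConfigError("beta must lie in [1/4, 1/2] for gamma = 1/2")
        if self.alpha is not None and self.alpha <= 0:
            raise ConfigError("penalty alpha must be > 0")


@dataclass
class SystemState:
    """Generalized coordinates/velocities/accelerations of the full system
    (guided coordinates included) plus multiplier estimates and residuals."""

    t: float
    q: np.ndarray
    qd: np.ndarray
    qdd: np.ndarray
    lam: np.ndarray
    max_phi: float = 0.0
    max_vel_res: float = 0.0
    patches: list = field(default_factory=list)
    spring_tensions: np.ndarray = None

    def copy(self) -> "SystemState":
        return SystemState(self.t, self.q.copy(), self.qd.copy(),
                           self.qdd.copy(), self.lam.copy(),
                           self.max_phi, self.max_vel_res,
                           list(self.patches),
                           None if self.spring_tensions is None
                           else self.spring_tensions.copy())


class Model:
    """Assembled multibody model (bodies, springs, contacts, constraints,
    guidance).  Coordinate layout: 7 per body, in body order."""

    def __init__(self, bodies: Sequence[RigidBody],
                 springs: Sequence[SpringDamperParams] = (),
                 contacts: Sequence[ContactPair] = (),
                 constraints: Sequence = (),
                 guidance: Optional[Dict[str, object]] = None,
                 gravity=(0.0, 0.0, -9.81)):
        names = [b.name for b in bodies]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate body ids")
        self.bodies = list(bodies)
        self.index = {b.name: i for i, b in enumerate(self.bodies)}
        self.springs = list(springs)
        self.contacts = list(contacts)
        self.guidance = dict(guidance or {})
        self.gravity = np.asarray(gravity, float)
        for b in self.bodies:
            if b.guided and b.name not in self.guidance:
                raise ConfigError(f"guided body '{b.name}' has no guidance")
        for s in self.springs:
            for bid, _ in (s.attach_A, s.attach_B):
                if bid not in self.index:
                    raise ConfigError(f"spring attached to unknown body '{bid}'")
        self.constraints = list(constraints)
        # every free body carries a quaternion-normalization constraint
        for b in self.bodies:
            if not b.guided:
                self.constraints.append(UnitQuaternion(b.name))
        self.free_idx = np.concatenate([
            np.arange(7 * i, 7 * i + 7)
            for i, b in enumerate(self.bodies) if not b.guided
        ]) if any(not b.guided for b in self.bodies) else np.empty(0, np.int64)

    # ---- coordinate helpers ----------------------------------------------

    @property
    def n_coords(self) -> int:
        return 7 * len(self.bodies)

    @property
    def n_constraints(self) -> int:
        return sum(c.rows for c in self.constraints)

    def r_slice(self, name: str) -> slice:
        i = self.index[name]
        return slice(7 * i, 7 * i + 3)

    def e_slice(self, name: str) -> slice:
        i = self.index[name]
        return slice(7 * i + 3, 7 * i + 7)

    def body_r(self, q, name):
        return q[self.r_slice(name)]

    def body_e(self, q, name):
        return q[self.e_slice(name)]

    def body_pose(self, q, name):
        return rotmat(self.body_e(q, name)), self.body_r(q, name)

    def body_vel(self, q, qd, name):
        """(linear velocity, world angular velocity)."""
        e = self.body_e(q, name)
        ed = qd[self.e_slice(name)]
        A = rotmat(e)
        return qd[self.r_slice(name)], A @ (2.0 * gmat(e) @ ed)

    @property
    def dof(self) -> int:
        """Net unknowns: 6 per free body minus non-normalization constraint
        rows that act on free bodies."""
        free = {b.name for b in self.bodies if not b.guided}
        n = 6 * len(free)
        for c in self.constraints:
            if isinstance(c, UnitQuaternion):
                continue
            if getattr(c, "body", None) in free:
                n -= c.rows
        return n

    # ---- state construction ----------------------------------------------

    def initial_state(self, t0: float = 0.0) -> SystemState:
        q = np.zeros(self.n_coords)
        qd = np.zeros(self.n_coords)
        for i, b in enumerate(self.bodies):
            q[7 * i:7 * i + 3] = b.r
            q[7 * i + 3:7 * i + 7] = b.e
            qd[7 * i:7 * i + 3] = b.v
            qd[7 * i + 3:7 * i + 7] = 0.5 * gmat(b.e).T @ b.omega
        st = SystemState(t0, q, qd, np.zeros(self.n_coords),
                         np.zeros(self.n_constraints))
        self.apply_guidance(st, t0)
        return st

    def apply_guidance(self, state: SystemState, t: float) -> None:
        for i, b in enumerate(self.bodies):
            if not b.guided:
                continue
            g = self.guidance[b.name]
            r, e = g.pose(t)
            rd, ed = g.velocity(t)
            rdd, edd = g.acceleration(t)
            state.q[7 * i:7 * i + 3] = r
            state.q[7 * i + 3:7 * i + 7] = e
            state.qd[7 * i:7 * i + 3] = rd
            state.qd[7 * i + 3:7 * i + 7] = ed
            state.qdd[7 * i:7 * i + 3] = rdd
            state.qdd[7 * i + 3:7 * i + 7] = edd

    # ---- constraint stack -------------------------------------------------

    def phi(self, q, t):
        if not self.constraints:
            return np.zeros(0)
        return np.concatenate([c.phi(self, q, t) for c in self.constraints])

    def phi_q(self, q, t):
        if not self.constraints:
            return np.zeros((0, self.n_coords))
        return np.vstack([c.jac(self, q, t) for c in self.constraints])

    def phi_t(self, q, t):
        if not self.constraints:
            return np.zeros(0)
        return np.concatenate([c.phi_t(self, q, t) for c in self.constraints])

    def vel_residual(self, q, qd, t):
        return self.phi_q(q, t) @ qd + self.phi_t(q, t)

    # ---- inertia ----------------------------------------------------------

    def mass_matrix(self, q) -> np.ndarray:
        M = np.zeros((self.n_coords, self.n_coords))
        for i, b in enumerate(self.bodies):
            M[7 * i:7 * i + 3, 7 * i:7 * i + 3] = b.mass * np.eye(3)
            G = gmat(q[7 * i + 3:7 * i + 7])
            M[7 * i + 3:7 * i + 7, 7 * i + 3:7 * i + 7] = 4.0 * G.T @ b.inertia @ G
        return M

    def quadratic_velocity(self, q, qd) -> np.ndarray:
        """Velocity-dependent inertia terms (quaternion blocks)."""
        c = np.zeros(self.n_coords)
        for i, b in enumerate(self.bodies):
            e = q[7 * i + 3:7 * i + 7]
            ed = qd[7 * i + 3:7 * i + 7]
            G = gmat(e)
            Gd = gmat(ed)
            c[7 * i + 3:7 * i + 7] = (4.0 * G.T @ b.inertia @ (Gd @ ed)
                                      + 8.0 * Gd.T @ b.inertia @ (G @ ed))
        return c

    # ---- applied forces ---------------------------------------------------

    def _apply_point_force(self, Q, q, name, point_world, F, kin=None):
        i = self.index[name]
        Q[7 * i:7 * i + 3] += F
        if kin is None:
            e = q[7 * i + 3:7 * i + 7]
            A, G = rotmat(e), gmat(e)
            r = q[7 * i:7 * i + 3]
        else:
            A, G, r = kin[i][0], kin[i][1], kin[i][2]
        torque_w = _cr(point_world - r, F)
        Q[7 * i + 3:7 * i + 7] += 2.0 * G.T @ (A.T @ torque_w)

    def _kin_cache(self, q, qd):
        """Per-body (A, G, r, v, omega_body) cache for one force evaluation."""
        cache = {}
        for i, b in enumerate(self.bodies):
            e = q[7 * i + 3:7 * i + 7]
            G = gmat(e)
            cache[i] = (rotmat(e), G, q[7 * i:7 * i + 3],
                        qd[7 * i:7 * i + 3],
                        2.0 * G @ qd[7 * i + 3:7 * i + 7])
        return cache

    def point_velocity(self, name, point_world, kin):
        """World velocity of a body-fixed point given a kinematics cache."""
        A, G, r, v0, wbody = kin[self.index[name]]
        return v0 + A @ _cr(wbody, A.T @ (point_world - r))

    def spring_state(self, q, qd, s: SpringDamperParams, kin=None):
        """(L, Ldot, unit vector A->B, world points a, b)."""
        if kin is None:
            kin = self._kin_cache(q, qd)
        (na, pa), (nb, pb) = s.attach_A, s.attach_B
        Aa, _, ra, va0, wa = kin[self.index[na]]
        Ab, _, rb, vb0, wb = kin[self.index[nb]]
        a = ra + Aa @ pa
        b = rb + Ab @ pb
        d = b - a
        L = float(np.sqrt(d @ d))
        u = d / L if L > 0 else np.zeros(3)
        va = va0 + Aa @ _cr(wa, pa)
        vb = vb0 + Ab @ _cr(wb, pb)
        Ldot = float(u @ (vb - va))
        return L, Ldot, u, a, b

    def detect_contacts(self, q, qd, t):
        """Fresh contact detection (episodes peeked, not committed), with
        the sphere-body reference position recorded per patch so the
        per-step linearized mode can update the indentation in place."""
        out = []
        for cp in self.contacts:
            pf = self.body_pose(q, cp.body_surface)
            pp = self.body_pose(q, cp.body_sphere)
            vf = self.body_vel(q, qd, cp.body_surface)
            vp = self.body_vel(q, qd, cp.body_sphere)
            ps = cp.backend.contacts((pf[0], pf[1]), (pp[0], pp[1]),
                                     vel_femur=vf, vel_patella=vp,
                                     t=t, track_episodes=False)
            ps = _peek_delta_dot0(cp.backend, ps)
            for p in ps:
                p._pair = cp
                p._r_ref = q[self.r_slice(cp.body_sphere)].copy()
                p._delta_ref = p.delta
            out.extend(ps)
        return out

    def applied_forces(self, q, qd, t, include_contact=True,
                       peek_episodes=True, frozen_contact=None):
        """Generalized applied forces.

        Returns (Q, spring_tensions, patches).  ``peek_episodes`` evaluates
        contact with episode state read-only (used inside Newton loops);
        the caller commits episodes once per accepted step.
        ``frozen_contact`` reuses previously detected patches, updating
        indentation to first order along the frozen normal (one geometric
        detection per step — the mesh backend's default economy).
        """
        from .forces import spring_damper_force
        Q = np.zeros(self.n_coords)
        for i, b in enumerate(self.bodies):
            Q[7 * i:7 * i + 3] += b.mass * self.gravity

        kin = self._kin_cache(q, qd)
        tensions = np.zeros(len(self.springs))
        for k, s in enumerate(self.springs):
            L, Ldot, u, a, b = self.spring_state(q, qd, s, kin)
            f = spring_damper_force(s, L, Ldot)
            tensions[k] = f
            self._apply_point_force(Q, q, s.attach_A[0], a, f * u, kin)
            self._apply_point_force(Q, q, s.attach_B[0], b, -f * u, kin)

        patches = []
        if include_contact and frozen_contact is not None:
            for p in frozen_contact:
                cp = p._pair
                r_now = q[self.r_slice(cp.body_sphere)]
                delta = p._delta_ref - float(p.normal @ (r_now - p._r_ref))
                p.delta = max(delta, 0.0)
                vf = self.point_velocity(cp.body_surface, p.point, kin)
                vp = self.point_velocity(cp.body_sphere, p.point, kin)
                p.delta_dot = float(p.normal @ (vf - vp))
                mag = flores_magnitude(cp.flores, p.delta, p.delta_dot,
                                       p.delta_dot0)
                p.force = mag
                if mag > 0.0:
                    F = mag * p.normal
                    self._apply_point_force(Q, q, cp.body_sphere, p.point, F, kin)
                    self._apply_point_force(Q, q, cp.body_surface, p.point, -F, kin)
                if p.delta > 0.0:
                    patches.append(p)
            return Q, tensions, patches
        if include_contact:
            for cp in self.contacts:
                pf = self.body_pose(q, cp.body_surface)
                pp = self.body_pose(q, cp.body_sphere)
                vf = self.body_vel(q, qd, cp.body_surface)
                vp = self.body_vel(q, qd, cp.body_sphere)
                ps = cp.backend.contacts((pf[0], pf[1]), (pp[0], pp[1]),
                                         vel_femur=vf, vel_patella=vp,
                                         t=t, track_episodes=False)
                ps = _peek_delta_dot0(cp.backend, ps)
                for patch in ps:
                    mag = flores_magnitude(cp.flores, patch.delta,
                                           patch.delta_dot, patch.delta_dot0)
                    F = mag * patch.normal
                    self._apply_point_force(Q, q, cp.body_sphere, patch.point, F, kin)
                    self._apply_point_force(Q, q, cp.body_surface, patch.point, -F, kin)
                    patch.force = mag
                patches.extend(ps)
        return Q, tensions, patches

    def commit_episodes(self, patches, t):
        for cp in self.contacts:
            mine = [p for p in patches]   # single pair in all bench models
            cp.backend.episodes.update(mine, t)

    # ---- energy (diagnostics / tests) -------------------------------------

    def mechanical_energy(self, state: SystemState,
                          include_contact: bool = True) -> float:
        """Kinetic + gravitational + spring elastic (+ contact elastic for
        Hertzian patches).  Spring damping/dissipation not included."""
        q, qd = state.q, state.qd
        E = 0.0
        for i, b in enumerate(self.bodies):
            v = qd[7 * i:7 * i + 3]
            e = q[7 * i + 3:7 * i + 7]
            w = 2.0 * gmat(e) @ qd[7 * i + 3:7 * i + 7]
            E += 0.5 * b.mass * v @ v + 0.5 * w @ b.inertia @ w
            E -= b.mass * self.gravity @ q[7 * i:7 * i + 3]
        for s in self.springs:
            L, _, _, _, _ = self.spring_state(q, qd, s)
            E += 0.5 * s.K * (L - s.L0) ** 2
        if include_contact:
            for cp in self.contacts:
                for p in state.patches:
                    E += (cp.flores.k_n * p.delta ** (cp.flores.p + 1)
                          / (cp.flores.p + 1))
        return float(E)


def _peek_delta_dot0(backend, patches):
    """Fill delta_dot0 from open episodes without mutating tracker state."""
    open_eps = backend.episodes.open_episodes
    for p in patches:
        best, best_d = None, backend.episodes.match_radius
        for ep in open_eps:
            d = float(np.linalg.norm(ep.point - p.point))
            if d < best_d:
                best, best_d = ep, d
        if best is not None:
            p.delta_dot0 = best.delta_dot0
            p.episode_id = best.eid
        else:
            p.delta_dot0 = p.delta_dot if p.delta_dot > 1e-3 else None
    return patches


def assemble(bodies, springs=(), contacts=(), constraints=(), guidance=None,
             gravity=(0.0, 0.0, -9.81)) -> Model:
    """Build a :class:`Model`, validating ids and guidance coverage."""
    return Model(bodies, springs, contacts, constraints, guidance, gravity)


# --------------------------------------------------------------------------
# Integrator
# --------------------------------------------------------------------------

def _alpha_for(model: Model, config: SimConfig) -> float:
    if config.alpha is not None:
        return config.alpha
    m = max(b.mass for b in model.bodies)
    # keep the penalty comparable to the Newmark leading term so multiplier
    # updates converge at the same rate for any step size
    return max(1e7 * m, 10.0 * m / (config.newmark_beta * config.h ** 2))


def _force_jacobians_fd(model, q, qd, t, free, eps_q=1e-8, eps_v=1e-6):
    """FD Jacobians of the smooth (non-contact) generalized forces minus the
    quadratic-velocity inertia term, w.r.t. free coordinates/velocities."""
    def f(qq, qqd):
        Q, _, _ = model.applied_forces(qq, qqd, t, include_contact=False)
        return Q[free] - model.quadratic_velocity(qq, qqd)[free]

    base = f(q, qd)
    n = len(free)
    Kq = np.zeros((n, n))
    Cv = np.zeros((n, n))
    for j, idx in enumerate(free):
        qp = q.copy(); qp[idx] += eps_q
        Kq[:, j] = (f(qp, qd) - base) / eps_q
        vp = qd.copy(); vp[idx] += eps_v
        Cv[:, j] = (f(q, vp) - base) / eps_v
    return Kq, Cv, base


def _contact_jacobian(model, q, patches, free):
    """Analytic approximation of the contact stiffness/damping blocks:
    the normal force acts along the (sphere-center-directed) patch normal,
    so the dominant term is k_c n n^T on the sphere body's translation."""
    n = len(free)
    K = np.zeros((n, n))
    C = np.zeros((n, n))
    pos_of = {idx: j for j, idx in enumerate(free)}
    for cp in model.contacts:
        i = model.index[cp.body_sphere]
        cols = [pos_of.get(7 * i + k) for k in range(3)]
        if any(c is None for c in cols):
            continue
        cols = np.asarray(cols)
        for p in patches:
            if p.delta <= 0:
                continue
            fl = cp.flores
            dd0 = p.delta_dot0 if (p.delta_dot0 and p.delta_dot0 > 0) else None
            bracket = 1.0
            if dd0:
                bracket += fl.dissipation_factor * p.delta_dot / dd0
            k_c = fl.k_n * fl.p * p.delta ** (fl.p - 1.0) * max(bracket, 0.0)
            nnT = np.outer(p.normal, p.normal)
            K[np.ix_(cols, cols)] += k_c * nnT
            if dd0:
                c_c = fl.k_n * p.delta ** fl.p * fl.dissipation_factor / dd0
                C[np.ix_(cols, cols)] += max(c_c, 0.0) * nnT
    return K, C


def step(model: Model, state: SystemState, config: SimConfig) -> SystemState:
    """Advance one Newmark/augmented-Lagrangian step of size ``config.h``."""
    h = config.h
    beta, gamma = config.newmark_beta, config.newmark_gamma
    alpha = _alpha_for(model, config)
    free = model.free_idx
    t1 = state.t + h

    new = state.copy()
    new.t = t1
    model.apply_guidance(new, t1)

    if not len(free):
        # everything prescribed: record forces/diagnostics and return
        Q, tensions, patches = model.applied_forces(new.q, new.qd, t1)
        model.commit_episodes(patches, t1)
        new.patches = patches
        new.spring_tensions = tensions
        Phi = model.phi(new.q, t1)
        new.max_phi = float(np.max(np.abs(Phi))) if len(Phi) else 0.0
        new.max_vel_res = 0.0   # no projectable rows without free coordinates
        return new

    q0, qd0, qdd0 = state.q, state.qd, state.qdd
    q = new.q
    q[free] = (q0 + h * qd0 + 0.5 * h * h * qdd0)[free]
    lam = new.lam

    inv_bh2 = 1.0 / (beta * h * h)
    gam_bh = gamma / (beta * h)

    def kinematics(qv):
        qdd = new.qdd.copy()
        qd = new.qd.copy()
        qdd[free] = ((qv - q0 - h * qd0)[free] * inv_bh2
                     - (0.5 / beta - 1.0) * qdd0[free])
        qd[free] = (qd0 + h * ((1.0 - gamma) * qdd0))[free] + h * gamma * qdd[free]
        return qd, qdd

    cache = getattr(model, "_jac_cache", None)
    refresh = (cache is None or cache[0] + config.jac_refresh * h <= t1
               or cache[1].shape[0] != len(free))
    Kq = Cv = None if refresh else None
    if not refresh:
        Kq, Cv = cache[1], cache[2]
    converged = False
    last = {}
    frozen = None
    for it in range(config.max_iter):
        qd, qdd = kinematics(q)
        if config.contact_mode == "per_step":
            if frozen is None:
                frozen = model.detect_contacts(q, qd, t1)
            Q, tensions, patches = model.applied_forces(q, qd, t1,
                                                        frozen_contact=frozen)
        else:
            Q, tensions, patches = model.applied_forces(q, qd, t1)
        Phi = model.phi(q, t1)
        Jphi = model.phi_q(q, t1)
        M = model.mass_matrix(q)
        cvel = model.quadratic_velocity(q, qd)
        R_full = M @ qdd + cvel + Jphi.T @ (alpha * Phi + lam) - Q
        R = R_full[free]

        if Kq is None:
            Kq, Cv, _ = _force_jacobians_fd(model, q, qd, t1, free)
            model._jac_cache = (t1, Kq, Cv)
        Kc, Cc = _contact_jacobian(model, q, patches, free)
        A = Jphi[:, free]
        J = (M[np.ix_(free, free)] * inv_bh2
             + alpha * (A.T @ A)
             + (Kc - Kq)
             + gam_bh * (Cc - Cv))

        try:
            dq = np.linalg.solve(J, -R)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular iteration matrix at t={t1}") from exc
        if not np.all(np.isfinite(dq)):
            raise ConvergenceError(f"non-finite Newton update at t={t1}")
        # clamp runaway updates (stiff contact transients)
        nmax = float(np.max(np.abs(dq)))
        if nmax > 0.02:
            dq *= 0.02 / nmax
        q[free] += dq
        Phi = model.phi(q, t1)
        lam += alpha * Phi
        last = {"it": it, "dq": float(np.max(np.abs(dq))),
                "phi": float(np.max(np.abs(Phi)) if len(Phi) else 0.0)}
        scale = max(1.0, float(np.max(np.abs(q[free]))))
        if last["dq"] < config.dq_tol * scale and last["phi"] <= config.pos_tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"Newmark/AL step failed at t={t1:.6f}: {last}; "
            f"consider a smaller time step", history=[last])

    qd, qdd = kinematics(q)
    new.q, new.qd, new.qdd, new.lam = q, qd, qdd, lam

    # velocity projection onto the constraint subspace.  Only rows that
    # touch free coordinates are projectable; rows acting purely on guided
    # bodies carry the (tiny) interpolation inconsistency of the pose
    # splines and are excluded from the projected residual.
    Jphi = model.phi_q(q, t1)
    phit = model.phi_t(q, t1)
    A = Jphi[:, free]
    proj_rows = np.any(A != 0.0, axis=1)
    M = model.mass_matrix(q)
    Mf = M[np.ix_(free, free)]
    S = Mf + alpha * (A.T @ A)
    res_v = Jphi @ new.qd + phit if model.n_constraints else np.zeros(0)
    for _ in range(4):
        if len(res_v) == 0 or np.max(np.abs(res_v[proj_rows]),
                                     initial=0.0) <= config.vel_tol:
            break
        new.qd[free] -= np.linalg.solve(S, A.T @ (alpha * res_v))
        res_v = Jphi @ new.qd + phit

    # acceleration projection (FD of the velocity residual along the motion)
    if model.n_constraints:
        epsm = 1e-7
        psi0 = Jphi @ new.qd + phit
        psi1 = model.vel_residual(q + epsm * new.qd, new.qd, t1 + epsm)
        rhs = (psi1 - psi0) / epsm       # Phidot_q qd + Phidot_t
        for _ in range(4):
            res_a = Jphi @ new.qdd + rhs
            if np.max(np.abs(res_a[proj_rows]), initial=0.0) <= config.vel_tol * 10:
                break
            new.qdd[free] -= np.linalg.solve(S, A.T @ (alpha * res_a))
        res_v = Jphi @ new.qd + phit

    # commit contact episodes and record diagnostics at the accepted state.
    # The geometry is unchanged since the last Newton iterate (projections
    # touch velocities only), so refresh rates/forces in place.
    kin = model._kin_cache(q, new.qd)
    tensions = np.empty(len(model.springs))
    for k2, s2 in enumerate(model.springs):
        L2, Ld2, _, _, _ = model.spring_state(q, new.qd, s2, kin)
        from .forces import spring_damper_force
        tensions[k2] = spring_damper_force(s2, L2, Ld2)
    for cp in model.contacts:
        for p in patches:
            vf = model.point_velocity(cp.body_surface, p.point, kin)
            vp = model.point_velocity(cp.body_sphere, p.point, kin)
            p.delta_dot = float(p.normal @ (vf - vp))
            p.force = flores_magnitude(cp.flores, p.delta, p.delta_dot,
                                       p.delta_dot0)
    model.commit_episodes(patches, t1)
    new.patches = patches
    new.spring_tensions = tensions
    new.max_phi = float(np.max(np.abs(model.phi(q, t1))) if model.n_constraints else 0.0)
    new.max_vel_res = float(np.max(np.abs(res_v[proj_rows]), initial=0.0)
                            if len(res_v) else 0.0)
    return new


def initialize_accelerations(model: Model, state: SystemState,
                             config: SimConfig) -> None:
    """Solve the EOM at the current state for consistent free accelerations
    (Newmark needs qdd at t0; starting from zero biases the first step)."""
    free = model.free_idx
    if not len(free):
        return
    t = state.t
    q, qd = state.q, state.qd
    alpha = _alpha_for(model, config)
    Q, _, _ = model.applied_forces(q, qd, t)
    cvel = model.quadratic_velocity(q, qd)
    M = model.mass_matrix(q)
    Jphi = model.phi_q(q, t)
    A = Jphi[:, free]
    S = M[np.ix_(free, free)] + alpha * (A.T @ A)
    epsm = 1e-7
    psi0 = model.vel_residual(q, qd, t)
    psi1 = model.vel_residual(q + epsm * qd, qd, t + epsm)
    rhs = (psi1 - psi0) / epsm
    guided_acc = Jphi @ state.qdd - A @ state.qdd[free]   # guided contribution
    b = (Q - cvel)[free] - A.T @ (alpha * (rhs + guided_acc))
    state.qdd[free] = np.linalg.solve(S, b)


# --------------------------------------------------------------------------
# Static equilibrium
# --------------------------------------------------------------------------

@dataclass
class StaticEquilibriumResult:
    state: SystemState
    converged: bool
    contacting: bool
    residual_history: List[float]
    message: str = ""


def static_equilibrium(model: Model, state: Optional[SystemState] = None,
                       config: Optional[SimConfig] = None, t0: float = 0.0,
                       require_contact: bool = False,
                       max_iter: int = 200) -> StaticEquilibriumResult:
    """Newton-Raphson search for a zero-velocity equilibrium of the free
    bodies (springs + contact + gravity + constraint reactions).

    The initial guess should approximate the measured pose of the free
    body.  Damped Newton on the augmented residual; the result's
    ``contacting`` flag reports whether any contact remains closed (a
    separated result with ``require_contact`` fails with
    "no contacting equilibrium found").
    """
    config = config or SimConfig()
    alpha = _alpha_for(model, config)
    if state is None:
        state = model.initial_state(t0)
    st = state.copy()
    model.apply_guidance(st, t0)
    st.qd[:] = 0.0
    st.qdd[:] = 0.0
    free = model.free_idx
    q = st.q
    lam = np.zeros(model.n_constraints)
    hist: List[float] = []

    def residual(qv):
        Q, _, patches = model.applied_forces(qv, st.qd, t0)
        Phi = model.phi(qv, t0)
        Jphi = model.phi_q(qv, t0)
        g = (Jphi.T @ (alpha * Phi + lam) - Q)[free]
        return g, Phi, Jphi, patches

    message = ""
    converged = False

    def newton(n_iter):
        """Inner Newton loop at fixed multipliers; returns True on success."""
        nonlocal q
        for _ in range(n_iter):
            g, Phi, Jphi, patches = residual(q)
            res = float(np.max(np.abs(g)) if len(g) else 0.0)
            hist.append(res)
            phimax = float(np.max(np.abs(Phi)) if len(Phi) else 0.0)
            if res < config.force_tol and phimax <= config.pos_tol:
                return True
            Kq, _, _ = _force_jacobians_fd(model, q, st.qd, t0, free)
            Kc, _ = _contact_jacobian(model, q, patches, free)
            A = Jphi[:, free]
            J = alpha * (A.T @ A) + (Kc - Kq)
            J += 1e-9 * np.eye(len(free)) * max(1.0, np.abs(J).max())
            try:
                dq = np.linalg.solve(J, -g)
            except np.linalg.LinAlgError:
                return False
            # clamp: the contact stiffness is strongly state dependent
            nmax = float(np.max(np.abs(dq)))
            if nmax > 2e-3:
                dq *= 2e-3 / nmax
            merit0 = res
            stepl = 1.0
            for _ in range(12):
                qtry = q.copy()
                qtry[free] += stepl * dq
                gt, _, _, _ = residual(qtry)
                if (np.max(np.abs(gt)) if len(gt) else 0.0) < merit0 or stepl < 1e-4:
                    q[:] = qtry
                    break
                stepl *= 0.5
        g, Phi, _, _ = residual(q)
        return (float(np.max(np.abs(g)) if len(g) else 0.0) < config.force_tol
                and float(np.max(np.abs(Phi)) if len(Phi) else 0.0) <= config.pos_tol)

    def relax(n_blocks=40, block=10):
        """Kinetic-damping dynamic relaxation: integrate with guidance
        frozen at t0, zeroing velocities every block (energy strictly
        decreases toward a minimum)."""
        nonlocal q
        saved = dict(model.guidance)
        model.guidance = {k: FrozenGuidance(v, t0) for k, v in saved.items()}
        model._jac_cache = None
        try:
            stt = st.copy()
            stt.q = q.copy()
            stt.qd[:] = 0.0
            stt.qdd[:] = 0.0
            stt.lam = np.zeros(model.n_constraints)
            cfg_rx = replace(config, h=min(config.h, 5e-4),
                             contact_mode="per_step")
            initialize_accelerations(model, stt, cfg_rx)
            for _ in range(n_blocks):
                for _ in range(block):
                    stt = step(model, stt, cfg_rx)
                stt.qd[:] = 0.0
                stt.qdd[:] = 0.0
                stt.t = t0
            q = stt.q.copy()
        finally:
            model.guidance = saved
            model._jac_cache = None

    def lm_polish():
        """Levenberg-Marquardt on the residual (robust to the approximate
        contact tangent the plain Newton uses)."""
        nonlocal q
        from scipy.optimize import least_squares

        def fvec(qf):
            qq = q.copy()
            qq[free] = qf
            g, Phi, _, _ = residual(qq)
            return g

        sol = least_squares(fvec, q[free].copy(), method="lm",
                            xtol=1e-15, ftol=1e-15, gtol=1e-15,
                            diff_step=1e-5, max_nfev=800)
        qq = q.copy()
        qq[free] = sol.x
        g, Phi, _, _ = residual(qq)
        if np.max(np.abs(g)) <= max(hist[-1] if hist else np.inf, 1e-12):
            q = qq
        hist.append(float(np.max(np.abs(g))))

    # outer augmented-Lagrangian loop with relaxation and LM fallbacks
    for outer in range(4):
        if newton(max_iter // 6):
            converged = True
            break
        if outer == 0:
            relax()
        else:
            lm_polish()
        lam += alpha * model.phi(q, t0)
        converged = newton(max_iter // 6)
        if converged:
            break
    if not converged:
        message = f"no convergence in {len(hist)} iterations"

    _, _, patches = model.applied_forces(q, st.qd, t0)
    contacting = any(p.delta > 0 for p in patches)
    if require_contact and converged and not contacting:
        converged = False
        message = "no contacting equilibrium found"
    if not converged and not message:
        message = f"residual {hist[-1]:.3e} > force_tol"
    st.q = q
    st.patches = patches
    st.max_phi = float(np.max(np.abs(model.phi(q, t0))) if model.n_constraints else 0.0)
    for cp in model.contacts:
        cp.backend.reset()
    return StaticEquilibriumResult(st, converged, contacting, hist, message)


# --------------------------------------------------------------------------
# Simulation driver and trajectory container
# --------------------------------------------------------------------------

class Trajectory:
    """Recorded simulation histories at the integrator step resolution."""

    def __init__(self, model: Model, config: SimConfig):
        self.body_names = [b.name for b in model.bodies]
        self.spring_count = len(model.springs)
        self.config = config
        self.t: List[float] = []
        self.poses = {n: [] for n in self.body_names}      # (r(3), e(4)) rows
        self.vels = {n: [] for n in self.body_names}
        self.spring_tensions: List[np.ndarray] = []
        self.contact_force: List[float] = []
        self.contact_delta: List[float] = []
        self.contact_delta_dot: List[float] = []
        self.contact_point: List[np.ndarray] = []
        self.contact_normal: List[np.ndarray] = []
        self.n_patches: List[int] = []
        self.max_phi: List[float] = []
        self.max_vel_res: List[float] = []
        self.events: List[dict] = []
        self.stats: dict = {}

    def record(self, model: Model, state: SystemState):
        self.t.append(state.t)
        for n in self.body_names:
            r = state.q[model.r_slice(n)].copy()
            e = state.q[model.e_slice(n)].copy()
            self.poses[n].append(np.concatenate([r, e]))
            v, w = model.body_vel(state.q, state.qd, n)
            self.vels[n].append(np.concatenate([v, w]))
        tens = (state.spring_tensions if state.spring_tensions is not None
                else np.zeros(self.spring_count))
        self.spring_tensions.append(np.asarray(tens, float))
        force = sum(getattr(p, "force", 0.0) for p in state.patches)
        delta = max((p.delta for p in state.patches), default=0.0)
        pt = (state.patches[0].point.copy() if state.patches
              else np.full(3, np.nan))
        nrm = (state.patches[0].normal.copy() if state.patches
               else np.full(3, np.nan))
        ddot = state.patches[0].delta_dot if state.patches else 0.0
        self.contact_force.append(float(force))
        self.contact_delta.append(float(delta))
        self.contact_delta_dot.append(float(ddot))
        self.contact_point.append(pt)
        self.contact_normal.append(nrm)
        self.n_patches.append(len(state.patches))
        self.max_phi.append(state.max_phi)
        self.max_vel_res.append(state.max_vel_res)

    def finalize(self):
        self.t = np.asarray(self.t)
        for n in self.body_names:
            self.poses[n] = np.asarray(self.poses[n])
            self.vels[n] = np.asarray(self.vels[n])
        self.spring_tensions = np.asarray(self.spring_tensions)
        self.contact_force = np.asarray(self.contact_force)
        self.contact_delta = np.asarray(self.contact_delta)
        self.contact_delta_dot = np.asarray(self.contact_delta_dot)
        self.contact_point = np.asarray(self.contact_point)
        self.contact_normal = np.asarray(self.contact_normal)
        self.n_patches = np.asarray(self.n_patches)
        self.max_phi = np.asarray(self.max_phi)
        self.max_vel_res = np.asarray(self.max_vel_res)
        return self

    def body_r(self, name):
        return self.poses[name][:, :3]

    def body_e(self, name):
        return self.poses[name][:, 3:]

    def to_frame(self):
        import pandas as pd
        data = {"t": self.t}
        for n in self.body_names:
            P = self.poses[n]
            for k, c in enumerate(["x", "y", "z", "e0", "e1", "e2", "e3"]):
                data[f"{n}_{c}"] = P[:, k]
        for k in range(self.spring_count):
            data[f"spring{k}_tension"] = self.spring_tensions[:, k]
        data["contact_force"] = self.contact_force
        data["contact_delta"] = self.contact_delta
        data["max_phi"] = self.max_phi
        data["max_vel_res"] = self.max_vel_res
        return pd.DataFrame(data)

    def save_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    def save_contact_log(self, path):
        """Per-step contact log: t, point, normal, delta, delta rate, force."""
        import pandas as pd
        pd.DataFrame({
            "t": self.t,
            "px": self.contact_point[:, 0],
            "py": self.contact_point[:, 1],
            "pz": self.contact_point[:, 2],
            "nx": self.contact_normal[:, 0],
            "ny": self.contact_normal[:, 1],
            "nz": self.contact_normal[:, 2],
            "delta": self.contact_delta,
            "delta_dot": self.contact_delta_dot,
            "force": self.contact_force,
        }).to_csv(path, index=False)


def _substep(model: Model, state: SystemState, config: SimConfig,
             depth: int, factor: int = 4, max_depth: int = 3) -> SystemState:
    """Advance one nominal step as ``factor`` sub-steps, recursively."""
    sub = replace(config, h=config.h / factor)
    for _ in range(factor):
        try:
            state = step(model, state, sub)
        except ConvergenceError:
            if depth >= max_depth:
                raise
            state = _substep(model, state, sub, depth + 1, factor, max_depth)
    return state


def simulate(model: Model, t_span: Tuple[float, float], config: SimConfig,
             state: Optional[SystemState] = None,
             record_every: int = 1,
             progress: bool = False) -> Trajectory:
    """Integrate the model over ``t_span`` and record full histories.

    Deterministic: identical model/config/state reproduce the trajectory
    bitwise.  Raises :class:`ConvergenceError` on step failure.
    """
    t0, t1 = t_span
    if state is None:
        state = model.initial_state(t0)
    for cp in model.contacts:
        cp.backend.reset()
    model._jac_cache = None
    initialize_accelerations(model, state, config)
    traj = Trajectory(model, config)
    # record the initial state with its diagnostics
    Q, tensions, patches = model.applied_forces(state.q, state.qd, t0)
    model.commit_episodes(patches, t0)
    state.patches = patches
    state.spring_tensions = tensions
    traj.record(model, state)

    n_steps = int(round((t1 - t0) / config.h))
    wall0 = _time.perf_counter()
    n_substepped = 0
    for k in range(n_steps):
        try:
            state = step(model, state, config)
        except ConvergenceError:
            # retry with temporary step halving (stiff transients, e.g.
            # ridge crossing during a dislocation)
            state = _substep(model, state, config, depth=0)
            n_substepped += 1
        if (k + 1) % record_every == 0:
            traj.record(model, state)
    wall = _time.perf_counter() - wall0
    traj.stats = {"n_steps": n_steps, "n_substepped": n_substepped,
                  "wall_time_s": wall,
                  "sim_time_s": t1 - t0,
                  "realtime_ratio": (t1 - t0) / wall if wall > 0 else np.inf}
    for cp in model.contacts:
        traj.events.extend(getattr(cp.backend, "left_domain_events", []))
    return traj.finalize()
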