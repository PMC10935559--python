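"""Synthetic patellofemoral test bench.

The physical rig this package emulates is a sensorized 3D-printed leg:
femoral and patellar implants, a quadriceps spring (K1 = 156 N/m,
L1 = 14.32 cm) anchored on the femur, a patellar-tendon spring
(K2 = 629 N/m, L2 = 7.14 cm) anchored on the tibia, adjustable
medial/lateral attachment supports on both bones, eight optical markers
at 100 Hz, and a manually driven passive flexion-extension motion that
starts near 45 degrees of knee flexion and flexes/extends twice.
Neither the implant CAD nor the captures are public, so this module
generates an equivalent bench: the groove height field of
:mod:`pftwin.geometry`, an icosphere button, virtual markers, and smooth
guided femur/tibia motion with known ground truth.

Frames: the femoral body frame is the groove frame (x sagittal toward the
hip, y medial, z toward the patella).  The femur hangs from a fixed
spherical hip joint and performs a small prescribed rocking; the tibia
rotates about the knee's medial-lateral axis by the flexion profile
(0 deg = full extension); the patella is free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .collision import (AnalyticContactBackend, MeshContactBackend,
                        SpherePrimitive)
from .dynamics import ContactPair, Model, RigidBody, SimConfig, SphericalJoint
from .errors import ConfigError
from .forces import FloresParams, SpringDamperParams
from .geometry import GrooveParams, MeshQuality, TriMesh, make_icosphere, \
    make_trochlear_surface
from .mocap import BodyPoseSeries, FrameRecipe, MarkerTrajectories
from .quat import quat_from_axis_angle, quat_multiply, rotmat
from .surface_fit import PolynomialSurface, fit_polynomial

__all__ = ["ScenarioConfig", "BenchLayout", "synth_motion", "flexion_profile",
           "make_backend", "build_model", "groove_track_pose",
           "sweep_trajectory", "MotionProfile", "set_patella_state",
           "default_timestep", "fit_femur_surface", "make_femur_surface_mesh",
           "MESH_TOLERANCES", "SPHERE_SUBDIVISIONS", "event_motion",
           "pathological_scenario", "treated_scenario", "prepare_run",
           "run_scenario", "grouped_tensions", "SPRING_GROUPS"]

#: mesh tolerance targets of the two mesh resolutions (chordal m, normal deg)
MESH_TOLERANCES = {"coarse": MeshQuality(1e-4, 1.0),
                   "fine": MeshQuality(6e-6, 0.5)}
SPHERE_SUBDIVISIONS = {"coarse": 2, "fine": 3}


@dataclass
class BenchLayout:
    """Fixed geometry of the synthetic bench (femur/tibia/patella local
    points, marker cluster, masses).  All coordinates in body frames, m."""

    hip_local: np.ndarray = field(
        default_factory=lambda: np.array([0.35, 0.0, 0.03]))
    # quadriceps-spring support on the femur (x, z); the y offset depends on
    # the medial/lateral support position.  The medial position is nearly
    # centered (physiological Q-angle); the lateral one biases the pull.
    quad_support: np.ndarray = field(
        default_factory=lambda: np.array([0.21, 0.0, 0.005]))
    quad_support_y: Dict[str, float] = field(
        default_factory=lambda: {"medial": 0.003, "lateral": -0.015})
    # patellar-tendon support (tibial tuberosity) in the tibia frame
    tibia_support: np.ndarray = field(
        default_factory=lambda: np.array([-0.090, 0.0, 0.010]))
    tibia_support_y: Dict[str, float] = field(
        default_factory=lambda: {"medial": 0.003, "lateral": -0.028})
    # spring attachment points on the patella (superior / inferior pole)
    # strap attachments sit on the posterior face near the button: with
    # the low anchors this makes the groove-aligned orientation elastically
    # stable about all three axes
    patella_sup: np.ndarray = field(
        default_factory=lambda: np.array([0.012, 0.0, -0.006]))
    patella_inf: np.ndarray = field(
        default_factory=lambda: np.array([-0.012, 0.0, -0.006]))
    # each tendon is a two-strand strap (K/2 per strand) whose strands
    # attach +-strap_halfwidth off the pole in y: like the physical straps,
    # this stabilizes patellar spin/tilt, which a single point spring
    # cannot (the contact force passes through the sphere center)
    strap_halfwidth: float = 0.006
    knee_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    femur_mass: float = 0.4
    tibia_mass: float = 0.5
    patella_mass: float = 0.03
    sphere_radius: float = 0.015

    marker_local: Dict[str, Dict[str, Tuple[float, float, float]]] = field(
        default_factory=lambda: {
            "femur": {"F1": (0.10, 0.035, 0.02), "F2": (0.18, -0.03, 0.035)},
            "tibia": {"T1": (-0.10, 0.035, 0.02), "T2": (-0.18, -0.03, 0.01),
                      "T3": (-0.14, 0.0, 0.055)},
            "patella": {"P1": (0.05, 0.0, 0.02), "P2": (-0.03, 0.045, 0.02),
                        "P3": (-0.03, -0.045, 0.02)},
        })

    def recipe(self, body: str) -> FrameRecipe:
        loc = {k: np.asarray(v, float)
               for k, v in self.marker_local[body].items()}
        if body == "femur":
            # two markers plus the known hip-joint location (Vaughan allows
            # pre-defined joint entities)
            loc["HIP"] = self.hip_local
            return FrameRecipe("F1", "HIP", "F2", loc)
        names = sorted(loc)
        return FrameRecipe(names[0], names[1], names[2], loc)

    def patella_inertia(self) -> np.ndarray:
        i = 0.4 * self.patella_mass * self.sphere_radius ** 2
        return np.eye(3) * i


@dataclass
class MotionProfile:
    """Two manual flexion-extension cycles starting near 45 deg."""

    start_flexion: float = 45.0      # deg
    peak_flexion: float = 60.0
    partial_extension: float = 20.0  # first extension stops here (deg)
    final_extension: float = 0.0     # second extension is complete
    cycles: int = 2
    duration: float = 6.0            # s
    femur_rock_amp: float = 1.5      # deg
    femur_rock_freq: float = 0.35    # Hz


@dataclass
class ScenarioConfig:
    """One bench configuration: attachments, springs, backend, integrator."""

    femur_attach: str = "medial"     # medial | lateral
    tibia_attach: str = "medial"
    quad_K: float = 156.0            # N/m
    quad_L0: float = 0.1432          # m
    tendon_K: float = 629.0
    tendon_L0: float = 0.0714
    quad_rigid_extension: float = 0.0    # m; the case-3 variant uses 0.0196
    flores: FloresParams = field(default_factory=FloresParams)
    sim: SimConfig = field(default_factory=SimConfig)
    groove: GrooveParams = field(default_factory=GrooveParams)
    layout: BenchLayout = field(default_factory=BenchLayout)
    motion: MotionProfile = field(default_factory=MotionProfile)
    backend: str = "analytic:5"
    marker_noise_std: float = 0.0    # m
    seed: int = 0

    def __post_init__(self):
        for att in (self.femur_attach, self.tibia_attach):
            if att not in ("medial", "lateral"):
                raise ConfigError(f"attachment must be medial|lateral, got {att}")
        for v in (self.quad_K, self.quad_L0, self.tendon_K, self.tendon_L0):
            if v <= 0:
                raise ConfigError("spring parameters must be positive")

    @property
    def quad_L0_effective(self) -> float:
        """Free length including the optional rigid extension piece."""
        return self.quad_L0 + self.quad_rigid_extension

    def springs(self) -> Tuple[SpringDamperParams, ...]:
        """Four spring elements: the quadriceps and patellar-tendon straps,
        two strands each (K/2 per strand, shared L0).  Order:
        quad_a, quad_b, tendon_a, tendon_b."""
        lay = self.layout
        fq = lay.quad_support.copy()
        fq[1] = lay.quad_support_y[self.femur_attach]
        tt = lay.tibia_support.copy()
        tt[1] = lay.tibia_support_y[self.tibia_attach]
        off = np.array([0.0, lay.strap_halfwidth, 0.0])
        out = []
        for sgn in (+1.0, -1.0):   # parallel strands: anchors offset too
            out.append(SpringDamperParams(
                K=self.quad_K / 2.0, L0=self.quad_L0_effective,
                attach_A=("femur", fq + sgn * off),
                attach_B=("patella", lay.patella_sup + sgn * off)))
        for sgn in (+1.0, -1.0):
            out.append(SpringDamperParams(
                K=self.tendon_K / 2.0, L0=self.tendon_L0,
                attach_A=("tibia", tt + sgn * off),
                attach_B=("patella", lay.patella_inf + sgn * off)))
        return tuple(out)


# --------------------------------------------------------------------------
# Guided motion (ground truth)
# --------------------------------------------------------------------------

def flexion_profile(motion: MotionProfile):
    """Knee flexion angle theta(t) in radians: C1 piecewise-cosine ramps
    with exactly ``cycles`` local maxima."""
    knots = [motion.start_flexion]
    for c in range(motion.cycles):
        knots.append(motion.peak_flexion)
        knots.append(motion.partial_extension if c < motion.cycles - 1
                     else motion.final_extension)
    knots = np.radians(knots)
    n_seg = len(knots) - 1
    tseg = motion.duration / n_seg

    def theta(t):
        t = np.clip(t, 0.0, motion.duration - 1e-12)
        k = np.minimum((t / tseg).astype(int) if np.ndim(t) else int(t / tseg),
                       n_seg - 1)
        s = (t - k * tseg) / tseg
        a = knots[k]
        b = knots[np.minimum(k + 1, n_seg)]
        return a + (b - a) * 0.5 * (1.0 - np.cos(np.pi * s))

    return theta


def _femur_pose(motion: MotionProfile, layout: BenchLayout, t):
    """Femur rocking about the fixed hip point (small prescribed wobble)."""
    a = np.radians(motion.femur_rock_amp) * np.sin(
        2 * np.pi * motion.femur_rock_freq * t)
    e = quat_from_axis_angle([0.0, 1.0, 0.0], a)
    hip_world = layout.hip_local.copy()   # initial pose is the identity
    r = hip_world - rotmat(e) @ layout.hip_local
    return r, e


def _tibia_pose(theta, motion, layout, t):
    """Tibia rotated by the flexion angle about the knee y-axis, riding on
    the femur's rocking motion."""
    rf, ef = _femur_pose(motion, layout, t)
    knee_world = rf + rotmat(ef) @ layout.knee_center
    e_rel = quat_from_axis_angle([0.0, 1.0, 0.0], -float(theta(t)))
    e = quat_multiply(ef, e_rel)
    r = knee_world - rotmat(e) @ layout.knee_center
    return r, e


def groove_track_pose(cfg: ScenarioConfig, theta_val: float,
                      delta: float = 2e-4, y_offset: float = 0.0):
    """Idealized groove-following patella pose (femur frame) at one flexion
    angle: the sphere center rides the groove floor at indentation
    ``delta``, the patellar long axis following the sagittal tangent.  The
    sagittal position tracks the spring force balance of the default
    bench (superior near extension, distal in flexion)."""
    g = cfg.groove
    x_ext, x_flex60 = 0.004, -0.003
    frac = np.clip(theta_val / np.radians(60.0), 0.0, 1.3)
    x = x_ext + (x_flex60 - x_ext) * frac
    y = y_offset
    n = _groove_normal(g, x, y)
    base = np.array([x, y, float(g.height(x, y))])
    center = base + (cfg.layout.sphere_radius - delta) * n
    slope = -x / g.sagittal_radius
    e = quat_from_axis_angle([0.0, 1.0, 0.0], -np.arctan(slope))
    return center, e


def _groove_normal(g: GrooveParams, x, y):
    fx, fy = g.gradient(x, y)
    n = np.array([-float(fx), -float(fy), 1.0])
    return n / np.linalg.norm(n)


def synth_motion(cfg: ScenarioConfig, fs: float = 100.0,
                 rng: Optional[np.random.Generator] = None):
    """Generate the synthetic bench capture.

    Returns ``(markers, truth)``: 8-marker trajectories at ``fs`` Hz (with
    optional iid Gaussian noise of ``cfg.marker_noise_std``) and the
    ground-truth :class:`BodyPoseSeries` per body.  The patella ground
    truth is the idealized groove-following path — it stands in for the
    recorded patella used to validate simulations and to seed the static
    equilibrium.
    """
    motion, layout = cfg.motion, cfg.layout
    theta = flexion_profile(motion)
    n = int(round(motion.duration * fs)) + 1
    t = np.arange(n) / fs
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    poses = {"femur": [], "tibia": [], "patella": []}
    for tk in t:
        rf, ef = _femur_pose(motion, layout, tk)
        rt, et = _tibia_pose(theta, motion, layout, tk)
        cp_local, ep_local = groove_track_pose(cfg, float(theta(tk)))
        Af = rotmat(ef)
        rp = rf + Af @ cp_local
        ep = quat_multiply(ef, ep_local)
        poses["femur"].append((rf, ef))
        poses["tibia"].append((rt, et))
        poses["patella"].append((rp, ep))

    truth = {}
    for body in poses:
        r = np.array([p[0] for p in poses[body]])
        e = np.array([p[1] for p in poses[body]])
        truth[body] = BodyPoseSeries(body=body, t=t, r=r, e=e)

    ids, markers = [], []
    for body, cluster in layout.marker_local.items():
        series = truth[body]
        for mid, loc in cluster.items():
            loc = np.asarray(loc, float)
            world = np.array([series.r[k] + rotmat(series.e[k]) @ loc
                              for k in range(n)])
            ids.append(mid)
            markers.append(world)
    pos = np.stack(markers, axis=1)
    if cfg.marker_noise_std > 0:
        pos = pos + rng.normal(0.0, cfg.marker_noise_std, pos.shape)
    return MarkerTrajectories(ids, pos, fs=fs), truth


def hip_world_point(cfg: ScenarioConfig) -> np.ndarray:
    return cfg.layout.hip_local.copy()


# --------------------------------------------------------------------------
# Backends and model assembly
# --------------------------------------------------------------------------

def make_femur_surface_mesh(cfg: ScenarioConfig, resolution: str) -> TriMesh:
    return make_trochlear_surface(cfg.groove, MESH_TOLERANCES[resolution])


def fit_femur_surface(cfg: ScenarioConfig, order: int,
                      resolution: str = "fine") -> PolynomialSurface:
    mesh = make_femur_surface_mesh(cfg, resolution)
    return fit_polynomial(mesh.vertices, order)


def make_backend(cfg: ScenarioConfig, spec: Optional[str] = None,
                 sphere_subdivisions: Optional[int] = None):
    """Backend factory: ``analytic:2|4|5`` or ``mesh:coarse|fine``."""
    spec = spec or cfg.backend
    kind, _, arg = spec.partition(":")
    sphere = SpherePrimitive(radius=cfg.layout.sphere_radius)
    if kind == "analytic":
        order = int(arg or 5)
        if order < 1:
            raise ConfigError("polynomial order must be >= 1")
        surface = fit_femur_surface(cfg, order)
        return AnalyticContactBackend(surface, sphere)
    if kind == "mesh":
        if arg not in MESH_TOLERANCES:
            raise ConfigError(
                f"unknown mesh resolution '{arg}'; valid: coarse, fine")
        femur_mesh = make_femur_surface_mesh(cfg, arg)
        sub = (SPHERE_SUBDIVISIONS[arg] if sphere_subdivisions is None
               else sphere_subdivisions)
        button = make_icosphere(cfg.layout.sphere_radius, sub)
        return MeshContactBackend(femur_mesh, button)
    raise ConfigError(
        f"unknown backend '{spec}'; valid: analytic:2|4|5, mesh:coarse|fine")


def default_timestep(spec: str) -> float:
    """1 ms for the analytic backend; 0.1 ms for mesh backends."""
    return 1e-3 if spec.startswith("analytic") else 1e-4


def build_model(cfg: ScenarioConfig, guidance: Dict[str, object],
                backend=None) -> Model:
    """Assemble the three-body guided bench model (patella free)."""
    lay = cfg.layout
    femur = RigidBody("femur", lay.femur_mass, np.eye(3) * 2e-3, guided=True)
    tibia = RigidBody("tibia", lay.tibia_mass, np.eye(3) * 3e-3, guided=True)
    patella = RigidBody("patella", lay.patella_mass, lay.patella_inertia())
    if backend is None:
        backend = make_backend(cfg)
    pair = ContactPair("femur", "patella", backend, cfg.flores)
    hip = SphericalJoint("femur", local_point=lay.hip_local,
                         world_point=hip_world_point(cfg))
    return Model([femur, tibia, patella], list(cfg.springs()), [pair],
                 constraints=[hip], guidance=guidance)


#: trajectory spring-tension columns per load-cell channel
SPRING_GROUPS = {"femoral": (0, 1), "tibial": (2, 3)}


def grouped_tensions(traj) -> Dict[str, np.ndarray]:
    """Sum strap strands into the two load-cell channels (N)."""
    return {name: traj.spring_tensions[:, list(cols)].sum(axis=1)
            for name, cols in SPRING_GROUPS.items()}


def set_patella_state(model: Model, state, r, e, v=None, omega=None):
    sl_r = model.r_slice("patella")
    sl_e = model.e_slice("patella")
    state.q[sl_r] = r
    state.q[sl_e] = e / np.linalg.norm(e)
    if v is not None:
        state.qd[sl_r] = v
    from .quat import gmat
    if omega is not None:
        state.qd[sl_e] = 0.5 * gmat(state.q[sl_e]).T @ omega


# --------------------------------------------------------------------------
# Scenario drivers and instability fixtures
# --------------------------------------------------------------------------

def event_motion(duration: float = 1.2) -> MotionProfile:
    """Single fast flexion-extension cycle (45 -> 60 -> 0 deg): the short
    fixture on which the dislocation / treatment logic is exercised."""
    return MotionProfile(start_flexion=45.0, peak_flexion=60.0,
                        final_extension=0.0, cycles=1, duration=duration)


def pathological_scenario(duration: float = 1.2, **kw) -> ScenarioConfig:
    """Lateralized attachments (increased Q-angle): dislocates at the end
    of extension, like the bench's unstable configuration."""
    kw.setdefault("femur_attach", "lateral")
    kw.setdefault("tibia_attach", "lateral")
    kw.setdefault("motion", event_motion(duration))
    return ScenarioConfig(**kw)


def treated_scenario(duration: float = 1.2, **kw) -> ScenarioConfig:
    """The pathological bench after tibial tuberosity medialization (only
    the tibial attachment changes)."""
    kw.setdefault("tibia_attach", "medial")
    return pathological_scenario(duration, **kw)


def prepare_run(cfg: ScenarioConfig, backend=None, equilibrate: bool = True):
    """Synthesize the capture, build guidance and the model, and (optionally)
    solve the initial static equilibrium seeded by the recorded patella.

    Returns ``(model, state0, truth, markers)``.
    """
    from .dynamics import static_equilibrium
    markers, truth = synth_motion(cfg)
    guidance = {b: truth[b].spline() for b in ("femur", "tibia")}
    model = build_model(cfg, guidance, backend=backend)
    state = model.initial_state(0.0)
    set_patella_state(model, state, truth["patella"].r[0], truth["patella"].e[0])
    if equilibrate:
        if isinstance(backend, MeshContactBackend) or (
                backend is None and cfg.backend.startswith("mesh")):
            # the faceted surface makes the equilibrium residual noisy at
            # the micrometer scale; solve it on the smooth analytic twin
            # of the same groove and hand the state over
            smooth = build_model(cfg, guidance,
                                 backend=make_backend(cfg, "analytic:5"))
            res = static_equilibrium(smooth, state, config=cfg.sim,
                                     require_contact=True)
        else:
            res = static_equilibrium(model, state, config=cfg.sim,
                                     require_contact=True)
        state = res.state
    return model, state, truth, markers


def run_scenario(cfg: ScenarioConfig, backend_spec: Optional[str] = None,
                 sim: Optional[SimConfig] = None, state=None, model=None,
                 record_every: int = 1):
    """End-to-end guided simulation of a scenario over its full motion."""
    from .dynamics import simulate
    spec = backend_spec or cfg.backend
    if model is None:
        backend = make_backend(cfg, spec)
        model, state, _, _ = prepare_run(cfg, backend=backend)
    if sim is None:
        sim = replace(cfg.sim, h=default_timestep(spec),
                      contact_mode="per_step" if spec.startswith("mesh")
                      else cfg.sim.contact_mode)
    return simulate(model, (0.0, cfg.motion.duration), sim, state=state,
                    record_every=record_every)


# --------------------------------------------------------------------------
# Kinematic sweep (backend comparison on a common trajectory)
# --------------------------------------------------------------------------

def sweep_trajectory(cfg: ScenarioConfig, fs: float = 2000.0,
                     duration: float = 1.0, delta_max: float = 5e-4,
                     y_amp: float = 0.25):
    """Prescribed sphere path along the groove with a smoothly varying
    indentation (up to ``delta_max``) and a small medial-lateral sway —
    the common trajectory on which contact backends are compared.

    Returns ``(t, centers)`` in the femur frame.
    """
    g = cfg.groove
    t = np.arange(int(round(duration * fs)) + 1) / fs
    s = t / duration
    x = (0.7 * g.x_halfwidth) * (1.0 - 2.0 * s)      # proximal -> distal
    y = (y_amp * g.groove_halfwidth) * np.sin(2 * np.pi * 1.5 * s)
    delta = delta_max * np.sin(np.pi * s) ** 2
    centers = np.empty((len(t), 3))
    for k in range(len(t)):
        n = _groove_normal(g, x[k], y[k])
        base = np.array([x[k], y[k], float(g.height(x[k], y[k]))])
        centers[k] = base + (cfg.layout.sphere_radius - delta[k]) * n
    return t, centers
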