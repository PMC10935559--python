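"""Tendon-parameter identification and treatment prediction.

The bench's spring parameters stand in for tendon properties that are
unknown in a real knee.  They are estimated by matching the simulated
patellar trajectory to the recorded one: a genetic algorithm searches
(K1, L1, K2, L2) inside a +-30% box around the nominal values, minimizing
the RMSE of the patellar relative-position distance error; measured
forces are deliberately not part of the objective (motion capture is the
only input available intra-operatively).  An optional Nelder-Mead polish
refines the best GA individual, mirroring the hybrid-function usage of
the classical GA toolboxes.

Treatment prediction re-simulates the calibrated twin with a modified
tibial attachment (tibial tuberosity medialization) and reports whether
the instability event disappears.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Dict, List, Optional

import numpy as np

from .analysis import (Event, PatellarKinematics, ValidationReport,
                       detect_events, kinematics_from_trajectory, rmse_report)
from .bench import ScenarioConfig, build_model, flexion_profile
from .dynamics import SimConfig, SystemState, Trajectory, simulate
from .errors import ConvergenceError, PftwinError

__all__ = ["GAConfig", "CalibrationResult", "TendonCalibration",
           "calibrate_tendons", "predict_treatment", "TreatmentReport"]

PARAM_NAMES = ("K1", "L1", "K2", "L2")


@dataclass
class GAConfig:
    """Genetic-algorithm settings (deterministic under a fixed seed)."""

    population: int = 8
    generations: int = 4
    tournament: int = 3
    crossover_rate: float = 0.9
    blend_alpha: float = 0.3
    mutation_rate: float = 0.35
    mutation_sigma: float = 0.10     # fraction of the box width
    elitism: int = 1
    seed: int = 0
    polish: bool = True
    polish_maxiter: int = 50         # residual evaluations for the local polish


@dataclass
class CalibrationResult:
    params: Dict[str, float]
    objective: float                 # mm
    trace: List[float]               # best objective per generation
    evaluations: List[dict]
    n_evals: int
    bounds: Dict[str, tuple]


class TendonCalibration:
    """Objective wrapper: simulate the bench at candidate spring parameters
    and score against observed patellar kinematics.

    All candidate simulations start from the same initial state as the
    observed motion (the recorded patella seeds it), share the collision
    backend, and integrate the same guided time span; the objective is the
    RMSE over frames of the Euclidean distance between simulated and
    observed sphere centers in the femur frame (mm).
    """

    def __init__(self, cfg: ScenarioConfig, guidance: dict,
                 initial_state: SystemState,
                 observed: Optional[PatellarKinematics], t_span,
                 sim_config: Optional[SimConfig] = None,
                 backend=None, record_every: int = 10):
        self.cfg = cfg
        self.guidance = guidance
        self.initial_state = initial_state
        self.observed = observed
        self.t_span = tuple(t_span)
        # one geometric contact detection per step and a slower Jacobian
        # refresh: candidate evaluations dominate calibration cost
        self.sim_config = sim_config or replace(cfg.sim,
                                                contact_mode="per_step",
                                                jac_refresh=10)
        self.backend = backend
        self.record_every = record_every
        self.log: List[dict] = []

    def observe_params(self, K1, L1, K2, L2) -> Trajectory:
        """Simulate ground-truth parameters and adopt the result as the
        observed motion (synthetic-experiment workflow)."""
        traj = self.simulate_params(K1, L1, K2, L2)
        self.observed = kinematics_from_trajectory(traj)
        return traj

    def simulate_params(self, K1, L1, K2, L2) -> Trajectory:
        cfg = replace(self.cfg, quad_K=float(K1), quad_L0=float(L1),
                      tendon_K=float(K2), tendon_L0=float(L2),
                      quad_rigid_extension=0.0)
        model = build_model(cfg, self.guidance, backend=self.backend)
        return simulate(model, self.t_span, self.sim_config,
                        state=self.initial_state.copy(),
                        record_every=self.record_every)

    def residuals(self, params) -> np.ndarray:
        """Per-frame patellar distance errors (mm) — the least-squares view
        of the objective used by the local polish."""
        K1, L1, K2, L2 = params
        try:
            traj = self.simulate_params(K1, L1, K2, L2)
        except ConvergenceError as exc:
            self.log.append({"params": list(map(float, params)),
                             "error": str(exc)})
            return np.full(len(self.observed.t), 1e3)
        kin = kinematics_from_trajectory(traj)
        pos = np.stack([np.interp(self.observed.t, kin.t, kin.position[:, k])
                        for k in range(3)], axis=1)
        return 1000.0 * np.linalg.norm(pos - self.observed.position, axis=1)

    def objective(self, params) -> float:
        res = self.residuals(params)
        val = float(np.sqrt(np.mean(res ** 2)))
        self.log.append({"params": list(map(float, params)), "objective": val})
        return val


def _ga_minimize(fun: Callable, lo: np.ndarray, hi: np.ndarray,
                 ga: GAConfig, residual_fun: Optional[Callable] = None):
    """Simple real-coded GA: tournament selection, blend crossover,
    Gaussian mutation, elitism; optionally followed by a bounded
    trust-region least-squares polish of the best individual (the hybrid
    local stage — the objective's K/L0 valley is slow for direct search
    but benign for a least-squares step).
    Returns (best_x, best_f, trace, n_evals)."""
    rng = np.random.default_rng(ga.seed)
    dim = len(lo)
    span = hi - lo
    pop = rng.uniform(lo, hi, size=(ga.population, dim))
    pop[0] = 0.5 * (lo + hi)            # nominal values join the initial pool
    fit = np.array([fun(x) for x in pop])
    n_evals = len(pop)
    trace = [float(fit.min())]

    for _ in range(ga.generations):
        order = np.argsort(fit)
        new = [pop[order[k]].copy() for k in range(ga.elitism)]
        while len(new) < ga.population:
            idx = rng.integers(0, ga.population, ga.tournament)
            p1 = pop[idx[np.argmin(fit[idx])]]
            idx = rng.integers(0, ga.population, ga.tournament)
            p2 = pop[idx[np.argmin(fit[idx])]]
            if rng.random() < ga.crossover_rate:
                a = ga.blend_alpha
                u = rng.uniform(-a, 1 + a, dim)
                child = p1 + u * (p2 - p1)
            else:
                child = p1.copy()
            mut = rng.random(dim) < ga.mutation_rate
            child = child + mut * rng.normal(0.0, ga.mutation_sigma * span, dim)
            new.append(np.clip(child, lo, hi))
        pop = np.asarray(new)
        fit = np.concatenate([fit[order[:ga.elitism]],
                              [fun(x) for x in pop[ga.elitism:]]])
        n_evals += ga.population - ga.elitism
        trace.append(float(fit.min()))

    k = int(np.argmin(fit))
    best_x, best_f = pop[k].copy(), float(fit[k])

    if ga.polish and residual_fun is not None:
        from scipy.optimize import least_squares
        count = [0]

        def rf(x):
            count[0] += 1
            return residual_fun(x)

        sol = least_squares(rf, best_x, bounds=(lo, hi), method="trf",
                            x_scale=0.5 * (lo + hi), diff_step=1e-4,
                            xtol=1e-8, ftol=1e-10, gtol=1e-10,
                            max_nfev=max(ga.polish_maxiter // 5, 2))
        n_evals += count[0]
        f_pol = float(np.sqrt(np.mean(sol.fun ** 2)))
        if f_pol < best_f:
            best_x, best_f = np.clip(sol.x, lo, hi), f_pol
        trace.append(best_f)
    return best_x, best_f, trace, n_evals


def calibrate_tendons(problem: TendonCalibration,
                      bounds_fraction: float = 0.3,
                      ga: Optional[GAConfig] = None) -> CalibrationResult:
    """Estimate (K1, L1, K2, L2) inside a +-``bounds_fraction`` box around
    the scenario's nominal spring parameters."""
    ga = ga or GAConfig()
    cfg = problem.cfg
    nominal = np.array([cfg.quad_K, cfg.quad_L0_effective,
                        cfg.tendon_K, cfg.tendon_L0])
    lo = nominal * (1.0 - bounds_fraction)
    hi = nominal * (1.0 + bounds_fraction)
    x, f, trace, n_evals = _ga_minimize(problem.objective, lo, hi, ga,
                                        residual_fun=problem.residuals)
    if not np.all(np.isfinite(x)) or f >= 1e6:
        raise PftwinError("calibration failed: all evaluations diverged; "
                          f"log has {len(problem.log)} entries")
    params = dict(zip(PARAM_NAMES, map(float, x)))
    return CalibrationResult(params=params, objective=f, trace=trace,
                             evaluations=problem.log, n_evals=n_evals,
                             bounds={n: (float(a), float(b))
                                     for n, a, b in zip(PARAM_NAMES, lo, hi)})


@dataclass
class TreatmentReport:
    trajectory: Trajectory
    events: List[Event]
    baseline_events: List[Event]
    validation: Optional[ValidationReport] = None

    @property
    def resolved(self) -> bool:
        """True when the baseline instability events are gone."""
        kinds = {e.kind for e in self.events}
        return all(e.kind not in kinds for e in self.baseline_events)


def predict_treatment(problem: TendonCalibration, calib: CalibrationResult,
                      edit: Optional[dict] = None,
                      reference: Optional[Trajectory] = None,
                      thresholds=None) -> TreatmentReport:
    """Simulate the calibrated twin after a treatment edit.

    ``edit`` maps :class:`ScenarioConfig` field names to new values; the
    default is tibial tuberosity medialization (``tibia_attach='medial'``).
    An empty edit reproduces the calibrated pathological simulation
    bitwise.  Events are detected on both the baseline (calibrated,
    un-edited) and the treated run.
    """
    if edit is None:
        edit = {"tibia_attach": "medial"}
    p = calib.params
    base = problem.simulate_params(p["K1"], p["L1"], p["K2"], p["L2"])
    theta = flexion_profile(problem.cfg.motion)
    base_events = detect_events(base, problem.cfg.groove, theta(base.t),
                                thresholds=thresholds)
    if edit:
        cfg2 = replace(problem.cfg, **edit)
        prob2 = TendonCalibration(cfg2, problem.guidance,
                                  problem.initial_state, problem.observed,
                                  problem.t_span, problem.sim_config,
                                  backend=problem.backend,
                                  record_every=problem.record_every)
        treated = prob2.simulate_params(p["K1"], p["L1"], p["K2"], p["L2"])
    else:
        treated = base
    events = detect_events(treated, problem.cfg.groove, theta(treated.t),
                           thresholds=thresholds)
    report = None
    if reference is not None:
        report = rmse_report(treated, reference)
    return TreatmentReport(trajectory=treated, events=events,
                           baseline_events=base_events, validation=report)
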