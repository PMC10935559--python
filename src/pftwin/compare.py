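"""Backend comparison on a common prescribed trajectory.

The sphere is swept along the groove with a known indentation history
(:func:`pftwin.bench.sweep_trajectory`); each collision backend detects
contact along the identical path and the Flores force histories are
compared.  Because the sweep offsets the center along the exact surface
normal by ``radius - delta`` (and the offset stays below the minimum
curvature radius), the true center-to-surface distance is known in closed
form — the generator itself provides the reference force history.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .bench import (SPHERE_SUBDIVISIONS, ScenarioConfig, make_backend,
                    sweep_trajectory)
from .forces import flores_magnitude

__all__ = ["sweep_reference", "backend_force_history", "highband_power"]

#: sphere subdivisions used for sweep comparisons (the accuracy study uses
#: a finer button than the dynamics default)
SWEEP_SPHERE_SUBDIVISIONS = {"coarse": 2, "fine": 4}


def _sweep(cfg: ScenarioConfig, fs: float, duration: float, delta_max: float):
    t, centers = sweep_trajectory(cfg, fs=fs, duration=duration,
                                  delta_max=delta_max)
    s = t / duration
    delta = delta_max * np.sin(np.pi * s) ** 2
    return t, centers, delta


def sweep_reference(cfg: ScenarioConfig, fs: float = 2000.0,
                    duration: float = 1.0, delta_max: float = 5e-4
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Exact Flores force history along the sweep (elastic branch: the
    sweep opens with a grazing contact, so the dissipative normalization
    is disabled exactly as the episode bookkeeping of the backends does)."""
    t, _, delta = _sweep(cfg, fs, duration, delta_max)
    force = np.array([flores_magnitude(cfg.flores, d, 0.0, None)
                      for d in delta])
    return t, force


def backend_force_history(cfg: ScenarioConfig, spec: str,
                          fs: float = 2000.0, duration: float = 1.0,
                          delta_max: float = 5e-4,
                          sphere_subdivisions: Optional[int] = None
                          ) -> Tuple[np.ndarray, np.ndarray]:
    """Contact-force history of one backend along the common sweep."""
    kind, _, arg = spec.partition(":")
    if sphere_subdivisions is None and kind == "mesh":
        sphere_subdivisions = SWEEP_SPHERE_SUBDIVISIONS.get(arg)
    backend = make_backend(cfg, spec, sphere_subdivisions=sphere_subdivisions)
    t, centers, _ = _sweep(cfg, fs, duration, delta_max)
    vel = np.gradient(centers, t, axis=0)
    I3 = np.eye(3)
    zero3 = np.zeros(3)
    force = np.zeros(len(t))
    for k in range(len(t)):
        patches = backend.contacts((I3, zero3), (I3, centers[k]),
                                   vel_femur=(zero3, zero3),
                                   vel_patella=(vel[k], zero3), t=t[k])
        force[k] = sum(
            flores_magnitude(cfg.flores, p.delta, p.delta_dot, p.delta_dot0)
            for p in patches)
    return t, force


def highband_power(force: np.ndarray, fs: float, f_cut: float = 50.0) -> float:
    """Spectral power of a force history above ``f_cut`` Hz (mean removed).

    The mesh backends' faceting shows up as exactly this high-frequency
    content; a finer mesh suppresses it."""
    x = np.asarray(force, float) - np.mean(force)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    return float(np.sum(np.abs(spec[freqs > f_cut]) ** 2) / len(x) ** 2)
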