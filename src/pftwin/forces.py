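"""Constitutive force laws: linear spring-damper tendons and the Flores
dissipative normal-contact model.

Tendons (quadriceps and patellar) are linear springs with a viscous term,

    F_i = K_i (L - L0_i) + c_i * dL/dt ,        c_i = 0.01 K_i by default,

where positive ``F`` is tension pulling the two attachment points together.
The damping sign is chosen dissipative: a lengthening tendon (dL/dt > 0) is
resisted by extra tension.  The opposite (as-printed) sign convention,
which injects energy over a closed length cycle, is available behind
``printed_damping_sign=True`` for comparison.

The contact normal force follows the Flores model,

    F_n = k_n * delta^p * [1 + 8(1 - eps)/(5 eps) * delta_dot / delta_dot0] ,

a Hertz-type stiffness term times a dissipative factor normalized by the
approach rate at first contact; ``eps`` is the coefficient of restitution
the model is constructed to approximate at low impact speeds.  The force
acts along the patch normal and is clamped to be non-adhesive (>= 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .collision.contact import ContactPatch

__all__ = ["SpringDamperParams", "FloresParams", "spring_damper_force",
           "flores_force", "flores_magnitude", "hertz_sphere_plane_stiffness"]


@dataclass
class SpringDamperParams:
    """One tendon spring: stiffness K (N/m), natural length L0 (m), damping
    c (N s/m, default 0.01 K), and the two attachments (body id, local point)."""

    K: float
    L0: float
    c: Optional[float] = None
    attach_A: tuple = ("femur", (0.0, 0.0, 0.0))
    attach_B: tuple = ("patella", (0.0, 0.0, 0.0))
    printed_damping_sign: bool = False

    def __post_init__(self):
        if self.K <= 0 or self.L0 <= 0:
            raise ValueError("K and L0 must be > 0")
        if self.c is None:
            self.c = 0.01 * self.K
        if self.c < 0:
            raise ValueError("damping coefficient must be >= 0")
        self.attach_A = (self.attach_A[0], np.asarray(self.attach_A[1], float))
        self.attach_B = (self.attach_B[0], np.asarray(self.attach_B[1], float))

    def scaled(self, K=None, L0=None) -> "SpringDamperParams":
        """Copy with a new K and/or L0 (damping re-derived as 0.01 K unless
        it was customized)."""
        newK = self.K if K is None else float(K)
        c = None if abs(self.c - 0.01 * self.K) < 1e-12 else self.c
        return SpringDamperParams(K=newK, L0=self.L0 if L0 is None else float(L0),
                                  c=c, attach_A=(self.attach_A[0], self.attach_A[1].copy()),
                                  attach_B=(self.attach_B[0], self.attach_B[1].copy()),
                                  printed_damping_sign=self.printed_damping_sign)


def spring_damper_force(params: SpringDamperParams, L: float, Ldot: float) -> float:
    """Scalar tendon tension (N, positive pulls the ends together)."""
    if L <= 0:
        raise ValueError("spring length must be > 0")
    sign = -1.0 if params.printed_damping_sign else 1.0
    return params.K * (L - params.L0) + sign * params.c * Ldot


@dataclass
class FloresParams:
    """Flores contact parameters: generalized stiffness k_n (N/m^p), Hertz
    exponent p (3/2 for smooth non-conforming contact), restitution eps."""

    k_n: float = 1.0e7
    p: float = 1.5
    eps: float = 0.9

    def __post_init__(self):
        if self.k_n <= 0:
            raise ValueError("k_n must be > 0")
        if self.p <= 0:
            raise ValueError("Hertz exponent must be > 0")
        if not (0.0 < self.eps <= 1.0):
            raise ValueError("restitution must lie in (0, 1]")

    @property
    def dissipation_factor(self) -> float:
        """8 (1 - eps) / (5 eps)."""
        return 8.0 * (1.0 - self.eps) / (5.0 * self.eps)


def flores_magnitude(params: FloresParams, delta: float, delta_dot: float,
                     delta_dot0: Optional[float]) -> float:
    """Scalar normal force.  ``delta_dot0 is None`` disables the dissipative
    term (episode that started already in contact).  Clamped to >= 0."""
    if delta <= 0.0:
        return 0.0
    f = params.k_n * delta ** params.p
    if delta_dot0 is not None and delta_dot0 > 0.0:
        f *= 1.0 + params.dissipation_factor * delta_dot / delta_dot0
    return max(f, 0.0)


def flores_force(params: FloresParams, patch: ContactPatch) -> np.ndarray:
    """Contact force vector on the patella (N), along the patch normal."""
    mag = flores_magnitude(params, patch.delta, patch.delta_dot, patch.delta_dot0)
    return mag * patch.normal


def hertz_sphere_plane_stiffness(radius: float, E: float = 3.0e9,
                                 nu: float = 0.36) -> float:
    """Hertz stiffness k_n = 4/3 E* sqrt(R) for a sphere on a flat of the
    same material (bulk moduli; the bench default is much softer because
    the printed parts and load-cell mount add compliance)."""
    e_star = E / (2.0 * (1.0 - nu * nu))
    return 4.0 / 3.0 * e_star * np.sqrt(radius)
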