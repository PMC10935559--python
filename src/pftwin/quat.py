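"""Euler-parameter (unit quaternion, scalar-first) helpers for rigid-body
kinematics.  Conventions follow the classical multibody literature:

* rotation matrix ``A(e)`` maps body to world,
* body-frame angular velocity ``w' = 2 G(e) edot``,
* generalized torque from a body-frame torque ``n'`` is ``2 G(e)^T n'``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rotmat", "gmat", "emat", "skew", "quat_from_axis_angle",
           "quat_multiply", "quat_conj", "rotate", "quat_from_matrix",
           "dAs_de", "omega_body_to_edot", "edot_to_omega_body", "slerp_sign"]


def skew(v):
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def rotmat(e):
    """Body-to-world rotation matrix from a unit quaternion (e0, e1, e2, e3)."""
    e0, e1, e2, e3 = e
    return np.array([
        [e0*e0 + e1*e1 - e2*e2 - e3*e3, 2*(e1*e2 - e0*e3), 2*(e1*e3 + e0*e2)],
        [2*(e1*e2 + e0*e3), e0*e0 - e1*e1 + e2*e2 - e3*e3, 2*(e2*e3 - e0*e1)],
        [2*(e1*e3 - e0*e2), 2*(e2*e3 + e0*e1), e0*e0 - e1*e1 - e2*e2 + e3*e3],
    ])


def gmat(e):
    """G(e): 3x4, body-frame angular velocity w' = 2 G edot."""
    e0, e1, e2, e3 = e
    return np.array([
        [-e1,  e0,  e3, -e2],
        [-e2, -e3,  e0,  e1],
        [-e3,  e2, -e1,  e0],
    ])


def emat(e):
    """E(e): 3x4, world-frame angular velocity w = 2 E edot."""
    e0, e1, e2, e3 = e
    return np.array([
        [-e1,  e0, -e3,  e2],
        [-e2,  e3,  e0, -e1],
        [-e3, -e2,  e1,  e0],
    ])


def omega_body_to_edot(e, omega_body):
    return 0.5 * gmat(e).T @ omega_body


def edot_to_omega_body(e, edot):
    return 2.0 * gmat(e) @ edot


def quat_from_axis_angle(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    return np.concatenate([[np.cos(angle / 2.0)], np.sin(angle / 2.0) * axis])


def quat_multiply(a, b):
    a0, av = a[0], a[1:]
    b0, bv = b[0], b[1:]
    return np.concatenate([[a0 * b0 - av @ bv],
                           a0 * bv + b0 * av + np.cross(av, bv)])


def quat_conj(e):
    return np.array([e[0], -e[1], -e[2], -e[3]])


def rotate(e, v):
    return rotmat(e) @ v


def quat_from_matrix(R):
    """Unit quaternion (scalar-first) from a rotation matrix (Shepperd)."""
    R = np.asarray(R, float)
    tr = np.trace(R)
    if tr > 0:
        s = np.sqrt(tr + 1.0) * 2.0
        e = np.array([0.25 * s, (R[2, 1] - R[1, 2]) / s,
                      (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s])
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(max(1.0 + R[i, i] - R[j, j] - R[k, k], 0.0)) * 2.0
        q = np.empty(4)
        q[0] = (R[k, j] - R[j, k]) / s
        q[i + 1] = 0.25 * s
        q[j + 1] = (R[j, i] + R[i, j]) / s
        q[k + 1] = (R[k, i] + R[i, k]) / s
        e = q
    return e / np.linalg.norm(e)


def dAs_de(e, s):
    """3x4 Jacobian of A(e) s with respect to e (s a constant body vector)."""
    e0, e1, e2, e3 = (float(v) for v in e)
    s1, s2, s3 = (float(v) for v in s)
    d = e1 * s1 + e2 * s2 + e3 * s3
    J = np.empty((3, 4))
    J[0, 0] = e0 * s1 + e2 * s3 - e3 * s2
    J[1, 0] = e0 * s2 + e3 * s1 - e1 * s3
    J[2, 0] = e0 * s3 + e1 * s2 - e2 * s1
    J[0, 1] = d
    J[0, 2] = e1 * s2 - s1 * e2 + e0 * s3
    J[0, 3] = e1 * s3 - s1 * e3 - e0 * s2
    J[1, 1] = e2 * s1 - s2 * e1 - e0 * s3
    J[1, 2] = d
    J[1, 3] = e2 * s3 - s2 * e3 + e0 * s1
    J[2, 1] = e3 * s1 - s3 * e1 + e0 * s2
    J[2, 2] = e3 * s2 - s3 * e2 - e0 * s1
    J[2, 3] = d
    return 2.0 * J


def slerp_sign(quats):
    """Flip quaternion signs along a sequence for continuity."""
    q = np.array(quats, float)
    for i in range(1, len(q)):
        if q[i] @ q[i - 1] < 0:
            q[i] = -q[i]
    return q
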