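"""Small rotation / rigid-body helpers used by the kinematics modules.

Conventions
-----------
Lab frame: +X walking direction (anterior), +Y up, +Z subject's right.
Anatomical segment basis: x lateral (right), y anterior, z superior
(longitudinal).  Orientation matrices hold the segment axes as columns,
expressed in lab coordinates.

The clinical Euler sequence flexion -> adduction -> rotation corresponds to
an intrinsic rotation about the segment x, then mobile y, then mobile z
axis: ``R = Rx(a) @ Ry(b) @ Rz(c)``.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError

#: neutral (standing) anatomical orientation expressed in the lab frame:
#: x=right=labZ, y=anterior=labX, z=up=labY
NEUTRAL_AXES = np.array([[0.0, 1.0, 0.0],
                         [0.0, 0.0, 1.0],
                         [1.0, 0.0, 0.0]])

_EPS = 1e-12


def unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalize vectors along ``axis``; raises on (near-)zero length."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    if np.any(n < _EPS):
        raise DegenerateGeometryError("cannot normalize zero-length vector")
    return v / n


def rot_x(deg):
    """Rotation matrices about the local x axis; broadcasts over ``deg``."""
    a = np.deg2rad(np.asarray(deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 0, 0] = 1.0
    out[..., 1, 1] = c
    out[..., 1, 2] = -s
    out[..., 2, 1] = s
    out[..., 2, 2] = c
    return out


def rot_y(deg):
    a = np.deg2rad(np.asarray(deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 1, 1] = 1.0
    out[..., 0, 0] = c
    out[..., 0, 2] = s
    out[..., 2, 0] = -s
    out[..., 2, 2] = c
    return out


def rot_z(deg):
    a = np.deg2rad(np.asarray(deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 2, 2] = 1.0
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    return out


def compose_xyz(flexion, adduction, rotation) -> np.ndarray:
    """``Rx(flexion) @ Ry(adduction) @ Rz(rotation)`` (degrees in)."""
    return rot_x(flexion) @ rot_y(adduction) @ rot_z(rotation)


def decompose_xyz(R: np.ndarray):
    """Inverse of :func:`compose_xyz`.

    Returns ``(a, b, c, gimbal)`` in degrees with ``b = asin(R[0, 2])``.
    ``gimbal`` flags middle angles beyond 89 deg where a and c become
    ill-conditioned; the decomposition is still returned, never raised.
    """
    R = np.asarray(R, dtype=float)
    sb = np.clip(R[..., 0, 2], -1.0, 1.0)
    b = np.arcsin(sb)
    a = np.arctan2(-R[..., 1, 2], R[..., 2, 2])
    c = np.arctan2(-R[..., 0, 1], R[..., 0, 0])
    gimbal = np.abs(sb) > np.sin(np.deg2rad(89.0))
    return np.rad2deg(a), np.rad2deg(b), np.rad2deg(c), gimbal


def wrap_angle(deg):
    """Wrap angles to the interval (-180, 180]."""
    return -((180.0 - np.asarray(deg, dtype=float)) % 360.0 - 180.0)


def angle_between(u: np.ndarray, v: np.ndarray, axis: int = -1):
    """Unsigned angle between vectors in degrees, in [0, 180]."""
    uu, vv = unit(u, axis=axis), unit(v, axis=axis)
    d = np.clip(np.sum(uu * vv, axis=axis), -1.0, 1.0)
    return np.rad2deg(np.arccos(d))


def kabsch(P: np.ndarray, Q: np.ndarray):
    """Best-fit rigid transform mapping point set ``P`` onto ``Q``.

    Both are (m, 3).  Returns ``(R, t)`` minimizing ``||R P + t - Q||``
    with ``det(R) = +1``.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, cq - R @ cp


def check_rotation(R: np.ndarray, tol: float = 1e-9) -> bool:
    """True when ``R`` is orthonormal with ``det = +1`` to ``tol``."""
    R = np.asarray(R, dtype=float)
    return (np.allclose(R.T @ R, np.eye(3), atol=tol)
            and abs(np.linalg.det(R) - 1.0) < max(tol, 1e-9))
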