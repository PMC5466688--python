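"""Euler-angle pose algebra for a three-circle (Eulerian cradle) sample mount.

An acquisition pose is a triple of Euler angles (psi, theta, phi), applied as
an intrinsic y-z'-y' rotation

    R(x) = R_y(psi) @ R_z(theta) @ R_y(phi),

with right-handed rotations,

    R_y(g) = [[cos g, 0, sin g], [0, 1, 0], [-sin g, 0, cos g]],
    R_z(g) = [[cos g, -sin g, 0], [sin g, cos g, 0], [0, 0, 1]].

The rotation carries the setup's sensitivity direction S (orthogonal to the
grating bars, in the grating plane) and beam direction T into the sample
frame: s(x) = R(x) @ S is the scattering orientation probed at pose x, and
t(x) = R(x) @ T is the direction along which the signal is integrated.

All angles are stored in degrees and normalized to (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Pose",
    "normalize_angle",
    "euler_rotation",
    "euler_rotation_batch",
    "pose_vectors",
    "minimal_rotation",
    "decompose_euler",
    "decompose_euler_batch",
]


def normalize_angle(angle):
    """Map angles (degrees) to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float) % 360.0
    a = np.where(a > 180.0, a - 360.0, a)
    return a if a.ndim else float(a)


@dataclass(frozen=True)
class Pose:
    """One acquisition pose: Euler angles in degrees (y, z', y' axes)."""

    psi: float
    theta: float
    phi: float

    def __post_init__(self):
        object.__setattr__(self, "psi", normalize_angle(self.psi))
        object.__setattr__(self, "theta", normalize_angle(self.theta))
        object.__setattr__(self, "phi", normalize_angle(self.phi))

    def as_tuple(self):
        return (self.psi, self.theta, self.phi)


def euler_rotation(pose: Pose) -> np.ndarray:
    """Rotation matrix R(x) = R_y(psi) R_z(theta) R_y(phi) for a pose."""
    return Rotation.from_euler(
        "YZY", [pose.psi, pose.theta, pose.phi], degrees=True
    ).as_matrix()


def euler_rotation_batch(psi, theta, phi) -> np.ndarray:
    """Stacked rotation matrices, shape (n, 3, 3), angles in degrees."""
    angles = np.stack(np.broadcast_arrays(psi, theta, phi), axis=-1)
    return Rotation.from_euler("YZY", angles, degrees=True).as_matrix()


def _check_unit(v, name):
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector")
    n = np.linalg.norm(v)
    if abs(n - 1.0) > 1e-9:
        raise ValueError(f"{name} must be a unit vector (|{name}| = {n:.3e})")
    return v / n


def pose_vectors(pose: Pose, S, T):
    """Sensitivity and tomographic vectors (s, t) = (R S, R T) at a pose.

    S and T must be orthonormal: the grating sensitivity lies in the detector
    plane, perpendicular to the beam.
    """
    S = _check_unit(S, "S")
    T = _check_unit(T, "T")
    if abs(S @ T) > 1e-8:
        raise ValueError("setup sensitivity S must be orthogonal to beam T")
    R = euler_rotation(pose)
    return R @ S, R @ T


def minimal_rotation(v1, v2) -> np.ndarray:
    """Minimal-angle rotation M with M @ v1 = v2 (axis v1 x v2, Rodrigues).

    Degenerate cases: v2 = v1 returns the identity; for antipodal v2 = -v1 a
    half-turn about a deterministic axis orthogonal to v1 is returned (the
    normalized rejection of [1,0,0] from v1, or of [0,1,0] when v1 is
    collinear with [1,0,0]).
    """
    v1 = _check_unit(v1, "v1")
    v2 = _check_unit(v2, "v2")
    axis = np.cross(v1, v2)
    sin_a = np.linalg.norm(axis)
    cos_a = float(np.clip(v1 @ v2, -1.0, 1.0))
    if sin_a < 1e-14:
        if cos_a > 0.0:
            return np.eye(3)
        # antipodal: 180 deg about a fixed orthogonal axis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(v1 @ ref) > 1.0 - 1e-9:
            ref = np.array([0.0, 1.0, 0.0])
        axis = ref - (ref @ v1) * v1
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    axis = axis / sin_a
    angle = np.arctan2(sin_a, cos_a)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def _yzy_branches(R: np.ndarray):
    """Both analytic y-z-y Euler branches of stacked rotation matrices.

    Works through the quaternion half-angle form, which is well conditioned
    everywhere: for q = q_y(psi) q_z(theta) q_y(phi) with sum/difference
    angles sigma = (psi+phi)/2, delta = (psi-phi)/2,

        w = cos(theta/2) cos(sigma),  y = cos(theta/2) sin(sigma),
        x = sin(theta/2) sin(delta),  z = sin(theta/2) cos(delta).

    Gimbal-degenerate matrices (theta = 0 or 180, where delta resp. sigma is
    unconstrained) put the whole y-rotation into phi and set psi = 0.  The
    second branch is (psi + 180, -theta, phi + 180), composing to the same
    matrix.  Returns arrays of shape (2, 3, n) in degrees.
    """
    R = np.asarray(R, dtype=float)
    quat = Rotation.from_matrix(R).as_quat()  # (..., [x, y, z, w])
    x, y, z, w = quat[..., 0], quat[..., 1], quat[..., 2], quat[..., 3]
    r_cos = np.hypot(w, y)  # cos(theta/2) >= 0
    r_sin = np.hypot(x, z)  # sin(theta/2) >= 0
    sigma = np.arctan2(y, w)
    delta = np.arctan2(x, z)
    # theta ~ 0: delta unconstrained -> pick psi = 0; theta ~ 180: sigma is.
    sigma = np.where(r_cos < 1e-12, -delta, sigma)
    delta = np.where(r_sin < 1e-12, -sigma, delta)
    theta = np.degrees(2.0 * np.arctan2(r_sin, r_cos))
    psi = np.degrees(sigma + delta)
    phi = np.degrees(sigma - delta)

    b1 = np.stack([psi, theta, phi])
    b2 = np.stack([psi + 180.0, -theta, phi + 180.0])
    branches = normalize_angle(np.stack([b1, b2]))  # (2, 3, n)
    return branches


def decompose_euler_batch(R: np.ndarray):
    """Euler angles (degrees) of stacked matrices, minimizing |psi|.

    Of the two analytic y-z-y branches the one with the smaller |psi| is
    returned, so that poses stay as close as possible to the mechanically
    accessible range of the first cradle circle.
    """
    branches = _yzy_branches(R)  # (2, 3, ...)
    pick = np.argmin(np.abs(branches[:, 0]), axis=0)
    out = np.take_along_axis(branches, pick[None, None], axis=0)[0]
    return out[0], out[1], out[2]


def decompose_euler(R: np.ndarray) -> Pose:
    """Pose of a single rotation matrix; see :func:`decompose_euler_batch`."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("R must be a 3x3 matrix")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
        raise ValueError("R must be a proper rotation matrix")
    psi, theta, phi = decompose_euler_batch(R[None])
    return Pose(float(psi[0]), float(theta[0]), float(phi[0]))
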