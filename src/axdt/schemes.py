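"""Construction of dark-field tomography acquisition schemes.

A scheme is an ordered list of Euler poses together with the setup vectors it
was designed for.  The constructions provided are:

* ``base_scheme`` -- the circular trajectory A(psi, theta, N) of conventional
  CT: N poses stepping phi by 180/N degrees at fixed (psi, theta).
* ``design_Y`` -- the rotationally-invariant trajectory Y(q, S, N): N poses
  whose sensitivity vector equals the target scattering orientation q while
  the tomographic vectors sweep the great circle orthogonal to q in equal
  steps of 180/N degrees.
* ``design_Z`` -- the full design Z(S, N): one Y-trajectory per target
  orientation of a hemisphere direction set (L * N poses).
* ``legacy_W`` -- the legacy Eulerian-cradle grid scheme W(N) with
  psi in {0, 20, 40}, theta in {0, 30, 60, 90} and N full-circle phi steps.
* ``truncate_scheme`` -- feasibility truncation to the mechanically
  reachable |psi| <= psi_max range (the cradle blocks the beam beyond it).
* ``measurable_fraction_sweep`` -- the fraction of Z(S(alpha), N) poses that
  survive truncation, swept over grating angle alpha and psi limit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    Pose,
    decompose_euler_batch,
    euler_rotation_batch,
    minimal_rotation,
)
from .sphere import DirectionSet

__all__ = [
    "AcquisitionScheme",
    "SetupLimits",
    "base_scheme",
    "design_Y",
    "design_Z",
    "legacy_W",
    "truncate_scheme",
    "sensitivity_from_alpha",
    "measurable_fraction_sweep",
    "write_scheme",
    "read_scheme",
]

DEFAULT_S = np.array([0.0, 1.0, 0.0])
DEFAULT_T = np.array([0.0, 0.0, 1.0])
Y_AXIS = np.array([0.0, 1.0, 0.0])


@dataclass(frozen=True)
class AcquisitionScheme:
    """An ordered pose list plus the setup it was designed for.

    ``poses`` is an (n, 3) array of (psi, theta, phi) in degrees.  When the
    scheme was built by the trajectory design, ``targets`` annotates each
    pose with its target scattering orientation q.
    """

    poses: np.ndarray
    S: np.ndarray
    T: np.ndarray
    label: str = ""
    targets: np.ndarray | None = None

    def __post_init__(self):
        poses = np.atleast_2d(np.asarray(self.poses, dtype=float))
        if poses.shape[1] != 3:
            raise ValueError("poses must be an (n, 3) array of Euler angles")
        object.__setattr__(self, "poses", poses)
        object.__setattr__(self, "S", np.asarray(self.S, dtype=float))
        object.__setattr__(self, "T", np.asarray(self.T, dtype=float))
        if abs(self.S @ self.T) > 1e-8:
            raise ValueError("setup sensitivity S must be orthogonal to beam T")
        if self.targets is not None:
            t = np.asarray(self.targets, dtype=float)
            if t.shape != poses.shape:
                raise ValueError("targets must be one unit vector per pose")
            object.__setattr__(self, "targets", t)

    def __len__(self):
        return len(self.poses)

    @property
    def psi(self):
        return self.poses[:, 0]

    def pose_list(self):
        return [Pose(*row) for row in self.poses]

    def rotations(self) -> np.ndarray:
        """Stacked rotation matrices R(x), shape (n, 3, 3)."""
        p = self.poses
        return euler_rotation_batch(p[:, 0], p[:, 1], p[:, 2])

    def sensitivity_vectors(self) -> np.ndarray:
        """s(x) = R(x) S for every pose."""
        return self.rotations() @ self.S

    def tomographic_vectors(self) -> np.ndarray:
        """t(x) = R(x) T for every pose."""
        return self.rotations() @ self.T


@dataclass(frozen=True)
class SetupLimits:
    """Mechanical reachability of the cradle's first circle: |psi| <= psi_max."""

    psi_max: float = 40.0

    def __post_init__(self):
        if not 0.0 <= self.psi_max <= 90.0:
            raise ValueError("psi_max must lie in [0, 90] degrees")


def base_scheme(psi, theta, N, S=DEFAULT_S, T=DEFAULT_T) -> AcquisitionScheme:
    """Circular scheme A(psi, theta, N): phi in {0, 180/N, ..., 180 - 180/N}."""
    if N < 1:
        raise ValueError("N must be at least 1")
    phis = 180.0 * np.arange(N) / N
    poses = np.column_stack([np.full(N, float(psi)), np.full(N, float(theta)), phis])
    return AcquisitionScheme(poses, S, T, label=f"A({psi},{theta},{N})")


def design_Y(q, S, N, T=DEFAULT_T) -> AcquisitionScheme:
    """Trajectory Y(q, S, N) fully measuring the scattering orientation q.

    Each base pose x in A(0, 0, N) is mapped to the rotation

        R_final(x) = M([0,1,0], q) . R(x) . M(S, [0,1,0])

    where M(v1, v2) is the minimal rotation taking v1 to v2.  This makes
    s(y) = q for every pose while the tomographic vectors inherit the equal
    180/N-degree spacing of the base circle, transported to the great circle
    orthogonal to q.  Of the two Euler decompositions of R_final, the branch
    minimizing |psi| is used.
    """
    q = np.asarray(q, dtype=float)
    q = q / np.linalg.norm(q)
    M0 = minimal_rotation(Y_AXIS, q)
    MS = minimal_rotation(S, Y_AXIS)
    phis = 180.0 * np.arange(N) / N
    R_base = euler_rotation_batch(np.zeros(N), np.zeros(N), phis)
    R_final = np.einsum("ab,nbc,cd->nad", M0, R_base, MS)
    psi, theta, phi = decompose_euler_batch(R_final)
    poses = np.column_stack([psi, theta, phi])
    return AcquisitionScheme(
        poses, S, T, label=f"Y(q,S,{N})", targets=np.tile(q, (N, 1))
    )


def design_Z(directions: DirectionSet, S, N, T=DEFAULT_T, label="Z") -> AcquisitionScheme:
    """Full design Z(S, N): concatenated Y(q_l, S, N) over L hemisphere
    directions; L * N poses, each annotated with its target orientation."""
    if len(directions) == 0:
        raise ValueError("direction set must be nonempty")
    parts = [design_Y(q, S, N, T=T) for q in directions.points]
    poses = np.concatenate([p.poses for p in parts])
    targets = np.concatenate([p.targets for p in parts])
    return AcquisitionScheme(poses, S, T, label=f"{label}(S,{N})", targets=targets)


def legacy_W(N, S=np.array([1.0, 0.0, 0.0]), T=DEFAULT_T) -> AcquisitionScheme:
    """Legacy grid scheme W(N): 12 (psi, theta) combinations x N phi steps.

    psi in {0, 20, 40}, theta in {0, 30, 60, 90}, phi stepping the full
    circle by 360/N.  Vertical grating alignment (S = [1, 0, 0]) is the
    configuration this scheme was historically used with.
    """
    if N < 1:
        raise ValueError("N must be at least 1")
    phis = 360.0 * np.arange(N) / N
    rows = [
        (psi, theta, phi)
        for psi in (0.0, 20.0, 40.0)
        for theta in (0.0, 30.0, 60.0, 90.0)
        for phi in phis
    ]
    return AcquisitionScheme(np.array(rows), S, T, label=f"W({N})")


def truncate_scheme(scheme: AcquisitionScheme, limits: SetupLimits) -> AcquisitionScheme:
    """Keep only the mechanically reachable poses with |psi| <= psi_max.

    The boundary is inclusive; psi is rounded to 1e-6 degrees first so the
    kept set does not depend on floating-point branch noise.
    """
    psi = np.round(scheme.psi, 6)
    keep = np.abs(psi) <= limits.psi_max
    return replace(
        scheme,
        poses=scheme.poses[keep],
        targets=None if scheme.targets is None else scheme.targets[keep],
        label=f"{scheme.label}|psi<={limits.psi_max:g}",
    )


def sensitivity_from_alpha(alpha) -> np.ndarray:
    """Setup sensitivity S(alpha) = [cos a, -sin a, 0] in the grating plane.

    alpha is the angle between the sensitivity direction and the vertical
    [1, 0, 0] axis: 0 for vertical gratings, 45 for diagonal (printed as
    [0.7071, -0.7071, 0]), 90 for horizontal.
    """
    if not 0.0 <= alpha <= 90.0:
        raise ValueError("alpha must lie in [0, 90] degrees")
    a = np.radians(alpha)
    return np.array([np.cos(a), -np.sin(a), 0.0])


def measurable_fraction_sweep(directions, N, alphas, psi_maxes) -> np.ndarray:
    """Fraction of Z(S(alpha), N) poses with |psi| <= psi_max.

    Returns a matrix of shape (len(alphas), len(psi_maxes)) with entries in
    [0, 1]; each row shares one scheme construction, columns only threshold
    the pose angles.
    """
    alphas = np.atleast_1d(np.asarray(alphas, dtype=float))
    psi_maxes = np.atleast_1d(np.asarray(psi_maxes, dtype=float))
    if alphas.size == 0 or psi_maxes.size == 0:
        raise ValueError("alpha and psi_max grids must be nonempty")
    out = np.empty((len(alphas), len(psi_maxes)))
    for i, a in enumerate(alphas):
        Z = design_Z(directions, sensitivity_from_alpha(a), N)
        psi = np.abs(np.round(Z.psi, 6))
        out[i] = np.mean(psi[:, None] <= psi_maxes[None, :], axis=0)
    return out


def write_scheme(scheme: AcquisitionScheme, csv_path) -> Path:
    """Write a scheme as CSV plus a JSON sidecar with the setup metadata."""
    csv_path = Path(csv_path)
    n = len(scheme)
    df = pd.DataFrame(
        {
            "index": np.arange(n),
            "psi_deg": scheme.poses[:, 0],
            "theta_deg": scheme.poses[:, 1],
            "phi_deg": scheme.poses[:, 2],
        }
    )
    q = scheme.targets if scheme.targets is not None else np.full((n, 3), np.nan)
    df[["qx", "qy", "qz"]] = q
    df.to_csv(csv_path, index=False)
    sidecar = {
        "S": list(scheme.S),
        "T": list(scheme.T),
        "label": scheme.label,
        "n_poses": n,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return csv_path


def read_scheme(csv_path) -> AcquisitionScheme:
    """Read a scheme written by :func:`write_scheme`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    targets = df[["qx", "qy", "qz"]].to_numpy()
    if np.isnan(targets).all():
        targets = None
    return AcquisitionScheme(
        df[["psi_deg", "theta_deg", "phi_deg"]].to_numpy(),
        np.array(meta["S"]),
        np.array(meta["T"]),
        label=meta.get("label", ""),
        targets=targets,
    )
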