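"""Reconstruction of the coefficient field and null-space probing.

The linear model p = A eta is solved in the least-squares sense with CGLS
(conjugate gradients on the normal equations A^T A eta = A^T p), which is
deterministic, requires only the matrix-free operator, and monotonically
reduces the data residual ||p - A eta||.

The null space (kernel) of A collects coefficient fields invisible to the
measurements: A(w + v) = A w for v in ker(A).  One kernel component is
probed by driving ||A v|| towards zero from the uniform isotropic start
(eta_0^0 = 0.01 in every voxel, all other coefficients zero) -- i.e. CGLS on
the target p = 0.  For a well-posed scheme the iterates collapse to zero;
for a psi-truncated scheme the surviving structure shows which spherical
components (and where in the volume) the missing wedges leave undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_model import (
    AXDTOperator,
    Geometry,
    SphericalHarmonicsField,
    WeightModel,
)
from .sphere import DirectionSet, sh_eval

__all__ = [
    "SolverConfig",
    "NullspaceProbe",
    "cgls",
    "cgls_solve",
    "project_nonnegative",
    "nullspace_component",
    "probe_field",
]


@dataclass(frozen=True)
class SolverConfig:
    """CGLS controls: iteration cap, relative-residual stop, RNG seed."""

    max_iterations: int = 50
    tolerance: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


def cgls(op: AXDTOperator, b: np.ndarray, x0: np.ndarray | None = None,
         config: SolverConfig = SolverConfig(), keep_history: bool = False):
    """CGLS iterations for min ||A x - b||; returns (x, residuals[, iterates]).

    ``residuals`` holds ||b - A x|| per iterate including the start.  Raises
    on divergence (residual growing beyond 10x its starting value), which
    for a consistent geometry indicates a broken operator.
    """
    b = np.asarray(b, dtype=float).reshape(op.range_shape)
    x = np.zeros(op.domain_shape) if x0 is None else np.array(x0, dtype=float)
    r = b - op.apply(x)
    s = op.adjoint(r)
    p = s.copy()
    gamma = float((s * s).sum())
    res0 = float(np.linalg.norm(r))
    residuals = [res0]
    iterates = [x.copy()] if keep_history else None
    scale = float((s * s).sum()) ** 0.5
    for _ in range(config.max_iterations):
        if gamma == 0.0:
            break
        q = op.apply(p)
        qq = float((q * q).sum())
        if qq == 0.0:
            break
        alpha = gamma / qq
        x = x + alpha * p
        r = r - alpha * q
        res = float(np.linalg.norm(r))
        residuals.append(res)
        if keep_history:
            iterates.append(x.copy())
        if res > 10.0 * (res0 + 1e-300):
            raise RuntimeError("CGLS diverged: residual grew beyond 10x")
        s = op.adjoint(r)
        gamma_new = float((s * s).sum())
        if gamma_new**0.5 <= config.tolerance * max(scale, 1e-300):
            gamma = gamma_new
            break
        beta = gamma_new / gamma
        gamma = gamma_new
        p = s + beta * p
    if keep_history:
        return x, np.array(residuals), iterates
    return x, np.array(residuals)


def cgls_solve(scheme, model: WeightModel, p_data, config: SolverConfig = SolverConfig(),
               geometry: Geometry | None = None,
               nonnegative: bool = False) -> SphericalHarmonicsField:
    """Least-squares coefficient field from log-domain projections p.

    ``p_data`` may be a ProjectionStack or a raw (n_poses, nu, nv) array (a
    raw array requires ``geometry``).  ``nonnegative`` applies the isotropic
    lift of :func:`project_nonnegative` to the solution (off by default; the
    plain model is unconstrained least squares).
    """
    if geometry is None:
        geometry = getattr(p_data, "geometry", None)
        if geometry is None:
            raise ValueError("geometry required when p_data is a raw array")
    p = p_data.p if hasattr(p_data, "p") else np.asarray(p_data, dtype=float)
    op = AXDTOperator(scheme, model, geometry)
    x, _ = cgls(op, p, config=config)
    field = SphericalHarmonicsField(x, geometry.vol_spacing, model.basis)
    return project_nonnegative(field) if nonnegative else field


def project_nonnegative(field: SphericalHarmonicsField,
                        grid: DirectionSet | None = None) -> SphericalHarmonicsField:
    """Isotropic lift making every voxel's spherical function nonnegative.

    Where the function dips below zero (sampled on a hemisphere grid), the
    isotropic coefficient is raised just enough to lift the minimum to
    zero.  This preserves each voxel's anisotropy exactly and is the
    mildest correction consistent with a physical (nonnegative) scattering
    profile.
    """
    from .sphere import fibonacci_hemisphere

    grid = grid or fibonacci_hemisphere(500)
    Y = sh_eval(field.basis, grid.points)
    flat = field.coeffs.reshape(-1, field.coeffs.shape[-1])
    minima = (flat @ Y.T).min(axis=1)
    lift = np.where(minima < 0.0, -minima, 0.0) * np.sqrt(4.0 * np.pi)
    coeffs = flat.copy()
    coeffs[:, 0] += lift
    return SphericalHarmonicsField(coeffs.reshape(field.coeffs.shape),
                                   field.spacing, field.basis)


@dataclass
class NullspaceProbe:
    """Result of one kernel-component estimation run."""

    field: SphericalHarmonicsField        # final iterate
    first_iteration: SphericalHarmonicsField  # iterate after one CG step
    residuals: np.ndarray                 # ||A v_i|| history

    @staticmethod
    def initial_field(geometry: Geometry, model: WeightModel,
                      level: float = 0.01) -> np.ndarray:
        """Uniform isotropic start: eta_0^0 = level everywhere, rest zero."""
        v0 = np.zeros(tuple(geometry.vol_shape) + (len(model.basis),))
        v0[..., 0] = level
        return v0


def nullspace_component(scheme, model: WeightModel, geometry: Geometry | None = None,
                        n_iter: int = 10, level: float = 0.01) -> NullspaceProbe:
    """Drive ||A v|| to its minimum from the uniform isotropic start.

    Default geometry is the 50x50x50 volume / 100x100 detector probing
    setup; the iterate after the first CG step is retained separately for
    visualization of the per-orientation missing-wedge structure.
    """
    if geometry is None:
        geometry = Geometry((50, 50, 50), 1.0, (100, 100), 1.0)
    op = AXDTOperator(scheme, model, geometry)
    v0 = NullspaceProbe.initial_field(geometry, model, level)
    cfg = SolverConfig(max_iterations=n_iter, tolerance=1e-12)
    x, residuals, iterates = cgls(op, np.zeros(op.range_shape), x0=v0,
                                  config=cfg, keep_history=True)
    first = iterates[1] if len(iterates) > 1 else iterates[0]
    spacing = geometry.vol_spacing
    return NullspaceProbe(
        SphericalHarmonicsField(x, spacing, model.basis),
        SphericalHarmonicsField(first, spacing, model.basis),
        residuals,
    )


def probe_field(field: SphericalHarmonicsField, directions: DirectionSet):
    """Evaluate the spherical function at probe directions, per voxel.

    Returns ``(volumes, maps)``: volumes has shape (nx, ny, nz, L) with the
    value of the voxel's spherical function at each q_l; maps is the mean
    over the y axis (one 2D x-z image per direction), matching the usual
    per-orientation null-space visualization.
    """
    Y = sh_eval(field.basis, directions.points)  # (L, n_coeff)
    volumes = field.coeffs @ Y.T
    maps = volumes.mean(axis=1)  # average over y -> (nx, nz, L)
    return volumes, maps
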