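"""The dark-field measurement model and its matrix-free system operator.

Per voxel the scattering profile is a spherical function expanded in real
even-degree spherical harmonics (coefficients eta_k^m, degree <= K).  A
pose-dependent weighting function h(q, s, t) encodes how strongly scattering
along q contributes to the dark-field signal when the sensitivity vector is
s and the beam direction is t.  The measured dark-field transmission at pose
x is

    d(x) = exp( -(1/4pi) sum_km h_k^m(s(x), t(x)) * integral_ray eta_k^m )

so the negative log p = -ln d is linear in the coefficient volumes:

    p = sum_km W_k^m P eta_k^m = A eta

with P the parallel-beam line-integral operator and W_k^m diagonal weighting
per pose.  ``AXDTOperator`` applies A and its adjoint matrix-free; the inner
per-pose projection collapses the coefficient volumes into a single weighted
volume first (h_k^m is constant per pose), so each pose costs one volume
combination plus one scalar projection.

The default weighting form is h(q, s, t) = <q,s>^2 (1 - <q,t>^2): maximal
(= 1) for scattering along the sensitivity direction, zero along the beam,
and band-limited at degree 4 so the K = 4 model represents it exactly.  The
form is pluggable through ``WeightModel``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import h5py

from ._projector import joseph_backproject, joseph_project
from .schemes import AcquisitionScheme
from .sphere import SHBasis, gauss_sphere_quadrature, sh_eval

__all__ = [
    "Geometry",
    "WeightModel",
    "SphericalHarmonicsField",
    "ProjectionStack",
    "weight_coeffs",
    "weight_coeffs_batch",
    "line_project",
    "line_backproject",
    "AXDTOperator",
    "apply_A",
    "adjoint_A",
    "forward_darkfield",
    "save_projections",
    "load_projections",
    "save_field",
    "load_field",
]


@dataclass(frozen=True)
class Geometry:
    """Volume lattice and detector raster, both centered on the origin.

    The volume is an isotropic voxel grid fixed in the sample frame; the
    detector reference axes are [1,0,0] (rows) and [0,1,0] (columns),
    rotated by R(x) together with the beam.  Parallel-beam geometry.
    """

    vol_shape: tuple = (32, 32, 32)
    vol_spacing: float = 1.0
    det_shape: tuple = (48, 48)
    det_spacing: float = 1.0

    def __post_init__(self):
        if len(self.vol_shape) != 3 or min(self.vol_shape) < 1:
            raise ValueError("vol_shape must be three positive integers")
        if len(self.det_shape) != 2 or min(self.det_shape) < 1:
            raise ValueError("det_shape must be two positive integers")
        if self.vol_spacing <= 0 or self.det_spacing <= 0:
            raise ValueError("spacings must be positive")


# -- weighting function ------------------------------------------------------

def _h_cos2_sin2(q, s, t):
    """h(q,s,t) = <q,s>^2 (1 - <q,t>^2); q may be (n,3)."""
    return (q @ s) ** 2 * (1.0 - (q @ t) ** 2)


_WEIGHT_FORMS = {"cos2_sin2": _h_cos2_sin2}


@dataclass(frozen=True)
class WeightModel:
    """Pose weighting function h and the basis its coefficients live in."""

    form: str = "cos2_sin2"
    basis: SHBasis = dc_field(default_factory=SHBasis)

    def __post_init__(self):
        if self.form not in _WEIGHT_FORMS:
            raise ValueError(f"unknown weighting form {self.form!r}")

    def __call__(self, q, s, t):
        return _WEIGHT_FORMS[self.form](np.asarray(q, float), s, t)


_QUAD_CACHE: dict = {}


def _weight_quadrature(basis: SHBasis):
    # products of two degree-K functions need degree-2K exactness
    key = basis.K
    if key not in _QUAD_CACHE:
        quad = gauss_sphere_quadrature(2 * basis.K)
        Y = sh_eval(basis, quad.points)
        _QUAD_CACHE[key] = (quad.points, quad.weights, Y)
    return _QUAD_CACHE[key]


def weight_coeffs(model: WeightModel, s, t) -> np.ndarray:
    """Spherical-harmonics coefficients of q -> h(q, s, t).

    Exact (to quadrature precision) for any form band-limited at the basis
    degree; s and t must be orthonormal.
    """
    return weight_coeffs_batch(model, np.asarray(s, float)[None],
                               np.asarray(t, float)[None])[0]


def weight_coeffs_batch(model: WeightModel, svecs, tvecs) -> np.ndarray:
    """Coefficients for many (s, t) pairs at once; shape (n, n_coeff)."""
    svecs = np.atleast_2d(np.asarray(svecs, float))
    tvecs = np.atleast_2d(np.asarray(tvecs, float))
    if np.any(np.abs(np.einsum("ij,ij->i", svecs, tvecs)) > 1e-8):
        raise ValueError("sensitivity and beam vectors must be orthogonal")
    pts, w, Y = _weight_quadrature(model.basis)
    hvals = (pts @ svecs.T) ** 2 * (1.0 - (pts @ tvecs.T) ** 2) \
        if model.form == "cos2_sin2" else \
        np.stack([model(pts, s, t) for s, t in zip(svecs, tvecs)], axis=1)
    return (Y.T @ (w[:, None] * hvals)).T


# -- containers --------------------------------------------------------------

@dataclass
class SphericalHarmonicsField:
    """Per-voxel real even-degree SH coefficients on an isotropic lattice."""

    coeffs: np.ndarray  # (nx, ny, nz, n_coeff)
    spacing: float = 1.0
    basis: SHBasis = dc_field(default_factory=SHBasis)

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 4 or self.coeffs.shape[3] != len(self.basis):
            raise ValueError(
                f"coeffs must have shape (nx, ny, nz, {len(self.basis)})"
            )

    @property
    def vol_shape(self):
        return self.coeffs.shape[:3]

    def evaluate(self, q) -> np.ndarray:
        """Spherical-function values at direction(s) q, per voxel."""
        Y = sh_eval(self.basis, q)
        return self.coeffs @ (Y.T if Y.ndim == 2 else Y)


@dataclass
class ProjectionStack:
    """Per-pose dark-field images d in (0, 1] and p = -ln d >= 0."""

    p: np.ndarray  # (n_poses, nu, nv)
    scheme: AcquisitionScheme
    geometry: Geometry

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 3 or len(self.p) != len(self.scheme):
            raise ValueError("p must be one detector image per pose")

    @property
    def d(self) -> np.ndarray:
        return np.exp(-self.p)


# -- projector ---------------------------------------------------------------

def line_project(volume, R, geometry: Geometry) -> np.ndarray:
    """Parallel-beam line integrals of a scalar volume at rotation R.

    Rays run along t = R @ [0,0,1] through every detector pixel; detector
    axes are R @ [1,0,0] and R @ [0,1,0].  Joseph-style interpolating ray
    tracing; linear in the volume and exactly adjoint to
    :func:`line_backproject`.
    """
    volume = np.ascontiguousarray(volume, dtype=np.float64)
    if volume.shape != tuple(geometry.vol_shape):
        raise ValueError("volume shape does not match geometry")
    return _project_pose(volume, np.asarray(R, float), geometry)


def line_backproject(image, R, geometry: Geometry) -> np.ndarray:
    """Adjoint of :func:`line_project` (smearing along the rays)."""
    image = np.ascontiguousarray(image, dtype=np.float64)
    if image.shape != tuple(geometry.det_shape):
        raise ValueError("image shape does not match geometry")
    return _backproject_pose(image, np.asarray(R, float), geometry)


def _pose_frame(R, geometry):
    t = R @ np.array([0.0, 0.0, 1.0])
    eu = R @ np.array([1.0, 0.0, 0.0])
    ev = R @ np.array([0.0, 1.0, 0.0])
    axis = int(np.argmax(np.abs(t)))
    perm = (axis, (axis + 1) % 3, (axis + 2) % 3)
    return t[list(perm)], eu[list(perm)], ev[list(perm)], perm


def _project_pose(volume, R, geometry):
    t, eu, ev, perm = _pose_frame(R, geometry)
    volp = np.ascontiguousarray(np.transpose(volume, perm))
    nu, nv = geometry.det_shape
    out = np.zeros((nu, nv))
    joseph_project(
        volp, geometry.vol_spacing, eu, ev, t,
        geometry.det_spacing, out,
    )
    return out


def _backproject_pose(image, R, geometry):
    t, eu, ev, perm = _pose_frame(R, geometry)
    shp = tuple(np.array(geometry.vol_shape)[list(perm)])
    volp = np.zeros(shp)
    joseph_backproject(
        volp, geometry.vol_spacing, eu, ev, t,
        geometry.det_spacing, image,
    )
    inv = np.argsort(perm)
    return np.ascontiguousarray(np.transpose(volp, inv))


# -- full system operator ----------------------------------------------------

class AXDTOperator:
    """Matrix-free full system operator A (and adjoint) of the linear model.

    Couples all coefficient volumes: for K = 4 the unknown is 15 volumes
    (2^K - 1 more than a scalar CT problem).  The 1/(4 pi) normalization of
    the measurement model is kept inside the operator so coefficient fields
    are comparable across weighting forms.
    """

    def __init__(self, scheme: AcquisitionScheme, model: WeightModel,
                 geometry: Geometry):
        self.scheme = scheme
        self.model = model
        self.geometry = geometry
        self.basis = model.basis
        self.rotations = scheme.rotations()
        svecs = self.rotations @ scheme.S
        tvecs = self.rotations @ scheme.T
        # (n_poses, n_coeff) weights, 1/4pi folded in
        self.H = weight_coeffs_batch(model, svecs, tvecs) / (4.0 * np.pi)

    @property
    def domain_shape(self):
        return tuple(self.geometry.vol_shape) + (len(self.basis),)

    @property
    def range_shape(self):
        return (len(self.scheme),) + tuple(self.geometry.det_shape)

    _chunk = 64  # poses per BLAS batch in the coefficient contractions

    def apply(self, coeffs: np.ndarray) -> np.ndarray:
        """p = A eta for a coefficient array of shape ``domain_shape``."""
        coeffs = np.asarray(coeffs, dtype=float).reshape(self.domain_shape)
        flat = coeffs.reshape(-1, len(self.basis))
        vol_shape = tuple(self.geometry.vol_shape)
        out = np.empty(self.range_shape)
        for lo in range(0, len(self.scheme), self._chunk):
            hi = min(lo + self._chunk, len(self.scheme))
            combined = flat @ self.H[lo:hi].T  # (n_vox, chunk)
            for i in range(lo, hi):
                out[i] = _project_pose(
                    combined[:, i - lo].reshape(vol_shape),
                    self.rotations[i], self.geometry,
                )
        return out

    def adjoint(self, p: np.ndarray) -> np.ndarray:
        """eta = A^T p; returns an array of shape ``domain_shape``."""
        p = np.asarray(p, dtype=float).reshape(self.range_shape)
        n_vox = int(np.prod(self.geometry.vol_shape))
        out = np.zeros((n_vox, len(self.basis)))
        B = np.empty((self._chunk, n_vox))
        for lo in range(0, len(self.scheme), self._chunk):
            hi = min(lo + self._chunk, len(self.scheme))
            for i in range(lo, hi):
                B[i - lo] = _backproject_pose(
                    p[i], self.rotations[i], self.geometry
                ).ravel()
            out += B[: hi - lo].T @ self.H[lo:hi]
        return out.reshape(self.domain_shape)


def apply_A(coeffs, scheme, model, geometry) -> np.ndarray:
    """Functional form of ``AXDTOperator(...).apply``."""
    return AXDTOperator(scheme, model, geometry).apply(coeffs)


def adjoint_A(p, scheme, model, geometry) -> np.ndarray:
    """Functional form of ``AXDTOperator(...).adjoint``."""
    return AXDTOperator(scheme, model, geometry).adjoint(p)


def forward_darkfield(field: SphericalHarmonicsField, scheme: AcquisitionScheme,
                      model: WeightModel | None = None,
                      geometry: Geometry | None = None) -> ProjectionStack:
    """Simulate dark-field projections of a coefficient field.

    Per pose, d = exp(-(1/4pi) sum_km h_k^m * P eta_k^m); the stack stores
    p = -ln d alongside.
    """
    model = model or WeightModel(basis=field.basis)
    if len(model.basis) != field.coeffs.shape[3]:
        raise ValueError("field basis does not match the weighting model")
    if geometry is None:
        geometry = Geometry(vol_shape=field.vol_shape,
                            vol_spacing=field.spacing)
    if tuple(geometry.vol_shape) != field.vol_shape:
        raise ValueError("field and geometry volume shapes differ")
    op = AXDTOperator(scheme, model, geometry)
    return ProjectionStack(op.apply(field.coeffs), scheme, geometry)


# -- file formats ------------------------------------------------------------

def save_projections(path, stack: ProjectionStack) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("p", data=stack.p)
        f.create_dataset("d", data=stack.d)
        f.create_dataset("poses", data=stack.scheme.poses)
        f.attrs["S"] = stack.scheme.S
        f.attrs["T"] = stack.scheme.T
        f.attrs["label"] = stack.scheme.label
        f.attrs["vol_shape"] = stack.geometry.vol_shape
        f.attrs["vol_spacing"] = stack.geometry.vol_spacing
        f.attrs["det_shape"] = stack.geometry.det_shape
        f.attrs["det_spacing"] = stack.geometry.det_spacing


def load_projections(path) -> ProjectionStack:
    with h5py.File(path, "r") as f:
        scheme = AcquisitionScheme(
            f["poses"][()], f.attrs["S"], f.attrs["T"],
            label=str(f.attrs["label"]),
        )
        geometry = Geometry(
            tuple(int(v) for v in f.attrs["vol_shape"]),
            float(f.attrs["vol_spacing"]),
            tuple(int(v) for v in f.attrs["det_shape"]),
            float(f.attrs["det_spacing"]),
        )
        return ProjectionStack(f["p"][()], scheme, geometry)


def save_field(path, field: SphericalHarmonicsField) -> None:
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        affine = np.diag([field.spacing] * 3 + [1.0])
        nib.save(nib.Nifti1Image(field.coeffs, affine), path)
    else:
        with h5py.File(path, "w") as f:
            f.create_dataset("coeffs", data=field.coeffs)
            f.attrs["spacing"] = field.spacing
            f.attrs["K"] = field.basis.K


def load_field(path) -> SphericalHarmonicsField:
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        img = nib.load(path)
        coeffs = np.asarray(img.dataobj, dtype=float)
        spacing = float(img.affine[0, 0])
        K = {1: 0, 6: 2, 15: 4, 28: 6}[coeffs.shape[3]]
        return SphericalHarmonicsField(coeffs, spacing, SHBasis(K))
    with h5py.File(path, "r") as f:
        return SphericalHarmonicsField(
            f["coeffs"][()], float(f.attrs["spacing"]),
            SHBasis(int(f.attrs["K"])),
        )
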