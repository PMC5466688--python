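"""Scheme-quality metrics and orientation extraction.

``extract_orientations`` reduces a reconstructed spherical-function field to
one unit vector per voxel: the direction extremizing the voxel's spherical
function on a dense search grid.  Fibers scatter least along their axis, so
``structure`` mode (the minimizer) tracks fiber axes, while ``scattering``
mode (the maximizer) tracks the dominant scattering direction.

``experimental_metric`` compares two orientation fields over a region of
interest as the mean absolute inner product EM = (1/I) sum_i |<U_i, V_i>|:
1 for identical orientations up to sign, 0 for everywhere-orthogonal ones.

``coverage_surrogate`` is this package's stand-in for a published
angular-coverage score whose exact formula is defined elsewhere: it bins the
sensitivity vectors of a scheme onto a hemisphere direction set and, per
bin, measures which angular sectors of the great circle orthogonal to the
bin direction are hit by the corresponding tomographic vectors.  Its
absolute values are package-specific; only relative rankings are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schemes import AcquisitionScheme
from .sphere import (
    DirectionSet,
    fibonacci_hemisphere,
    hemisphere,
    load_tdesign_56,
    sh_eval,
)

__all__ = [
    "OrientationField",
    "extract_orientations",
    "experimental_metric",
    "coverage_surrogate",
    "save_orientations",
    "load_orientations",
]


@dataclass
class OrientationField:
    """Per-voxel unit vectors with a validity mask.

    Orientations are axial (u and -u are the same orientation); vectors on
    masked-out voxels are undefined and excluded from metrics.
    """

    vectors: np.ndarray  # (nx, ny, nz, 3)
    mask: np.ndarray     # (nx, ny, nz) bool

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.vectors.shape[-1] != 3 or self.vectors.shape[:-1] != self.mask.shape:
            raise ValueError("vectors must be (..., 3) matching the mask")
        norms = np.linalg.norm(self.vectors[self.mask], axis=-1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("defined orientation vectors must be unit length")


def extract_orientations(field, search_grid: DirectionSet | None = None,
                         mode: str = "structure",
                         degenerate_tol: float = 1e-9) -> OrientationField:
    """Per-voxel extremal direction of the reconstructed spherical function.

    ``mode='structure'`` returns the minimizer (fiber axis), ``'scattering'``
    the maximizer.  Voxels whose spherical function is constant over the
    grid within ``degenerate_tol`` (e.g. isotropic or empty voxels) are
    masked as undefined.  Ties break to the first grid index, so extraction
    is deterministic for a fixed grid.
    """
    if search_grid is None:
        search_grid = fibonacci_hemisphere(2000)
    if len(search_grid) == 0:
        raise ValueError("search grid must be nonempty")
    if mode not in ("structure", "scattering"):
        raise ValueError("mode must be 'structure' or 'scattering'")
    Y = sh_eval(field.basis, search_grid.points)  # (L, n_coeff)
    shape = field.coeffs.shape[:3]
    flat = field.coeffs.reshape(-1, field.coeffs.shape[-1])
    values = flat @ Y.T  # (n_vox, L)
    spread = values.max(axis=1) - values.min(axis=1)
    idx = values.argmin(axis=1) if mode == "structure" else values.argmax(axis=1)
    vectors = search_grid.points[idx].reshape(shape + (3,))
    mask = (spread > degenerate_tol).reshape(shape)
    vectors[~mask] = 0.0
    return OrientationField(vectors, mask)


def experimental_metric(X: OrientationField, ref: OrientationField,
                        roi: np.ndarray | None = None) -> float:
    """Mean absolute inner product of two orientation fields over a ROI.

    The ROI defaults to the voxels where both fields are defined; supplying
    a ROI restricts further.  Symmetric in its arguments and invariant to
    per-voxel sign flips; values lie in [0, 1].
    """
    valid = X.mask & ref.mask
    if roi is not None:
        valid = valid & np.asarray(roi, dtype=bool)
    if not valid.any():
        raise ValueError("empty region of interest")
    dots = np.einsum("ij,ij->i", X.vectors[valid], ref.vectors[valid])
    return float(np.mean(np.abs(dots)))


def coverage_surrogate(scheme: AcquisitionScheme,
                       sphere_bins: DirectionSet | None = None,
                       n_sectors: int = 18) -> float:
    """Fraction of tomographic sectors covered, averaged over sphere bins.

    Every pose is assigned to the bin direction closest (up to sign) to its
    sensitivity vector s(x); the pose's tomographic vector t(x) is projected
    onto the great circle orthogonal to the bin direction and lands in one
    of ``n_sectors`` half-circle sectors (t and -t are identified).  The
    score is the mean covered-sector fraction over all bins: 1 when every
    orientation's circle is fully swept, monotone non-decreasing under
    adding poses.
    """
    if len(scheme) == 0:
        raise ValueError("scheme must contain at least one pose")
    if sphere_bins is None:
        sphere_bins = hemisphere(load_tdesign_56())
    bins = sphere_bins.points
    s = scheme.sensitivity_vectors()
    t = scheme.tomographic_vectors()
    assign = np.abs(s @ bins.T).argmax(axis=1)
    covered = np.zeros((len(bins), n_sectors), dtype=bool)
    for b, q in enumerate(bins):
        sel = assign == b
        if not sel.any():
            continue
        # in-plane frame of the great circle orthogonal to q
        ref = np.array([1.0, 0.0, 0.0])
        if abs(q @ ref) > 1.0 - 1e-9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - (ref @ q) * q
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(q, e1)
        ang = np.arctan2(t[sel] @ e2, t[sel] @ e1) % np.pi  # axial
        sector = np.minimum((ang / np.pi * n_sectors).astype(int), n_sectors - 1)
        covered[b, sector] = True
    return float(covered.sum() / covered.size)


def save_orientations(path, field: OrientationField) -> None:
    """Write an orientation field as 4-component NIfTI (vector + mask) or,
    for a ``.csv`` path, one row of voxel indices and components per
    defined voxel."""
    path = str(path)
    if path.endswith(".csv"):
        import pandas as pd

        idx = np.argwhere(field.mask)
        vecs = field.vectors[field.mask]
        df = pd.DataFrame(
            np.column_stack([idx, vecs]),
            columns=["i", "j", "k", "ux", "uy", "uz"],
        )
        df[["i", "j", "k"]] = df[["i", "j", "k"]].astype(int)
        df.to_csv(path, index=False)
    else:
        import nibabel as nib

        data = np.concatenate(
            [field.vectors, field.mask[..., None].astype(float)], axis=-1
        )
        nib.save(nib.Nifti1Image(data, np.eye(4)), path)


def load_orientations(path) -> OrientationField:
    """Read a 4-component NIfTI orientation field written by
    :func:`save_orientations`."""
    import nibabel as nib

    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if data.ndim != 4 or data.shape[-1] != 4:
        raise ValueError("expected a 4-component orientation volume")
    return OrientationField(data[..., :3], data[..., 3] > 0.5)
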