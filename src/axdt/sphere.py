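"""Point sets, quadrature and real spherical harmonics on the unit sphere.

Dark-field scattering profiles are antipodally symmetric spherical functions,
so everything here is organized around symmetric (closed under q -> -q)
direction sets and even-degree harmonics.

Spherical harmonics convention
------------------------------
Real, orthonormal, Condon-Shortley-free harmonics built from the complex
orthonormal harmonics Y_k^m(theta, phi):

    Y_km(real) = Y_k^0                          m = 0
               = sqrt(2) (-1)^m Re(Y_k^m)       m > 0
               = sqrt(2) (-1)^m Im(Y_k^|m|)     m < 0

With this convention the Gram matrix over the sphere is the identity and
Y_0^0 = 1/sqrt(4 pi).  Only even degrees k in {0, 2, ..., K} are carried;
the even-degree basis for K = 4 has 15 = 2^4 - 1 functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "DirectionSet",
    "SHBasis",
    "load_tdesign_56",
    "hemisphere",
    "sh_eval",
    "sh_expand",
    "gauss_sphere_quadrature",
    "fibonacci_hemisphere",
]


@dataclass(frozen=True)
class DirectionSet:
    """A finite set of unit vectors, optionally with quadrature weights.

    ``symmetric`` declares closure under the antipodal map; it is validated
    on construction.
    """

    points: np.ndarray  # (n, 3)
    symmetric: bool = False
    weights: np.ndarray | None = None

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        norms = np.linalg.norm(pts, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("all directions must have unit norm")
        object.__setattr__(self, "points", pts / norms[:, None])
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(pts),):
                raise ValueError("weights must match the number of points")
            object.__setattr__(self, "weights", w)
        if self.symmetric and not _is_symmetric(self.points):
            raise ValueError("direction set is not closed under q -> -q")

    def __len__(self):
        return len(self.points)


def _is_symmetric(pts, tol=1e-9):
    for p in pts:
        if np.min(np.linalg.norm(pts + p, axis=1)) > tol:
            return False
    return True


def load_tdesign_56() -> DirectionSet:
    """The bundled symmetric 56-point spherical 9-design.

    28 antipodal pairs of uniformly distributed scattering orientations.
    The table is a synthetic stand-in computed by this package (numerical
    minimization of the even-degree harmonic moments, degrees 2-8; the mean
    of every degree 1-9 harmonic over the set vanishes to below 1e-8); its
    9-design property is validated by the test suite.
    """
    text = resources.files("axdt.data").joinpath("tdesign56.txt").read_text()
    pts = np.loadtxt(text.splitlines())
    if pts.shape != (56, 3):
        raise RuntimeError("packaged t-design table is corrupt")
    return DirectionSet(pts, symmetric=True)


def hemisphere(ds: DirectionSet) -> DirectionSet:
    """One representative per antipodal pair of a symmetric set.

    The representative is the member with positive z (positive y, then
    positive x, on ties), so the output covers a single half of the sphere.
    """
    if not ds.symmetric:
        raise ValueError("hemisphere reduction requires a symmetric set")
    keep = []
    for p in ds.points:
        key = next(c for c in (p[2], p[1], p[0]) if abs(c) > 1e-9)
        if key > 0:
            keep.append(p)
    out = np.array(keep)
    if 2 * len(out) != len(ds):
        raise ValueError("direction set has coincident or unpaired points")
    return DirectionSet(out, symmetric=False)


@dataclass(frozen=True)
class SHBasis:
    """Real even-degree spherical harmonics basis up to degree K."""

    K: int = 4
    indices: tuple = field(init=False)

    def __post_init__(self):
        if self.K < 0 or self.K % 2:
            raise ValueError("K must be a nonnegative even integer")
        idx = tuple(
            (k, m) for k in range(0, self.K + 1, 2) for m in range(-k, k + 1)
        )
        object.__setattr__(self, "indices", idx)

    def __len__(self):
        return len(self.indices)


def sh_eval(basis: SHBasis, q) -> np.ndarray:
    """Evaluate all basis functions at directions q; shape (..., n_coeff)."""
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    pts = np.atleast_2d(q)
    theta = np.arccos(np.clip(pts[:, 2], -1.0, 1.0))
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    out = np.empty((len(pts), len(basis)))
    for j, (k, m) in enumerate(basis.indices):
        y = sph_harm_y(k, abs(m), theta, phi)
        if m == 0:
            out[:, j] = y.real
        elif m > 0:
            out[:, j] = np.sqrt(2.0) * (-1.0) ** m * y.real
        else:
            out[:, j] = np.sqrt(2.0) * (-1.0) ** m * y.imag
    return out[0] if single else out


def gauss_sphere_quadrature(degree: int = 8) -> DirectionSet:
    """Product Gauss-Legendre x uniform-azimuth quadrature on the sphere.

    Exact for spherical polynomials up to the given degree; weights sum to
    4 pi.  Used for expanding band-limited functions (products of two
    degree-4 functions need degree-8 exactness).
    """
    n_polar = degree // 2 + 1
    n_az = degree + 1
    x, w = np.polynomial.legendre.leggauss(n_polar)
    az = 2.0 * np.pi * np.arange(n_az) / n_az
    sin_t = np.sqrt(1.0 - x**2)
    pts = np.stack(
        [
            np.outer(sin_t, np.cos(az)).ravel(),
            np.outer(sin_t, np.sin(az)).ravel(),
            np.outer(x, np.ones(n_az)).ravel(),
        ],
        axis=1,
    )
    weights = np.outer(w, np.full(n_az, 2.0 * np.pi / n_az)).ravel()
    return DirectionSet(pts, weights=weights)


def sh_expand(f, basis: SHBasis, quadrature: DirectionSet | None = None) -> np.ndarray:
    """Expansion coefficients c_km = sum_j w_j f(q_j) Y_km(q_j).

    ``f`` is either a callable mapping an (n, 3) array of directions to n
    values, or an array of values already sampled on the quadrature nodes.
    Exact for band-limited f of degree <= K when the quadrature integrates
    degree 2K (the default grid does).
    """
    if quadrature is None:
        quadrature = gauss_sphere_quadrature(2 * basis.K)
    if quadrature.weights is None:
        raise ValueError("quadrature DirectionSet must carry weights")
    vals = f(quadrature.points) if callable(f) else np.asarray(f, dtype=float)
    if vals.shape != (len(quadrature),):
        raise ValueError("sampled values do not match the quadrature nodes")
    Y = sh_eval(basis, quadrature.points)
    return Y.T @ (quadrature.weights * vals)


def fibonacci_hemisphere(n: int = 2000) -> DirectionSet:
    """n quasi-uniform directions on the upper hemisphere (z >= 0).

    Golden-angle lattice; used as a dense search grid for extracting
    extremal orientations from reconstructed spherical functions.
    """
    if n < 1:
        raise ValueError("n must be positive")
    i = np.arange(n)
    z = (i + 0.5) / n  # stratified in z over (0, 1)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    r = np.sqrt(1.0 - z**2)
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return DirectionSet(pts)
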