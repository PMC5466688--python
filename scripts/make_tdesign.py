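"""Regenerate the bundled symmetric spherical 9-design with 56 points.

A point set {q_j} u {-q_j} is a spherical t-design iff the equal-weight sum
of every spherical harmonic of degree 1..t vanishes.  Odd degrees vanish by
symmetry, so only even degrees k in {2,4,6,8} constrain the 28 free points.
By the addition theorem,

    sum_m |sum_j Y_k^m(q_j)|^2 = (2k+1)/(4pi) * sum_{j,j'} P_k(<q_j, q_j'>)

so we minimize F(Q) = sum_k (2k+1) sum_{jj'} P_k(Q Q^T) with an analytic
gradient, over unconstrained 3-vectors normalized to the sphere.  Seeded and
deterministic; the shipped table was produced by exactly this script.
"""
from pathlib import Path

import numpy as np
from numpy.polynomial import legendre
from scipy.optimize import minimize

DEGREES = [2, 4, 6, 8]
L = 28

Pk = {k: legendre.Legendre.basis(k) for k in DEGREES}
dPk = {k: Pk[k].deriv() for k in DEGREES}


def objective(x):
    V = x.reshape(L, 3)
    nrm = np.linalg.norm(V, axis=1, keepdims=True)
    Q = V / nrm
    C = np.clip(Q @ Q.T, -1.0, 1.0)
    F = 0.0
    G = np.zeros_like(Q)
    for k in DEGREES:
        w = 2 * k + 1
        F += w * Pk[k](C).sum()
        G += 2 * w * (dPk[k](C) @ Q)
    # project gradient to the sphere tangent, chain back to V
    GV = (G - (G * Q).sum(axis=1, keepdims=True) * Q) / nrm
    return F, GV.reshape(-1)


def moment_residual(Q):
    """max over even degrees 2..8 of sum_m |mean_j Y_k^m|^2 (should be ~0)."""
    C = np.clip(Q @ Q.T, -1.0, 1.0)
    return max(
        abs((2 * k + 1) / (4 * np.pi) * Pk[k](C).sum() / L**2)
        for k in DEGREES
    )


def main():
    rng = np.random.default_rng(0)
    best = None
    for attempt in range(40):
        V0 = rng.normal(size=(L, 3))
        res = minimize(objective, V0.reshape(-1), jac=True, method="L-BFGS-B",
                       options=dict(maxiter=20000, ftol=1e-18, gtol=1e-14))
        V = res.x.reshape(L, 3)
        Q = V / np.linalg.norm(V, axis=1, keepdims=True)
        r = moment_residual(Q)
        if best is None or r < best[0]:
            best = (r, Q)
        print(f"attempt {attempt}: F={res.fun:.3e} residual={r:.3e}")
        if r < 1e-22:
            break
    r, Q = best
    print("best residual:", r)
    out = Path(__file__).resolve().parents[1] / "src/axdt/data/tdesign56.txt"
    np.savetxt(out, np.vstack([Q, -Q]), fmt="%+.16e")
    print(f"saved 56 points to {out}")


if __name__ == "__main__":
    main()
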