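"""Joseph-style parallel-beam ray tracing kernels (numba-compiled).

Both kernels assume the caller has permuted the volume so that axis 0 is the
principal ray axis (|t0| is the largest component of the ray direction).
One interpolation plane is visited per axis-0 slab; within the plane the
contribution is bilinear in the two transverse axes.  The backprojector uses
the identical interpolation weights, so the pair passes the adjoint
dot-product identity to machine precision.

Coordinates: voxel (i0, i1, i2) is centered at ((i - (n-1)/2) * h) along each
axis; detector pixel (iu, iv) sits at u * e_u + v * e_v with
u = (iu - (nu-1)/2) * du.  Rays carry a path-length weight h / |t0| per slab.
"""

import numpy as np
from numba import njit


@njit(cache=False, fastmath=False)
def joseph_project(vol, h, eu, ev, t, det_spacing, out):
    n0, n1, n2 = vol.shape
    nu, nv = out.shape
    c0 = 0.5 * (n0 - 1)
    c1 = 0.5 * (n1 - 1)
    c2 = 0.5 * (n2 - 1)
    cu = 0.5 * (nu - 1)
    cv = 0.5 * (nv - 1)
    step = h / abs(t[0])
    # transverse grid coordinates are affine in the slab index k
    d1 = t[1] / t[0]
    d2 = t[2] / t[0]
    for iu in range(nu):
        u = (iu - cu) * det_spacing
        for iv in range(nv):
            v = (iv - cv) * det_spacing
            o0 = u * eu[0] + v * ev[0]
            o1 = u * eu[1] + v * ev[1]
            o2 = u * eu[2] + v * ev[2]
            # grid coords at slab k: g = (o + ((k-c0)*h - o0)/t0 * t)/h + c
            g1 = (o1 + (-c0 * h - o0) * d1) / h + c1
            g2 = (o2 + (-c0 * h - o0) * d2) / h + c2
            acc = 0.0
            for k in range(n0):
                i1 = int(np.floor(g1))
                i2 = int(np.floor(g2))
                f1 = g1 - i1
                f2 = g2 - i2
                if -1 <= i1 < n1 and -1 <= i2 < n2:
                    if i1 >= 0 and i2 >= 0:
                        acc += vol[k, i1, i2] * (1.0 - f1) * (1.0 - f2)
                    if i1 >= 0 and i2 + 1 < n2:
                        acc += vol[k, i1, i2 + 1] * (1.0 - f1) * f2
                    if i1 + 1 < n1 and i2 >= 0:
                        acc += vol[k, i1 + 1, i2] * f1 * (1.0 - f2)
                    if i1 + 1 < n1 and i2 + 1 < n2:
                        acc += vol[k, i1 + 1, i2 + 1] * f1 * f2
                g1 += d1
                g2 += d2
            out[iu, iv] = acc * step


@njit(cache=False, fastmath=False)
def joseph_backproject(vol, h, eu, ev, t, det_spacing, image):
    n0, n1, n2 = vol.shape
    nu, nv = image.shape
    c0 = 0.5 * (n0 - 1)
    c1 = 0.5 * (n1 - 1)
    c2 = 0.5 * (n2 - 1)
    cu = 0.5 * (nu - 1)
    cv = 0.5 * (nv - 1)
    step = h / abs(t[0])
    d1 = t[1] / t[0]
    d2 = t[2] / t[0]
    for iu in range(nu):
        u = (iu - cu) * det_spacing
        for iv in range(nv):
            v = (iv - cv) * det_spacing
            val = image[iu, iv] * step
            if val == 0.0:
                continue
            o0 = u * eu[0] + v * ev[0]
            o1 = u * eu[1] + v * ev[1]
            o2 = u * eu[2] + v * ev[2]
            g1 = (o1 + (-c0 * h - o0) * d1) / h + c1
            g2 = (o2 + (-c0 * h - o0) * d2) / h + c2
            for k in range(n0):
                i1 = int(np.floor(g1))
                i2 = int(np.floor(g2))
                f1 = g1 - i1
                f2 = g2 - i2
                if -1 <= i1 < n1 and -1 <= i2 < n2:
                    if i1 >= 0 and i2 >= 0:
                        vol[k, i1, i2] += val * (1.0 - f1) * (1.0 - f2)
                    if i1 >= 0 and i2 + 1 < n2:
                        vol[k, i1, i2 + 1] += val * (1.0 - f1) * f2
                    if i1 + 1 < n1 and i2 >= 0:
                        vol[k, i1 + 1, i2] += val * f1 * (1.0 - f2)
                    if i1 + 1 < n1 and i2 + 1 < n2:
                        vol[k, i1 + 1, i2 + 1] += val * f1 * f2
                g1 += d1
                g2 += d2
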