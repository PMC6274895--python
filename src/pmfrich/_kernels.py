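"""Numba-compiled inner-loop kernels.

The engine's per-step cost is dominated by many small array operations;
these kernels fuse them.  If numba is unavailable the engine falls back to
the vectorized numpy implementations, which are arithmetically equivalent.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def dihedral_kernel(positions, quads):
    """Angles (m,) and gradients (m, 4, 3) for index quadruples."""
    m = quads.shape[0]
    phi = np.empty(m)
    grad = np.empty((m, 4, 3))
    for t in range(m):
        i0, i1, i2, i3 = quads[t, 0], quads[t, 1], quads[t, 2], quads[t, 3]
        b1 = positions[i1] - positions[i0]
        b2 = positions[i2] - positions[i1]
        b3 = positions[i3] - positions[i2]
        n1 = np.array([b1[1] * b2[2] - b1[2] * b2[1],
                       b1[2] * b2[0] - b1[0] * b2[2],
                       b1[0] * b2[1] - b1[1] * b2[0]])
        n2 = np.array([b2[1] * b3[2] - b2[2] * b3[1],
                       b2[2] * b3[0] - b2[0] * b3[2],
                       b2[0] * b3[1] - b2[1] * b3[0]])
        nb2 = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
        n1sq = n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2
        n2sq = n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2
        cx = np.array([n1[1] * n2[2] - n1[2] * n2[1],
                       n1[2] * n2[0] - n1[0] * n2[2],
                       n1[0] * n2[1] - n1[1] * n2[0]])
        x = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
        y = (cx[0] * b2[0] + cx[1] * b2[1] + cx[2] * b2[2]) / nb2
        phi[t] = np.arctan2(y, x)
        d1 = -(nb2 / n1sq) * n1
        d4 = (nb2 / n2sq) * n2
        a = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / nb2 ** 2
        b = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / nb2 ** 2
        for k in range(3):
            grad[t, 0, k] = d1[k]
            grad[t, 1, k] = -(1.0 + a) * d1[k] + b * d4[k]
            grad[t, 2, k] = a * d1[k] - (1.0 + b) * d4[k]
            grad[t, 3, k] = d4[k]
    return phi, grad


@njit(cache=True)
def forces_kernel(positions, bond_idx, bond_k, bond_r0, angle_idx, angle_k,
                  angle_t0, cos_idx, cos_k, cos_n, cos_phi0, dw_idx,
                  dw_barrier, rep_idx, rep_eps, rep_sigma):
    """Fused toy-chain energy and gradient."""
    n = positions.shape[0]
    grad = np.zeros((n, 3))
    energy = 0.0

    for t in range(bond_idx.shape[0]):
        i, j = bond_idx[t, 0], bond_idx[t, 1]
        dx = positions[i] - positions[j]
        r = np.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        dr = r - bond_r0[t]
        energy += 0.5 * bond_k[t] * dr * dr
        c = bond_k[t] * dr / max(r, 1e-12)
        for k in range(3):
            grad[i, k] += c * dx[k]
            grad[j, k] -= c * dx[k]

    for t in range(angle_idx.shape[0]):
        i, j, l = angle_idx[t, 0], angle_idx[t, 1], angle_idx[t, 2]
        u = positions[i] - positions[j]
        v = positions[l] - positions[j]
        nu = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
        nv = np.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
        c = (u[0] * v[0] + u[1] * v[1] + u[2] * v[2]) / (nu * nv)
        c = min(1.0, max(-1.0, c))
        theta = np.arccos(c)
        s = np.sqrt(max(1.0 - c * c, 1e-16))
        coeff = angle_k[t] * (theta - angle_t0[t])
        energy += 0.5 * angle_k[t] * (theta - angle_t0[t]) ** 2
        for k in range(3):
            dci = v[k] / (nu * nv) - c * u[k] / nu ** 2
            dck = u[k] / (nu * nv) - c * v[k] / nv ** 2
            di = -dci / s
            dk = -dck / s
            grad[i, k] += coeff * di
            grad[l, k] += coeff * dk
            grad[j, k] += coeff * (-di - dk)

    if cos_idx.shape[0] > 0:
        phi_c, dphi_c = dihedral_kernel(positions, cos_idx)
        for t in range(cos_idx.shape[0]):
            arg = cos_n[t] * phi_c[t] - cos_phi0[t]
            energy += cos_k[t] * (1.0 + np.cos(arg))
            dU = -cos_k[t] * cos_n[t] * np.sin(arg)
            for a in range(4):
                for k in range(3):
                    grad[cos_idx[t, a], k] += dU * dphi_c[t, a, k]

    if dw_idx.shape[0] > 0:
        phi_d, dphi_d = dihedral_kernel(positions, dw_idx)
        for t in range(dw_idx.shape[0]):
            energy += dw_barrier[t] * np.sin(phi_d[t]) ** 2
            dU = dw_barrier[t] * np.sin(2.0 * phi_d[t])
            for a in range(4):
                for k in range(3):
                    grad[dw_idx[t, a], k] += dU * dphi_d[t, a, k]

    r_cap = 0.6 * rep_sigma
    f_cap = 12.0 * rep_eps * (rep_sigma / r_cap) ** 12 / r_cap
    for t in range(rep_idx.shape[0]):
        i, j = rep_idx[t, 0], rep_idx[t, 1]
        dx = positions[i] - positions[j]
        r = np.sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
        r = max(r, 1e-12)
        rr = max(r, r_cap)
        sr12 = (rep_sigma / rr) ** 12
        energy += rep_eps * sr12
        if r < r_cap:
            energy += f_cap * (r_cap - r)
        f = -12.0 * rep_eps * sr12 / rr
        c = f / r
        for k in range(3):
            grad[i, k] += c * dx[k]
            grad[j, k] -= c * dx[k]

    return energy, grad
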