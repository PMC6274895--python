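"""Internal-coordinate geometry: angles, dihedrals, and their Cartesian
gradients (radians internally), plus NeRF placement for fixture construction."""

from __future__ import annotations

import math

import numpy as np


def bond_angle_and_gradient(ri, rj, rk):
    """Angle i-j-k (vertex j) in radians and its gradient w.r.t. the 3 atoms.

    Returns ``(theta, (3, 3) array)`` with rows ordered (i, j, k).
    """
    ri, rj, rk = (np.asarray(r, dtype=float) for r in (ri, rj, rk))
    u = ri - rj
    v = rk - rj
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("degenerate angle: coincident atoms")
    c = float(np.dot(u, v) / (nu * nv))
    c = max(-1.0, min(1.0, c))
    theta = math.acos(c)
    s = math.sqrt(max(1.0 - c * c, 1e-16))
    dci = v / (nu * nv) - c * u / nu**2
    dck = u / (nu * nv) - c * v / nv**2
    di = -dci / s
    dk = -dck / s
    dj = -(di + dk)
    return theta, np.vstack([di, dj, dk])


def dihedral_angle_and_gradient(r1, r2, r3, r4):
    """Signed dihedral about the r2–r3 axis (radians, (−π, π]) and its
    Cartesian gradient, the Blondel–Karplus form.

    Returns ``(phi, (4, 3) array)``.
    """
    r1, r2, r3, r4 = (np.asarray(r, dtype=float) for r in (r1, r2, r3, r4))
    b1 = r2 - r1
    b2 = r3 - r2
    b3 = r4 - r3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    n1sq = float(np.dot(n1, n1))
    n2sq = float(np.dot(n2, n2))
    if nb2 == 0.0 or n1sq == 0.0 or n2sq == 0.0:
        raise ValueError("degenerate dihedral frame")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    phi = math.atan2(y, x)

    d1 = -(nb2 / n1sq) * n1
    d4 = (nb2 / n2sq) * n2
    a = float(np.dot(b1, b2)) / nb2**2
    b = float(np.dot(b3, b2)) / nb2**2
    d2 = -(1.0 + a) * d1 + b * d4
    d3 = a * d1 - (1.0 + b) * d4
    return phi, np.vstack([d1, d2, d3, d4])


def _cross_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product without ``np.cross``'s axis-juggling overhead
    (this sits in the engine's inner loop)."""
    c = np.empty_like(a)
    c[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    c[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    c[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return c


def dihedral_batch(positions: np.ndarray, quads: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized dihedrals: angles (m,) in radians and gradients (m, 4, 3)
    for an (m, 4) array of atom-index quadruples."""
    quads = np.asarray(quads, dtype=int)
    r = positions[quads]                      # (m, 4, 3)
    b1 = r[:, 1] - r[:, 0]
    b2 = r[:, 2] - r[:, 1]
    b3 = r[:, 3] - r[:, 2]
    n1 = _cross_rows(b1, b2)
    n2 = _cross_rows(b2, b3)
    nb2 = np.sqrt(np.einsum("ij,ij->i", b2, b2))
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", _cross_rows(n1, n2), b2) / nb2
    phi = np.arctan2(y, x)
    d1 = -(nb2 / n1sq)[:, None] * n1
    d4 = (nb2 / n2sq)[:, None] * n2
    a = np.einsum("ij,ij->i", b1, b2) / nb2**2
    b = np.einsum("ij,ij->i", b3, b2) / nb2**2
    d2 = -(1.0 + a)[:, None] * d1 + b[:, None] * d4
    d3 = a[:, None] * d1 - (1.0 + b)[:, None] * d4
    return phi, np.stack([d1, d2, d3, d4], axis=1)


def angle_batch(positions: np.ndarray, triples: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized bond angles: (m,) radians and gradients (m, 3, 3)."""
    triples = np.asarray(triples, dtype=int)
    r = positions[triples]
    u = r[:, 0] - r[:, 1]
    v = r[:, 2] - r[:, 1]
    nu = np.sqrt(np.einsum("ij,ij->i", u, u))
    nv = np.sqrt(np.einsum("ij,ij->i", v, v))
    c = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(c)
    s = np.sqrt(np.maximum(1.0 - c * c, 1e-16))
    dci = v / (nu * nv)[:, None] - (c / nu**2)[:, None] * u
    dck = u / (nu * nv)[:, None] - (c / nv**2)[:, None] * v
    di = -dci / s[:, None]
    dk = -dck / s[:, None]
    dj = -(di + dk)
    return theta, np.stack([di, dj, dk], axis=1)


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position of a new atom bonded to ``c`` with bond length
    ``bond``, angle b-c-new and torsion a-b-c-new (degrees)."""
    a, b, c = (np.asarray(r, dtype=float) for r in (a, b, c))
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(phi),
        bond * math.sin(theta) * math.sin(phi),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("collinear reference atoms in NeRF placement")
    n /= nn
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local
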