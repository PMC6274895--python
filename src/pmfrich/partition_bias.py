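"""Normalized partition Ω over active p-PMF values and its gradients.

Ω is a Boltzmann-weighted (softmax) partition over the p-PMF values of the
currently active coordinates:

    Ω_i = e^(−β w_i) / Σ_j e^(−β w_j),    Σ_i Ω_i = 1.

Because a constant offset δw shared by every w cancels between numerator and
denominator, Ω — and hence every gradient derived from it — is invariant
under the unknown additive error that the quasi-homogeneity approximation
introduces into each p-PMF.  That cancellation is the reason the bias is
built from ∇Ω rather than from the p-PMFs themselves.

The per-coordinate bias gradient is the derivative of Ω_i along the system's
motion.  With J_ij = ∂Ω_i/∂x_j = β Ω_i Ω_j w'_j − δ_ij β Ω_i w'_i (the
quotient-rule derivative of the softmax; the cross term carries a positive
sign), two application modes are provided:

* ``"full"`` (default): g_i = Σ_j J_ij — all coordinates co-vary, matching
  the printed two-term structure of the published gradient;
* ``"diagonal"``: g_i = J_ii = −β Ω_i (1 − Ω_i) w'_i — only the coordinate's
  own response.

Ω must be re-evaluated at every configuration; nothing here caches across
configurations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .geometry import dihedral_angle_and_gradient

logger = logging.getLogger(__name__)


@dataclass
class PartitionWeights:
    """Ω over the active coordinates at one configuration."""

    coordinate_ids: tuple
    values: np.ndarray           # current coordinate values (nm or rad)
    w: np.ndarray                # current p-PMF values, kJ/mol
    omega: np.ndarray            # normalized weights
    beta: float                  # mol/kJ
    delta_w: float = 0.0         # test-only shared additive offset


@dataclass
class BiasGradients:
    """Per-coordinate dΩ/dx and the mapped per-atom Cartesian vectors."""

    per_coordinate: np.ndarray   # 1/nm for pairs, 1/rad for torsions
    per_atom: np.ndarray         # (n_atoms, 3) gradient of H(B)
    skipped: list = field(default_factory=list)


def partition_state(coordinate_ids: Sequence, values: Sequence[float],
                    w: Sequence[float], beta: float,
                    delta_w: float = 0.0) -> PartitionWeights:
    """Bundle one configuration's Ω evaluation into a PartitionWeights
    record; ``delta_w`` is a test-only shared offset added to every w (it
    cannot change Ω)."""
    w = np.asarray(w, dtype=float) + delta_w
    return PartitionWeights(coordinate_ids=tuple(coordinate_ids),
                            values=np.asarray(values, dtype=float), w=w,
                            omega=evaluate_omega(w, beta), beta=beta,
                            delta_w=delta_w)


def evaluate_omega(w: Sequence[float], beta: float) -> np.ndarray:
    """Numerically stable softmax of −βw (the min w is subtracted before
    exponentiation, which changes nothing by shift invariance)."""
    w = np.asarray(w, dtype=float)
    if w.size == 0:
        raise ValueError("evaluate_omega needs at least one p-PMF value")
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite p-PMF value")
    z = np.exp(-beta * (w - w.min()))
    return z / z.sum()


def omega_jacobian(w: Sequence[float], dwdx: Sequence[float],
                   beta: float) -> np.ndarray:
    """Full response matrix J_ij = ∂Ω_i/∂x_j.

    J_ij = β Ω_i Ω_j (dw_j/dx_j) − δ_ij β Ω_i (dw_i/dx_i); rows sum against
    coordinate motions, columns identify the perturbed coordinate.
    """
    w = np.asarray(w, dtype=float)
    dwdx = np.asarray(dwdx, dtype=float)
    if w.shape != dwdx.shape:
        raise ValueError("w and dw/dx must have the same length")
    omega = evaluate_omega(w, beta)
    J = beta * np.outer(omega, omega * dwdx)
    J[np.diag_indices_from(J)] -= beta * omega * dwdx
    return J


def omega_gradient(w: Sequence[float], dwdx: Sequence[float], beta: float,
                   mode: Literal["full", "diagonal"] = "full") -> np.ndarray:
    """Per-coordinate bias gradient dΩ_i/dx (see module docstring).

    ``full`` returns the total derivative of Ω_i when every coordinate moves
    along its own axis: g_i = −β Ω_i w'_i + β Ω_i Σ_j Ω_j w'_j.  ``diagonal``
    keeps only the coordinate's own response −β Ω_i (1 − Ω_i) w'_i.
    """
    w = np.asarray(w, dtype=float)
    dwdx = np.asarray(dwdx, dtype=float)
    if w.shape != dwdx.shape:
        raise ValueError("w and dw/dx must have the same length")
    omega = evaluate_omega(w, beta)
    if mode == "diagonal":
        return -beta * omega * (1.0 - omega) * dwdx
    if mode == "full":
        return -beta * omega * dwdx + beta * omega * float(np.dot(omega, dwdx))
    raise ValueError(f"unknown mode: {mode}")


def omega_free_energy(omega: np.ndarray, kT: float) -> np.ndarray:
    """Diagnostic quasi-free-energy −kT ln Ω; never used for propagation."""
    return -kT * np.log(omega)


# --------------------------------------------------------------------------
# Cartesian mapping
# --------------------------------------------------------------------------

def cartesian_bias_forces(positions: np.ndarray,
                          coordinates: Sequence[tuple[str, tuple]],
                          grad_per_coordinate: Sequence[float]) -> BiasGradients:
    """Map per-coordinate dΩ/dx to per-atom Cartesian gradients of H(B).

    ``coordinates`` is a list of ``("distance", (i, j))`` or
    ``("torsion", (i, j, k, l))`` atom-index tuples; ``grad_per_coordinate``
    the matching dΩ/dr (1/nm) or dΩ/dθ (1/rad) values.  Distance terms act
    equal-and-opposite along the inter-atom unit vector, torsion terms through
    the four-atom dihedral gradient; degenerate geometries are skipped and
    logged.  The returned vectors are gradients; the applied bias force is
    their negative.
    """
    positions = np.asarray(positions, dtype=float)
    grads = np.asarray(grad_per_coordinate, dtype=float)
    if len(coordinates) != len(grads):
        raise ValueError("one gradient per coordinate required")
    per_atom = np.zeros_like(positions)
    skipped: list = []
    for (kind, idx), g in zip(coordinates, grads):
        if kind == "distance":
            i, j = idx
            rij = positions[i] - positions[j]
            r = np.linalg.norm(rij)
            if r < 1e-10:
                skipped.append((kind, idx))
                continue
            u = rij / r
            per_atom[i] += g * u
            per_atom[j] -= g * u
        elif kind == "torsion":
            try:
                _, dphi = dihedral_angle_and_gradient(*(positions[a] for a in idx))
            except ValueError:
                skipped.append((kind, idx))
                continue
            for a, da in zip(idx, dphi):
                per_atom[a] += g * da
        else:
            raise ValueError(f"unknown coordinate kind: {kind}")
    if skipped:
        logger.warning("cartesian_bias_forces: skipped %d degenerate coordinates",
                       len(skipped))
    return BiasGradients(per_coordinate=grads, per_atom=per_atom, skipped=skipped)
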