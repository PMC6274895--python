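"""Renormalized hybrid-Hamiltonian dynamics on toy bead chains.

The reference Hamiltonian H(A) is a bead-chain force field (harmonic bonds
and angles, cosine or double-well dihedrals, short-range pair repulsion).
The knowledge-based bias H(B) enters only through the renormalization

    ∇H(C) = ∇H(A)/(1+α) + α·(‖∇H(A)‖/‖∇B_rad‖)·∇B_rad
                        + α·(‖∇H(A)‖/‖∇B_ang‖)·∇B_ang,

so each bias term is rescaled to a fraction α(t) of the reference gradient
magnitude (global Euclidean norms over the biased atoms; a zero-norm term
contributes nothing).  The coupling α(t) fluctuates around α via a uniform
random process.  Integration is BAOA Langevin (kick, drift, Ornstein–
Uhlenbeck, drift), which shares configurational averages with BAOAB and is
unconditionally stable at toy scale.

Unit mapping of the toy scale: energies in kJ/mol with kT ≈ 2.494 kJ/mol at
300 K, lengths in nm with bond lengths near 0.153 nm, time step analog of
1–5 fs (0.001–0.005 ps).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .geometry import angle_batch, dihedral_batch
from .pmf_builder import PmfLibrary, interpolate
from .units import KB

logger = logging.getLogger(__name__)

# RNG stream salts: thermostat noise and α(t) draws are independent streams
# so an α = 0 run is bitwise identical to the unbiased run at equal seed.
_SALT_THERMO = 11
_SALT_ALPHA = 12
_SALT_INIT = 13


# --------------------------------------------------------------------------
# coupling
# --------------------------------------------------------------------------

@dataclass
class HybridCoupling:
    """Coupling state α/ε and the fluctuation mode of α(t).

    * ``"literal"``: α(t) = α·(1−ξ)·ε, ξ ~ U[0,1] (empirical mean α·ε/2);
    * ``"mean-preserving"`` (default): the literal draw rescaled by 2/ε so
      the long-run mean is exactly α;
    * ``"off"``: α(t) = α.
    """

    alpha: float
    epsilon: float = 1.0
    mode: Literal["literal", "mean-preserving", "off"] = "mean-preserving"
    resample_interval: int = 1
    _warned: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.epsilon < 0:
            raise ValueError("alpha and epsilon must be non-negative")


def sample_alpha(coupling: HybridCoupling, rng: np.random.Generator,
                 size: int | None = None) -> float | np.ndarray:
    """Draws of the fluctuating coupling α(t) ≥ 0 (scalar, or an array when
    ``size`` is given)."""
    if coupling.mode == "off":
        return coupling.alpha if size is None else np.full(size, coupling.alpha)
    if coupling.epsilon == 0.0:
        if not coupling._warned:
            logger.info("sample_alpha: epsilon = 0, coupling degenerates to alpha")
            coupling._warned = True
        return coupling.alpha if size is None else np.full(size, coupling.alpha)
    xi = rng.random() if size is None else rng.random(size)
    draw = coupling.alpha * (1.0 - xi) * coupling.epsilon
    if coupling.mode == "literal":
        return draw
    if coupling.mode == "mean-preserving":
        return draw * 2.0 / coupling.epsilon
    raise ValueError(f"unknown mode: {coupling.mode}")


# --------------------------------------------------------------------------
# toy topology and its forces
# --------------------------------------------------------------------------

@dataclass
class ToyTopology:
    """Bead-chain reference Hamiltonian H(A).

    ``bonds``: (i, j, k, r0) harmonic ½k(r−r0)²; ``angles``:
    (i, j, k, ka, θ0) harmonic ½ka(θ−θ0)²; ``dihedrals``: dicts with
    ``indices`` and either ``kind="cosine"`` (k, n, phi0) or
    ``kind="double_well"`` (barrier B, U = B sin²φ).  ``repulsion_pairs``
    feel U = ε(σ/r)¹², force-capped below 0.6σ.
    """

    masses: np.ndarray
    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    dihedrals: list = field(default_factory=list)
    repulsion_pairs: list = field(default_factory=list)
    repulsion_eps: float = 0.2
    repulsion_sigma: float = 0.25
    biasable_torsions: list = field(default_factory=list)
    biasable_pairs: list = field(default_factory=list)

    _cached_arrays: dict | None = field(default=None, repr=False, compare=False)

    @property
    def n_beads(self) -> int:
        return len(self.masses)

    def term_arrays(self) -> dict:
        """Index/parameter arrays for vectorized force evaluation (cached)."""
        if self._cached_arrays is None:
            bonds = np.array([(i, j) for i, j, _, _ in self.bonds],
                             dtype=int).reshape(-1, 2)
            cos_terms = [t for t in self.dihedrals if t["kind"] == "cosine"]
            dw_terms = [t for t in self.dihedrals if t["kind"] == "double_well"]
            self._cached_arrays = {
                "bond_idx": bonds,
                "bond_k": np.array([k for _, _, k, _ in self.bonds]),
                "bond_r0": np.array([r0 for _, _, _, r0 in self.bonds]),
                "angle_idx": np.array([(i, j, k) for i, j, k, _, _ in self.angles],
                                      dtype=int).reshape(-1, 3),
                "angle_k": np.array([ka for *_, ka, _ in self.angles]),
                "angle_t0": np.array([t0 for *_, t0 in self.angles]),
                "cos_idx": np.array([t["indices"] for t in cos_terms],
                                    dtype=int).reshape(-1, 4),
                "cos_k": np.array([t["k"] for t in cos_terms]),
                "cos_n": np.array([t["n"] for t in cos_terms]),
                "cos_phi0": np.array([t["phi0"] for t in cos_terms]),
                "dw_idx": np.array([t["indices"] for t in dw_terms],
                                   dtype=int).reshape(-1, 4),
                "dw_barrier": np.array([t["barrier"] for t in dw_terms]),
                "rep_idx": np.array(self.repulsion_pairs,
                                    dtype=int).reshape(-1, 2),
            }
        return self._cached_arrays

    def initial_positions(self, bond_r0: float | None = None) -> np.ndarray:
        """Near-trans zig-zag start with the double-well dihedral at 180°."""
        r0 = bond_r0 if bond_r0 is not None else (
            self.bonds[0][3] if self.bonds else 0.153)
        theta = self.angles[0][4] if self.angles else math.radians(111.0)
        pos = np.zeros((self.n_beads, 3))
        direction = 1.0
        for i in range(1, self.n_beads):
            step = np.array([r0 * math.sin(theta / 2.0),
                             direction * r0 * math.cos(theta / 2.0), 0.0])
            pos[i] = pos[i - 1] + step
            direction *= -1.0
        return pos


def toy_forces(topology: ToyTopology, positions: np.ndarray
               ) -> tuple[float, np.ndarray]:
    """Potential energy and per-atom gradient ∇H(A) of the toy terms."""
    positions = np.asarray(positions, dtype=float)
    arrs = topology.term_arrays()
    if _kernels.HAVE_NUMBA:
        energy, grad = _kernels.forces_kernel(
            positions, arrs["bond_idx"], arrs["bond_k"], arrs["bond_r0"],
            arrs["angle_idx"], arrs["angle_k"], arrs["angle_t0"],
            arrs["cos_idx"], arrs["cos_k"].astype(float),
            arrs["cos_n"].astype(float), arrs["cos_phi0"].astype(float),
            arrs["dw_idx"], arrs["dw_barrier"], arrs["rep_idx"],
            topology.repulsion_eps, topology.repulsion_sigma)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite toy forces")
        return float(energy), grad
    return _toy_forces_numpy(topology, positions)


def _toy_forces_numpy(topology: ToyTopology, positions: np.ndarray
                      ) -> tuple[float, np.ndarray]:
    """Vectorized numpy evaluation (fallback and cross-check path)."""
    energy = 0.0
    grad = np.zeros_like(positions)
    arrs = topology.term_arrays()

    if len(arrs["bond_idx"]):
        i, j = arrs["bond_idx"].T
        rij = positions[i] - positions[j]
        r = np.linalg.norm(rij, axis=1)
        k, r0 = arrs["bond_k"], arrs["bond_r0"]
        energy += float(np.sum(0.5 * k * (r - r0) ** 2))
        f = (k * (r - r0) / np.maximum(r, 1e-12))[:, None] * rij
        np.add.at(grad, i, f)
        np.add.at(grad, j, -f)

    if len(arrs["angle_idx"]):
        theta, dtheta = angle_batch(positions, arrs["angle_idx"])
        ka, t0 = arrs["angle_k"], arrs["angle_t0"]
        energy += float(np.sum(0.5 * ka * (theta - t0) ** 2))
        coeff = ka * (theta - t0)
        np.add.at(grad, arrs["angle_idx"], coeff[:, None, None] * dtheta)

    if len(arrs["cos_idx"]):
        phi, dphi = dihedral_batch(positions, arrs["cos_idx"])
        k, n, phi0 = arrs["cos_k"], arrs["cos_n"], arrs["cos_phi0"]
        energy += float(np.sum(k * (1.0 + np.cos(n * phi - phi0))))
        dU = -k * n * np.sin(n * phi - phi0)
        np.add.at(grad, arrs["cos_idx"], dU[:, None, None] * dphi)

    if len(arrs["dw_idx"]):
        phi, dphi = dihedral_batch(positions, arrs["dw_idx"])
        B = arrs["dw_barrier"]
        energy += float(np.sum(B * np.sin(phi) ** 2))
        dU = B * np.sin(2.0 * phi)
        np.add.at(grad, arrs["dw_idx"], dU[:, None, None] * dphi)

    if len(arrs["rep_idx"]):
        eps, sigma = topology.repulsion_eps, topology.repulsion_sigma
        r_cap = 0.6 * sigma
        i, j = arrs["rep_idx"].T
        rij = positions[i] - positions[j]
        r = np.linalg.norm(rij, axis=1)
        if np.any(r < 1e-12):
            logger.warning("toy_forces: overlapping beads, repulsion capped")
            r = np.maximum(r, 1e-12)
        rr = np.maximum(r, r_cap)
        sr12 = (sigma / rr) ** 12
        energy += float(np.sum(eps * sr12))
        # below the cap the potential continues linearly (capped force)
        capped = r < r_cap
        f_cap = 12.0 * eps * (sigma / r_cap) ** 12 / r_cap
        energy += float(np.sum(capped * f_cap * (r_cap - r)))
        f = -12.0 * eps * sr12 / rr
        fv = (f / r)[:, None] * rij
        np.add.at(grad, i, fv)
        np.add.at(grad, j, -fv)

    if not np.all(np.isfinite(grad)):
        raise FloatingPointError("non-finite toy forces")
    return energy, grad


# --------------------------------------------------------------------------
# renormalization and integration
# --------------------------------------------------------------------------

def renormalize_terms(grad_A: np.ndarray, bias_terms: Sequence[np.ndarray],
                      alpha_t: float) -> tuple[np.ndarray, list[np.ndarray]]:
    """Rescale each bias term to norm α(t)·‖∇H(A)‖ and combine with
    ∇H(A)/(1+α).  Returns (combined gradient, rescaled terms); a zero-norm
    bias term is returned as zeros."""
    grad_A = np.asarray(grad_A, dtype=float)
    if not np.all(np.isfinite(grad_A)):
        raise ValueError("non-finite gradient input")
    if alpha_t == 0.0:
        return grad_A, [np.zeros_like(grad_A) for _ in bias_terms]
    norm_A = float(np.linalg.norm(grad_A))
    combined = grad_A / (1.0 + alpha_t)
    rescaled = []
    for term in bias_terms:
        term = np.asarray(term, dtype=float)
        if not np.all(np.isfinite(term)):
            raise ValueError("non-finite gradient input")
        norm_B = float(np.linalg.norm(term))
        if norm_B > 0.0:
            scaled = alpha_t * (norm_A / norm_B) * term
            combined = combined + scaled
        else:
            scaled = np.zeros_like(grad_A)
        rescaled.append(scaled)
    return combined, rescaled


def renormalize_gradient(grad_A: np.ndarray, grad_B_radial: np.ndarray,
                         grad_B_angular: np.ndarray, alpha_t: float,
                         joint: bool = False) -> np.ndarray:
    """Combine the reference gradient with the bias gradients.

    Each bias term is rescaled so its global norm equals α(t)·‖∇H(A)‖; a
    zero-norm term contributes nothing.  ``joint=True`` renormalizes the sum
    of the two bias terms as one (default: independently, as printed).
    """
    if joint:
        terms = [np.asarray(grad_B_radial, dtype=float)
                 + np.asarray(grad_B_angular, dtype=float)]
    else:
        terms = [grad_B_radial, grad_B_angular]
    combined, _ = renormalize_terms(grad_A, terms, alpha_t)
    return combined


@dataclass
class EngineState:
    """Positions (nm), momenta (amu·nm/ps), time (ps) and step counter."""

    positions: np.ndarray
    momenta: np.ndarray
    time: float = 0.0
    step: int = 0
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.momenta = np.asarray(self.momenta, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")
        # T = 0 is allowed as the deterministic limit of the thermostat
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


def langevin_step(state: EngineState, gradient: np.ndarray, dt: float,
                  friction: float, masses: np.ndarray,
                  rng: np.random.Generator) -> EngineState:
    """One BAOA Langevin update with the supplied ∇H(C).

    Kick (full dt), half drift, Ornstein–Uhlenbeck momentum refresh, half
    drift.  With zero force and T → 0 positions are unchanged.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    gradient = np.asarray(gradient, dtype=float)
    if not np.all(np.isfinite(gradient)):
        raise FloatingPointError(f"non-finite force at step {state.step}")
    m = np.asarray(masses, dtype=float)[:, None]
    kT = KB * state.temperature
    p = state.momenta - gradient * dt
    q = state.positions + (p / m) * (dt / 2.0)
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt((1.0 - c1 * c1) * kT)
    p = c1 * p + c2 * np.sqrt(m) * rng.standard_normal(p.shape)
    q = q + (p / m) * (dt / 2.0)
    return EngineState(positions=q, momenta=p, time=state.time + dt,
                       step=state.step + 1, temperature=state.temperature)


def maxwell_momenta(masses: np.ndarray, temperature: float,
                    rng: np.random.Generator) -> np.ndarray:
    kT = KB * temperature
    m = np.asarray(masses, dtype=float)[:, None]
    return np.sqrt(m * kT) * rng.standard_normal((len(masses), 3))


# --------------------------------------------------------------------------
# run loop
# --------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Trajectory (logged frames), scalar log, and the final engine state."""

    trajectory: np.ndarray           # (n_logged, n_beads, 3)
    log: pd.DataFrame
    final_state: EngineState


def _measure_and_bias(positions: np.ndarray, kind: str, idx: np.ndarray,
                      tables: list, beta: float, gradient_mode: str
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate one Ω partition (radial or angular) and map its gradient to
    per-atom Cartesian vectors.  ``idx`` is an (m, 2) pair or (m, 4) torsion
    index array with one table per coordinate; the coordinate gradients
    (∂x/∂R) computed for the measurement are reused for the mapping."""
    if len(idx) == 0:
        return np.zeros_like(positions), np.zeros(0)
    per_atom = np.zeros_like(positions)
    if kind == "distance":
        rij = positions[idx[:, 0]] - positions[idx[:, 1]]
        values = np.sqrt(np.einsum("ij,ij->i", rij, rij))
        ok = values > 1e-10
        if not np.all(ok):
            logger.warning("bias: skipped %d degenerate pairs", int((~ok).sum()))
        unit = rij / np.maximum(values, 1e-10)[:, None]
    elif _kernels.HAVE_NUMBA:
        values, dphi = _kernels.dihedral_kernel(positions, idx)
    else:
        values, dphi = dihedral_batch(positions, idx)
    w_vals = np.empty(len(idx))
    dw_vals = np.empty(len(idx))
    for m, table in enumerate(tables):
        w_vals[m], dw_vals[m] = interpolate(table, values[m])
    # lean inline of omega_gradient (same arithmetic, no re-validation)
    z = np.exp(-beta * (w_vals - w_vals.min()))
    om = z / z.sum()
    if gradient_mode == "full":
        grad_coords = beta * om * (float(om @ dw_vals) - dw_vals)
    else:
        grad_coords = -beta * om * (1.0 - om) * dw_vals
    if kind == "distance":
        g = np.where(ok, grad_coords, 0.0)[:, None] * unit
        np.add.at(per_atom, idx[:, 0], g)
        np.add.at(per_atom, idx[:, 1], -g)
    else:
        np.add.at(per_atom, idx, grad_coords[:, None, None] * dphi)
    return per_atom, values


def run_pmf_enriched(topology: ToyTopology, library: PmfLibrary,
                     coupling: HybridCoupling, n_steps: int, dt: float,
                     seed: int, temperature: float = 300.0,
                     friction: float = 2.0, log_interval: int = 1,
                     gradient_mode: str = "full",
                     start_positions: np.ndarray | None = None,
                     zero_momenta: bool = False,
                     callback: Callable | None = None,
                     callback_interval: int = 1) -> SimulationResult:
    """PMF-enriched dynamics: per step, measure the biased coordinates,
    interpolate w and dw/dx, evaluate the radial and angular Ω partitions and
    their gradients, map to Cartesian bias terms, draw α(t), renormalize
    against ∇H(A) and integrate.

    The Ω partitions are re-evaluated from scratch at every step.  An α = 0
    run consumes the same thermostat stream as an unbiased run with the same
    seed and is bitwise identical to it.
    """
    rng_thermo = np.random.default_rng([seed, _SALT_THERMO])
    rng_alpha = np.random.default_rng([seed, _SALT_ALPHA])
    rng_init = np.random.default_rng([seed, _SALT_INIT])
    beta = 1.0 / (KB * temperature)

    positions = (np.asarray(start_positions, dtype=float)
                 if start_positions is not None else topology.initial_positions())
    momenta = (np.zeros_like(positions) if zero_momenta
               else maxwell_momenta(topology.masses, temperature, rng_init))
    state = EngineState(positions=positions, momenta=momenta,
                        temperature=temperature)

    dist_entries = library.distance_entries()
    tors_entries = library.torsion_entries()
    dist_idx = np.array([e.sites for e in dist_entries], dtype=int).reshape(-1, 2)
    dist_tables = [e.table for e in dist_entries]
    tors_idx = np.array([e.sites for e in tors_entries], dtype=int).reshape(-1, 4)
    tors_tables = [e.table for e in tors_entries]
    frames = [state.positions.copy()]
    rows = []
    alpha_t = coupling.alpha if coupling.mode == "off" else 0.0
    m_col = np.asarray(topology.masses, dtype=float)[:, None]
    half_dt = dt / 2.0
    c1 = math.exp(-friction * dt)
    c2_sqrt_m = math.sqrt((1.0 - c1 * c1) * KB * temperature) * np.sqrt(m_col)
    for step in range(n_steps):
        energy, grad_A = toy_forces(topology, state.positions)
        biased = coupling.alpha > 0.0
        if biased:
            grad_B_rad, dist_vals = _measure_and_bias(
                state.positions, "distance", dist_idx, dist_tables, beta,
                gradient_mode)
            grad_B_ang, tors_vals = _measure_and_bias(
                state.positions, "torsion", tors_idx, tors_tables, beta,
                gradient_mode)
            if step % coupling.resample_interval == 0:
                alpha_t = sample_alpha(coupling, rng_alpha)
            # lean inline of renormalize_terms (identical arithmetic)
            if alpha_t == 0.0:
                combined = grad_A
                term_rad = term_ang = None
            else:
                norm_A = math.sqrt(float(np.sum(grad_A * grad_A)))
                combined = grad_A / (1.0 + alpha_t)
                nb = math.sqrt(float(np.sum(grad_B_rad * grad_B_rad)))
                term_rad = (alpha_t * (norm_A / nb)) * grad_B_rad if nb > 0 \
                    else None
                if term_rad is not None:
                    combined = combined + term_rad
                nb = math.sqrt(float(np.sum(grad_B_ang * grad_B_ang)))
                term_ang = (alpha_t * (norm_A / nb)) * grad_B_ang if nb > 0 \
                    else None
                if term_ang is not None:
                    combined = combined + term_ang
        else:
            grad_B_rad = grad_B_ang = None
            term_rad = term_ang = None
            dist_vals, tors_vals = [], []
            alpha_t = 0.0
            combined = grad_A

        if step % log_interval == 0:
            row = {"step": step, "time": state.time, "energy_A": energy,
                   "norm_grad_A": float(np.linalg.norm(grad_A)),
                   "alpha_t": alpha_t,
                   "norm_bias_rad": (float(np.linalg.norm(grad_B_rad))
                                     if grad_B_rad is not None else 0.0),
                   "norm_bias_ang": (float(np.linalg.norm(grad_B_ang))
                                     if grad_B_ang is not None else 0.0),
                   "norm_term_rad": (float(np.linalg.norm(term_rad))
                                     if term_rad is not None else 0.0),
                   "norm_term_ang": (float(np.linalg.norm(term_ang))
                                     if term_ang is not None else 0.0),
                   "norm_delta": float(np.linalg.norm(
                       combined - grad_A / (1.0 + alpha_t)))}
            for i, v in enumerate(dist_vals):
                row[f"pair_{i}"] = v
            for i, v in enumerate(tors_vals):
                row[f"torsion_{i}"] = v
            rows.append(row)

        # inlined BAOA update (same arithmetic and RNG stream as
        # langevin_step; kept inline to avoid per-step object construction)
        p = state.momenta - combined * dt
        q = state.positions + (p / m_col) * half_dt
        p = c1 * p + c2_sqrt_m * rng_thermo.standard_normal(p.shape)
        q = q + (p / m_col) * half_dt
        state.positions = q
        state.momenta = p
        state.time += dt
        state.step += 1
        if step % log_interval == log_interval - 1 or log_interval == 1:
            frames.append(state.positions.copy())
        if callback is not None and step % callback_interval == 0:
            if callback(step, state) is False:
                break

    return SimulationResult(trajectory=np.array(frames),
                            log=pd.DataFrame(rows), final_state=state)
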