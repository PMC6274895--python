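"""Seeded generators for synthetic structure ensembles and toy topologies.

These generators stand in for database-scale structure sets: they produce
PDB-format ensembles with *known* torsion and pair-distance statistics
(wrapped-Gaussian torsions; Boltzmann-distributed distances under a stated
potential), so every downstream stage — torsion extraction, histogram
accumulation, Boltzmann inversion, partition gradients — can be checked
against ground truth without any download.

RNG policy: every generator call builds one fresh ``numpy`` Generator from
``default_rng([seed, SALT])`` where SALT is a fixed per-function constant,
so calls are bit-reproducible and mutually independent for a shared user
seed.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from . import structure_io as sio
from .geometry import place_atom
from .units import KB

# per-function RNG stream salts (documented splitting rule)
_SALT_TORSION = 101
_SALT_PAIR = 202

# ideal backbone internal coordinates (nm / degrees)
BOND_N_CA = 0.1458
BOND_CA_C = 0.1525
BOND_C_N = 0.1329
BOND_C_O = 0.1231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

# idealized DNA backbone internal coordinates (nm / degrees); only torsion
# statistics matter downstream, not stereochemical perfection
DNA_BONDS = {("P", "O5'"): 0.1593, ("O5'", "C5'"): 0.1440,
             ("C5'", "C4'"): 0.1510, ("C4'", "C3'"): 0.1524,
             ("C3'", "O3'"): 0.1423, ("O3'", "P"): 0.1607}
DNA_ANGLE = 109.5
DNA_ANGLE_P = 120.0


def _wrap_deg(a: float) -> float:
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def build_polypeptide(phi: Sequence[float], psi: Sequence[float],
                      res_name: str = "ALA", chain_id: str = "A") -> sio.StructureRecord:
    """Backbone-only polypeptide with the given per-residue Φ/Ψ (degrees).

    ``phi[0]`` and ``psi[-1]`` are not geometrically defined (chain termini)
    and are ignored.  Atoms N, CA, C, O are emitted per residue with ideal
    bond lengths/angles, so extracted torsions equal the inputs exactly.
    """
    n = len(phi)
    if len(psi) != n:
        raise ValueError("phi and psi must have equal length")
    if n < 1:
        raise ValueError("need at least one residue")
    atoms: list[sio.Atom] = []

    def add(name: str, elem: str, res: int, pos: np.ndarray) -> None:
        atoms.append(sio.Atom(name=name, element=elem, res_name=res_name,
                              res_index=res, chain_id=chain_id, position=pos))

    pos_n = np.zeros(3)
    pos_ca = np.array([BOND_N_CA, 0.0, 0.0])
    t = math.radians(180.0 - ANGLE_N_CA_C)
    pos_c = pos_ca + BOND_CA_C * np.array([math.cos(t), math.sin(t), 0.0])
    add("N", "N", 1, pos_n)
    add("CA", "C", 1, pos_ca)
    add("C", "C", 1, pos_c)
    for i in range(1, n + 1):
        if i < n:
            pos_n_next = place_atom(pos_n, pos_ca, pos_c, BOND_C_N,
                                    ANGLE_CA_C_N, psi[i - 1])
            pos_o = place_atom(pos_n, pos_ca, pos_c, BOND_C_O, ANGLE_CA_C_O,
                               _wrap_deg(psi[i - 1] + 180.0))
            add("O", "O", i, pos_o)
            pos_ca_next = place_atom(pos_ca, pos_c, pos_n_next, BOND_N_CA,
                                     ANGLE_C_N_CA, OMEGA)
            pos_c_next = place_atom(pos_c, pos_n_next, pos_ca_next, BOND_CA_C,
                                    ANGLE_N_CA_C, phi[i])
            add("N", "N", i + 1, pos_n_next)
            add("CA", "C", i + 1, pos_ca_next)
            add("C", "C", i + 1, pos_c_next)
            pos_n, pos_ca, pos_c = pos_n_next, pos_ca_next, pos_c_next
        else:
            pos_o = place_atom(pos_n, pos_ca, pos_c, BOND_C_O, ANGLE_CA_C_O, 0.0)
            add("O", "O", i, pos_o)

    atoms.sort(key=lambda a: (a.res_index, ("N", "CA", "C", "O").index(a.name)))
    seq = sio.THREE_TO_ONE.get(res_name, "X") * n
    return sio.StructureRecord(atoms=atoms, sequences={chain_id: seq})


def build_dna_dinucleotide(torsions_1: Mapping[str, float],
                           torsions_2: Mapping[str, float],
                           res_names: tuple[str, str] = ("DG", "DC"),
                           chain_id: str = "A") -> sio.StructureRecord:
    """Idealized DNA dinucleotide with controllable backbone/glycosidic
    torsions (degrees).

    Controllable: residue 1 — β, γ, δ, ε, ζ, χ; residue 2 — α, β, γ, δ, χ.
    α of residue 1 and ε/ζ of residue 2 need neighbours outside the
    dinucleotide and are not represented.
    """
    t1 = {"beta": -60.0, "gamma": 60.0, "delta": 120.0, "epsilon": 180.0,
          "zeta": -90.0, "chi": -100.0} | dict(torsions_1)
    t2 = {"alpha": -60.0, "beta": 180.0, "gamma": 60.0, "delta": 120.0,
          "chi": -100.0} | dict(torsions_2)
    atoms: list[sio.Atom] = []

    def add(name: str, res: int, pos: np.ndarray) -> None:
        elem = name[0]
        atoms.append(sio.Atom(name=name, element=elem, res_name=res_names[res - 1],
                              res_index=res, chain_id=chain_id, position=pos))

    # main chain of residue 1: P, O5', C5' seeded, then NeRF with torsions
    p1 = np.zeros(3)
    o5_1 = p1 + np.array([DNA_BONDS[("P", "O5'")], 0.0, 0.0])
    ang = math.radians(180.0 - DNA_ANGLE_P)
    c5_1 = o5_1 + DNA_BONDS[("O5'", "C5'")] * np.array([math.cos(ang), math.sin(ang), 0.0])
    c4_1 = place_atom(p1, o5_1, c5_1, DNA_BONDS[("C5'", "C4'")], DNA_ANGLE, t1["beta"])
    c3_1 = place_atom(o5_1, c5_1, c4_1, DNA_BONDS[("C4'", "C3'")], DNA_ANGLE, t1["gamma"])
    o3_1 = place_atom(c5_1, c4_1, c3_1, DNA_BONDS[("C3'", "O3'")], DNA_ANGLE, t1["delta"])
    p2 = place_atom(c4_1, c3_1, o3_1, DNA_BONDS[("O3'", "P")], DNA_ANGLE_P, t1["epsilon"])
    o5_2 = place_atom(c3_1, o3_1, p2, DNA_BONDS[("P", "O5'")], DNA_ANGLE_P, t1["zeta"])
    c5_2 = place_atom(o3_1, p2, o5_2, DNA_BONDS[("O5'", "C5'")], DNA_ANGLE_P, t2["alpha"])
    c4_2 = place_atom(p2, o5_2, c5_2, DNA_BONDS[("C5'", "C4'")], DNA_ANGLE, t2["beta"])
    c3_2 = place_atom(o5_2, c5_2, c4_2, DNA_BONDS[("C4'", "C3'")], DNA_ANGLE, t2["gamma"])
    o3_2 = place_atom(c5_2, c4_2, c3_2, DNA_BONDS[("C3'", "O3'")], DNA_ANGLE, t2["delta"])

    for res, (c5, c4, c3, chi) in ((1, (c5_1, c4_1, c3_1, t1["chi"])),
                                   (2, (c5_2, c4_2, c3_2, t2["chi"]))):
        o4 = place_atom(c5, c3, c4, 0.1450, DNA_ANGLE, -120.0)
        c1 = place_atom(c3, c4, o4, 0.1410, DNA_ANGLE, -25.0)
        purine = res_names[res - 1] in sio.DNA_PURINES
        n_name = "N9" if purine else "N1"
        c_name = "C4" if purine else "C2"
        n_gly = place_atom(c4, o4, c1, 0.1470, 108.0, -120.0)
        c_ref = place_atom(o4, c1, n_gly, 0.1370, 127.0, chi)
        add("O4'", res, o4)
        add("C1'", res, c1)
        add(n_name, res, n_gly)
        add(c_name, res, c_ref)

    add("P", 1, p1)
    add("O5'", 1, o5_1)
    add("C5'", 1, c5_1)
    add("C4'", 1, c4_1)
    add("C3'", 1, c3_1)
    add("O3'", 1, o3_1)
    add("P", 2, p2)
    add("O5'", 2, o5_2)
    add("C5'", 2, c5_2)
    add("C4'", 2, c4_2)
    add("C3'", 2, c3_2)
    add("O3'", 2, o3_2)
    atoms.sort(key=lambda a: a.res_index)
    seq = "".join(sio.THREE_TO_ONE.get(r, "N") for r in res_names)
    return sio.StructureRecord(atoms=atoms, sequences={chain_id: seq})


def make_torsion_ensemble(n_structures: int,
                          torsion_means: Mapping[str, float],
                          torsion_sigmas: Mapping[str, float] | float,
                          seed: int,
                          n_residues: int = 5,
                          max_retries: int = 20) -> list[sio.StructureRecord]:
    """Polypeptide ensemble with wrapped-Gaussian backbone torsions.

    ``torsion_means`` maps ``"phi"``/``"psi"`` to means in degrees;
    ``torsion_sigmas`` gives the circular standard deviations (a scalar
    applies to all torsions).  Structures whose beads collapse sterically
    (any non-bonded atom pair closer than 0.05 nm) are redrawn, up to
    ``max_retries`` per structure.
    """
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    if isinstance(torsion_sigmas, (int, float)):
        torsion_sigmas = {k: float(torsion_sigmas) for k in torsion_means}
    for s in torsion_sigmas.values():
        if s < 0:
            raise ValueError("sigmas must be >= 0")
    rng = np.random.default_rng([seed, _SALT_TORSION])
    records = []
    n_retried = 0
    for _ in range(n_structures):
        for attempt in range(max_retries):
            phi = [_wrap_deg(torsion_means.get("phi", -57.0)
                             + torsion_sigmas.get("phi", 0.0) * rng.standard_normal())
                   for _ in range(n_residues)]
            psi = [_wrap_deg(torsion_means.get("psi", -47.0)
                             + torsion_sigmas.get("psi", 0.0) * rng.standard_normal())
                   for _ in range(n_residues)]
            rec = build_polypeptide(phi, psi)
            pos = rec.positions()
            d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
            near = d + np.eye(len(pos)) + np.tri(len(pos), k=2) * 10
            if near.min() > 0.05:
                records.append(rec)
                break
            n_retried += 1
        else:
            raise RuntimeError(f"steric collapse persisted after {max_retries} retries")
    return records


def make_pair_ensemble(potential: Callable[[np.ndarray], np.ndarray],
                       n_samples: int, temperature: float, seed: int,
                       r_max: float = 2.5, n_grid: int = 20_000) -> np.ndarray:
    """Distances drawn from the density ∝ r² e^(−u(r)/kT) on (0, r_max] nm.

    Inverse-CDF sampling on a dense grid; ``potential`` is a vectorized
    u(r) in kJ/mol, finite on the support.
    """
    rng = np.random.default_rng([seed, _SALT_PAIR])
    kT = KB * temperature
    r = np.linspace(0.0, r_max, n_grid + 1)[1:]
    u = np.asarray(potential(r), dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("potential must be finite on (0, r_max]")
    log_dens = 2.0 * np.log(r) - u / kT
    dens = np.exp(log_dens - log_dens.max())
    cdf = np.cumsum(dens)
    total = cdf[-1]
    if not np.isfinite(total) or total <= 0:
        raise ValueError("non-normalizable density")
    cdf /= total
    xi = rng.random(n_samples)
    return np.interp(xi, cdf, r)


def make_toy_chain(n_beads: int, preset: str = "chain",
                   barrier_kT: float = 8.0, temperature: float = 300.0,
                   bond_k: float = 8000.0, bond_r0: float = 0.153,
                   angle_k: float = 150.0, angle_theta0_deg: float = 111.0,
                   mass: float = 12.0, repulsion_eps: float = 0.2,
                   repulsion_sigma: float = 0.25):
    """Bead-chain topology with harmonic bonds/angles and dihedral terms.

    ``preset="double_well"`` is the dialanine analog: a 4-bead chain whose
    single dihedral carries a symmetric double well U(φ) = B·sin²φ (minima at
    0° and 180°, barrier exactly ``barrier_kT``·kT at ±90°), with the dihedral
    and the 1–4 distance declared biasable.
    """
    from .hybrid_engine import ToyTopology

    if n_beads < 2:
        raise ValueError("need at least 2 beads")
    bonds = [(i, i + 1, bond_k, bond_r0) for i in range(n_beads - 1)]
    angles = [(i, i + 1, i + 2, angle_k, math.radians(angle_theta0_deg))
              for i in range(n_beads - 2)]
    dihedrals = []
    biasable_torsions = []
    biasable_pairs = []
    if preset == "double_well":
        if n_beads < 4:
            raise ValueError("double_well preset needs >= 4 beads")
        barrier = barrier_kT * KB * temperature
        dihedrals.append({"indices": (0, 1, 2, 3), "kind": "double_well",
                          "barrier": barrier})
        biasable_torsions.append((0, 1, 2, 3))
        biasable_pairs.append((0, 3))
        # longer chains: mild cosine dihedrals on the remaining quads, all
        # declared biasable (a softmax partition needs >= 2 active
        # coordinates to produce a non-zero gradient)
        for i in range(1, n_beads - 3):
            quad = (i, i + 1, i + 2, i + 3)
            dihedrals.append({"indices": quad, "kind": "cosine",
                              "k": 1.0, "n": 3, "phi0": 0.0})
            biasable_torsions.append(quad)
        for i in range(n_beads):
            for j in range(i + 3, n_beads):
                if (i, j) != (0, 3):
                    biasable_pairs.append((i, j))
    elif preset == "chain":
        for i in range(n_beads - 3):
            dihedrals.append({"indices": (i, i + 1, i + 2, i + 3),
                              "kind": "cosine", "k": 2.0, "n": 3, "phi0": 0.0})
    else:
        raise ValueError(f"unknown preset: {preset}")
    pairs = [(i, j) for i in range(n_beads) for j in range(i + 3, n_beads)]
    return ToyTopology(
        masses=np.full(n_beads, float(mass)),
        bonds=bonds, angles=angles, dihedrals=dihedrals,
        repulsion_pairs=pairs, repulsion_eps=repulsion_eps,
        repulsion_sigma=repulsion_sigma,
        biasable_torsions=biasable_torsions, biasable_pairs=biasable_pairs,
    )


def write_ensemble(records: Sequence[sio.StructureRecord], directory: str | Path,
                   manifest: Mapping | None = None) -> list[Path]:
    """Write an ensemble as numbered PDB files plus a JSON sidecar manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, rec in enumerate(records):
        p = directory / f"fixture_{i:04d}.pdb"
        sio.write_structure(rec, p)
        paths.append(p)
    with open(directory / "manifest.json", "w") as fh:
        json.dump({"n_structures": len(records), **(dict(manifest or {}))}, fh, indent=1)
    return paths
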