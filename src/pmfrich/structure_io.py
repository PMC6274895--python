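"""PDB-format structure I/O, bias-atom selection, torsions, and dataset filters.

Coordinates are stored in nm internally; Å appears only at file boundaries
(standard PDB precision is 3 decimals in Å).  Parsing and writing of the PDB
format itself is delegated to :mod:`gemmi`; this module only defines the flat
in-memory record the rest of the package consumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import gemmi
import numpy as np
import pandas as pd

from .units import ANGSTROM_TO_NM

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# residue vocabularies
# --------------------------------------------------------------------------

PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "ACE", "NME",
}

#: DNA residue names (PDB v3 plus bare one-letter variants) → purine flag.
DNA_PURINES = {"DA", "DG", "A", "G"}
DNA_PYRIMIDINES = {"DC", "DT", "C", "T"}
DNA_RESIDUES = DNA_PURINES | DNA_PYRIMIDINES

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
    "DA": "A", "DG": "G", "DC": "C", "DT": "T",
}

#: Backbone atoms biased for proteins (in canonical per-residue order).
PROTEIN_BIAS_ATOMS = ("N", "CA", "C", "O")

#: Nucleic-acid atoms biased for DNA; glycosidic N and in-ring C depend on
#: purine/pyrimidine identity (N9/C4 vs N1/C2).
DNA_BIAS_ATOMS_PURINE = ("P", "O5'", "C5'", "C4'", "N9", "C4")
DNA_BIAS_ATOMS_PYRIMIDINE = ("P", "O5'", "C5'", "C4'", "N1", "C2")


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed or is malformed."""


class EmptyStructureError(ValueError):
    """Raised when a structure contains no atoms."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class Atom:
    name: str
    element: str
    res_name: str
    res_index: int
    chain_id: str
    position: np.ndarray  # (3,) in nm

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")


@dataclass
class StructureRecord:
    """One structural model: a flat atom list plus per-chain sequences."""

    atoms: list[Atom] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        last: dict[str, int] = {}
        for a in self.atoms:
            key = (a.chain_id, a.res_index, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom name {a.name} in residue "
                                 f"{a.chain_id}:{a.res_index}")
            seen.add(key)
            prev = last.get(a.chain_id)
            if prev is not None and a.res_index < prev:
                raise ValueError("residue indices must not decrease within a chain")
            last[a.chain_id] = a.res_index

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.vstack([a.position for a in self.atoms])

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def atom_index(self, chain_id: str, res_index: int, name: str) -> int | None:
        for i, a in enumerate(self.atoms):
            if a.chain_id == chain_id and a.res_index == res_index and a.name == name:
                return i
        return None

    def is_polymer_empty(self) -> bool:
        return not any(a.res_name in PROTEIN_RESIDUES or a.res_name in DNA_RESIDUES
                       for a in self.atoms)


@dataclass(frozen=True)
class TorsionDefinition:
    """A named backbone torsion given by four (atom name, residue offset) ids.

    Atom names may carry a purine/pyrimidine alias written ``"N9/N1"``; the
    purine branch is taken for DA/DG, the pyrimidine branch for DC/DT.
    """

    name: str
    atoms: tuple[tuple[str, int], ...]
    applicability: Literal["protein", "dna"]

    def __post_init__(self) -> None:
        if len(self.atoms) != 4:
            raise ValueError("a torsion needs exactly four atom identifiers")
        for _, off in self.atoms:
            if off not in (-1, 0, 1):
                raise ValueError("residue offsets must be in {-1, 0, +1}")


PROTEIN_TORSIONS = (
    TorsionDefinition("phi", (("C", -1), ("N", 0), ("CA", 0), ("C", 0)), "protein"),
    TorsionDefinition("psi", (("N", 0), ("CA", 0), ("C", 0), ("N", 1)), "protein"),
)

DNA_TORSIONS = (
    TorsionDefinition("alpha", (("O3'", -1), ("P", 0), ("O5'", 0), ("C5'", 0)), "dna"),
    TorsionDefinition("beta", (("P", 0), ("O5'", 0), ("C5'", 0), ("C4'", 0)), "dna"),
    TorsionDefinition("gamma", (("O5'", 0), ("C5'", 0), ("C4'", 0), ("C3'", 0)), "dna"),
    TorsionDefinition("delta", (("C5'", 0), ("C4'", 0), ("C3'", 0), ("O3'", 0)), "dna"),
    TorsionDefinition("epsilon", (("C4'", 0), ("C3'", 0), ("O3'", 0), ("P", 1)), "dna"),
    TorsionDefinition("zeta", (("C3'", 0), ("O3'", 0), ("P", 1), ("O5'", 1)), "dna"),
    TorsionDefinition("chi", (("O4'", 0), ("C1'", 0), ("N9/N1", 0), ("C4/C2", 0)), "dna"),
)


@dataclass
class DatasetEntry:
    """One row of the dataset-metadata table used by the selection filters."""

    structure_id: str
    resolution: float | None
    polymer_type: str
    chain_length: int
    cluster: str | None
    contains_rna: bool = False
    contains_dna: bool = False
    protein_length: int = 0

    def __post_init__(self) -> None:
        if self.resolution is not None and not self.resolution > 0:
            raise ValueError("resolution must be positive when present")
        if self.chain_length < 0 or self.protein_length < 0:
            raise ValueError("lengths must be non-negative")


# --------------------------------------------------------------------------
# reading / writing
# --------------------------------------------------------------------------

def read_structure(path: str | Path, format: str = "pdb",
                   model_index: int = 0) -> StructureRecord:
    """Read one model of a PDB file into a :class:`StructureRecord`.

    Coordinates are converted Å → nm.  Multi-model files yield the model at
    ``model_index`` (first model by default).  Only the first alternate
    location of each atom is kept; dropped altlocs are counted in
    ``metadata["n_altloc_dropped"]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format != "pdb":
        raise ValueError(f"unsupported format: {format}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no models")
    if model_index >= len(st):
        raise IndexError(f"model {model_index} not in {path} ({len(st)} models)")

    n_altloc = 0
    atoms: list[Atom] = []
    sequences: dict[str, str] = {}
    model = st[model_index]
    for chain in model:
        seq: list[str] = []
        for res in chain:
            if res.name in THREE_TO_ONE:
                seq.append(THREE_TO_ONE[res.name])
            seen: set[str] = set()
            for at in res:
                if at.name in seen:       # later altloc of an atom already taken
                    n_altloc += 1
                    continue
                seen.add(at.name)
                atoms.append(Atom(
                    name=at.name,
                    element=at.element.name,
                    res_name=res.name,
                    res_index=res.seqid.num,
                    chain_id=chain.name,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]) * ANGSTROM_TO_NM,
                ))
        if seq:
            sequences[chain.name] = "".join(seq)

    if not atoms:
        raise EmptyStructureError(f"{path} contains no atoms")
    if n_altloc:
        logger.info("read_structure(%s): dropped %d alternate-location atoms",
                    path.name, n_altloc)

    record = StructureRecord(atoms=atoms, sequences=sequences,
                             metadata={"source": str(path),
                                       "n_altloc_dropped": n_altloc})
    if record.is_polymer_empty():
        record.metadata["polymer_empty"] = True
    return record


def write_structure(record: StructureRecord, path: str | Path) -> None:
    """Write a record as a single-model PDB file (nm → Å)."""
    # group first: gemmi's add_* methods copy, so containers are filled
    # bottom-up before insertion
    grouped: dict[str, dict[tuple[int, str], list[Atom]]] = {}
    for a in record.atoms:
        grouped.setdefault(a.chain_id, {}).setdefault(
            (a.res_index, a.res_name), []).append(a)

    st = gemmi.Structure()
    st.name = "pmfrich"
    model = gemmi.Model("1")
    for chain_id, residues in grouped.items():
        chain = gemmi.Chain(chain_id)
        for (res_index, res_name), atom_list in residues.items():
            res = gemmi.Residue()
            res.name = res_name
            res.seqid = gemmi.SeqId(res_index, " ")
            res.het_flag = "A"
            for a in atom_list:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element or a.name[0])
                x, y, z = np.asarray(a.position) / ANGSTROM_TO_NM
                at.pos = gemmi.Position(x, y, z)
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_multi_model(records: Sequence[StructureRecord], path: str | Path) -> None:
    """Write a trajectory-style multi-model PDB file."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, rec in enumerate(records, start=1):
            fh.write(f"MODEL     {i:4d}\n")
            serial = 1
            for a in rec.atoms:
                x, y, z = np.asarray(a.position) / ANGSTROM_TO_NM
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                fh.write(f"ATOM  {serial:5d} {name:4s} {a.res_name:>3s} "
                         f"{a.chain_id:1s}{a.res_index:4d}    "
                         f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                         f"{a.element:>2s}\n")
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


# --------------------------------------------------------------------------
# bias-atom selection
# --------------------------------------------------------------------------

def select_bias_atoms(record: StructureRecord,
                      kind: Literal["protein", "dna"]) -> list[int]:
    """Indices of the biased atoms: protein backbone N/CA/C/O, or the DNA
    set P, O5', C5', C4' plus the glycosidic N9/N1 and in-ring C4/C2.

    Ordering is deterministic: by chain, residue index, then canonical
    per-residue atom order.  Unknown residue names are skipped with a logged
    count.
    """
    if kind not in ("protein", "dna"):
        raise ValueError(f"unknown kind: {kind}")
    by_residue: dict[tuple[str, int], dict[str, int]] = {}
    res_names: dict[tuple[str, int], str] = {}
    order: list[tuple[str, int]] = []
    for i, a in enumerate(record.atoms):
        key = (a.chain_id, a.res_index)
        if key not in by_residue:
            by_residue[key] = {}
            res_names[key] = a.res_name
            order.append(key)
        by_residue[key][a.name] = i

    selected: list[int] = []
    n_unknown = 0
    for key in order:
        rname = res_names[key]
        if kind == "protein":
            if rname not in PROTEIN_RESIDUES:
                if rname not in DNA_RESIDUES and rname != "HOH":
                    n_unknown += 1
                continue
            wanted: Iterable[str] = PROTEIN_BIAS_ATOMS
        else:
            if rname in DNA_PURINES:
                wanted = DNA_BIAS_ATOMS_PURINE
            elif rname in DNA_PYRIMIDINES:
                wanted = DNA_BIAS_ATOMS_PYRIMIDINE
            else:
                if rname not in PROTEIN_RESIDUES and rname != "HOH":
                    n_unknown += 1
                continue
        for name in wanted:
            idx = by_residue[key].get(name)
            if idx is not None:
                selected.append(idx)
    if n_unknown:
        logger.warning("select_bias_atoms: skipped %d residues with unknown names",
                       n_unknown)
    return selected


# --------------------------------------------------------------------------
# dihedrals
# --------------------------------------------------------------------------

class UndefinedTorsionError(ValueError):
    """Raised when three consecutive dihedral atoms are collinear."""


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle about the p2–p3 axis, in degrees, in (−180, 180].

    Uses the atan2 formulation, which is numerically robust near 0° and 180°.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n == 0.0:
        raise UndefinedTorsionError("coincident central atoms")
    scale = max(np.linalg.norm(b1), 1.0) * max(b2n, 1.0)
    if np.linalg.norm(n1) < 1e-10 * scale or np.linalg.norm(n2) < 1e-10 * scale:
        raise UndefinedTorsionError("collinear atoms: torsion undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / b2n)
    angle = math.degrees(math.atan2(y, x))
    if angle <= -180.0:       # map to (−180, 180]
        angle += 360.0
    return angle


def _resolve_alias(name: str, res_name: str) -> str:
    if "/" not in name:
        return name
    pur, pyr = name.split("/")
    return pur if res_name in DNA_PURINES else pyr


def extract_torsion_series(record: StructureRecord,
                           defs: Sequence[TorsionDefinition]) -> pd.DataFrame:
    """One row per resolvable torsion: (chain, residue index, torsion, angle°).

    Torsions whose atoms are missing (chain termini, incomplete residues) are
    omitted; the omission count is stored in ``df.attrs["n_omitted"]``.
    """
    index: dict[tuple[str, int, str], int] = {}
    res_names: dict[tuple[str, int], str] = {}
    chain_residues: dict[str, list[int]] = {}
    for i, a in enumerate(record.atoms):
        index[(a.chain_id, a.res_index, a.name)] = i
        res_names[(a.chain_id, a.res_index)] = a.res_name
        chain_residues.setdefault(a.chain_id, [])
        if a.res_index not in chain_residues[a.chain_id]:
            chain_residues[a.chain_id].append(a.res_index)

    rows = []
    n_omitted = 0
    for chain_id, residues in chain_residues.items():
        for res_index in residues:
            rname = res_names[(chain_id, res_index)]
            is_dna = rname in DNA_RESIDUES
            for tdef in defs:
                if (tdef.applicability == "dna") != is_dna:
                    continue
                idxs = []
                for name, off in tdef.atoms:
                    target_res = res_index + off
                    target_rname = res_names.get((chain_id, target_res), rname)
                    resolved = _resolve_alias(name, target_rname)
                    j = index.get((chain_id, target_res, resolved))
                    if j is None:
                        break
                    idxs.append(j)
                if len(idxs) != 4:
                    n_omitted += 1
                    continue
                try:
                    ang = compute_dihedral(*(record.atoms[j].position for j in idxs))
                except UndefinedTorsionError:
                    n_omitted += 1
                    continue
                rows.append((chain_id, res_index, tdef.name, ang))

    df = pd.DataFrame(rows, columns=["chain", "residue", "torsion", "angle_deg"])
    df.attrs["n_omitted"] = n_omitted
    return df


# --------------------------------------------------------------------------
# dataset filtering
# --------------------------------------------------------------------------

#: Selection thresholds for the two dataset flavours.
PROTEIN_RESOLUTION_CUT = 2.5   # Å
PROTEIN_MIN_LENGTH = 50        # residues
DNA_RESOLUTION_CUT = 3.0       # Å
DNA_MIN_LENGTH = 5             # nucleotides
DNA_MIN_PROTEIN_LENGTH = 20    # aa, for protein chains allowed alongside DNA


def filter_dataset(entries: Sequence[DatasetEntry],
                   criteria: Literal["protein", "dna"]) -> list[DatasetEntry]:
    """Apply the dataset selection rules and de-duplicate identity clusters.

    Protein sets keep X-ray entries better than 2.5 Å with more than 50
    residues and no nucleic acid; DNA sets keep entries better than 3.0 Å with
    DNA longer than 5 nucleotides, no RNA, and any protein chains longer than
    20 aa.  Within an identity cluster only the best-resolution entry
    survives, standing in for the precomputed non-redundant PDB sets.
    """
    if criteria not in ("protein", "dna"):
        raise ValueError(f"unknown criteria: {criteria}")
    kept: list[DatasetEntry] = []
    for e in entries:
        if e.resolution is None:
            logger.info("filter_dataset: %s rejected (missing resolution)",
                        e.structure_id)
            continue
        if criteria == "protein":
            if not (e.resolution < PROTEIN_RESOLUTION_CUT
                    and e.chain_length > PROTEIN_MIN_LENGTH
                    and not e.contains_dna and not e.contains_rna):
                continue
        else:
            if not (e.resolution < DNA_RESOLUTION_CUT
                    and e.contains_dna
                    and e.chain_length > DNA_MIN_LENGTH
                    and not e.contains_rna):
                continue
            if 0 < e.protein_length <= DNA_MIN_PROTEIN_LENGTH:
                continue
        kept.append(e)

    best: dict[str, DatasetEntry] = {}
    for e in kept:
        if e.cluster is not None and (
                e.cluster not in best or e.resolution < best[e.cluster].resolution):
            best[e.cluster] = e
    return [e for e in kept if e.cluster is None or best[e.cluster] is e]


def read_dataset_table(path: str | Path) -> list[DatasetEntry]:
    """Read a dataset-metadata table (TSV with a documented header).

    Expected columns: ``structure_id resolution polymer_type chain_length
    cluster contains_rna contains_dna protein_length``; resolution may be
    empty, cluster may be empty.
    """
    df = pd.read_csv(path, sep="\t")
    entries = []
    for _, row in df.iterrows():
        res = row["resolution"]
        clu = row["cluster"]
        entries.append(DatasetEntry(
            structure_id=str(row["structure_id"]),
            resolution=None if pd.isna(res) else float(res),
            polymer_type=str(row["polymer_type"]),
            chain_length=int(row["chain_length"]),
            cluster=None if pd.isna(clu) else str(clu),
            contains_rna=bool(row["contains_rna"]),
            contains_dna=bool(row["contains_dna"]),
            protein_length=int(row["protein_length"]),
        ))
    return entries
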