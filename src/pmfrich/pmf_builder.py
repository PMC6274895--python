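"""Pseudo-potentials of mean force from structure ensembles.

Pair distances are histogrammed up to a 2.5 nm cutoff and compared against a
homogeneous density in the cutoff sphere (the quasi-homogeneity
approximation: every structure is treated as sharing one particle number and
one reference volume V = (4/3)π·2.5³ nm³).  Torsions are histogrammed on the
circle.  Boltzmann inversion w = −kT ln g then yields the pseudo-PMF
(p-PMF); the additive constant this normalization leaves undetermined is
exactly what the downstream Ω partition cancels, so each table is simply
shifted to min w = 0 for comparability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from . import structure_io as sio
from .units import KB

logger = logging.getLogger(__name__)

#: Radial cutoff (nm) inside which the associated error is taken as constant.
RADIAL_CUTOFF = 2.5

#: Reference volume of the quasi-homogeneous cutoff sphere, nm³.
V_CUT = 4.0 / 3.0 * math.pi * RADIAL_CUTOFF**3

DEFAULT_RADIAL_BIN = 0.02    # nm
DEFAULT_ANGULAR_BIN = 5.0    # degrees
DEFAULT_G_FLOOR = 1e-6


# --------------------------------------------------------------------------
# histograms
# --------------------------------------------------------------------------

@dataclass
class RadialHistogram:
    """Binned pair-distance counts against the homogeneous reference."""

    key: tuple
    edges: np.ndarray            # nm, strictly increasing, last = cutoff
    counts: np.ndarray
    n_pairs: int = 0
    g: np.ndarray | None = None
    empty: bool = False

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def shell_fractions(self) -> np.ndarray:
        """[V(r+δr) − V(r)] / V_cut for each bin of the cutoff sphere."""
        vol = 4.0 / 3.0 * math.pi * self.edges**3
        return np.diff(vol) / V_CUT


@dataclass
class AngularHistogram:
    """Circular histogram over (−180, 180] with a per-degree density."""

    key: tuple
    edges_deg: np.ndarray
    counts: np.ndarray
    g: np.ndarray | None = None
    empty: bool = False

    @property
    def bin_width(self) -> float:
        return float(self.edges_deg[1] - self.edges_deg[0])

    @property
    def centers_deg(self) -> np.ndarray:
        return 0.5 * (self.edges_deg[:-1] + self.edges_deg[1:])


def _radial_edges(bin_width: float) -> np.ndarray:
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    n_bins = int(round(RADIAL_CUTOFF / bin_width))
    if abs(n_bins * bin_width - RADIAL_CUTOFF) > 1e-9:
        n_bins = int(math.ceil(RADIAL_CUTOFF / bin_width))
    return np.linspace(0.0, RADIAL_CUTOFF, n_bins + 1)


def histogram_distances(distances: Sequence[float], bin_width: float = DEFAULT_RADIAL_BIN,
                        key: tuple = ("samples",)) -> RadialHistogram:
    """Accumulate raw distances (nm) into a radial histogram; values beyond
    the 2.5 nm cutoff are ignored."""
    edges = _radial_edges(bin_width)
    d = np.asarray(distances, dtype=float)
    d = d[(d > 0) & (d <= RADIAL_CUTOFF)]
    counts, _ = np.histogram(d, bins=edges)
    hist = RadialHistogram(key=key, edges=edges, counts=counts.astype(float),
                           n_pairs=int(counts.sum()), empty=counts.sum() == 0)
    if hist.empty:
        logger.warning("histogram_distances: no pairs within cutoff for key %s", key)
    return hist


def accumulate_radial(structures: Sequence[sio.StructureRecord], key_spec: tuple,
                      bin_width: float = DEFAULT_RADIAL_BIN) -> RadialHistogram:
    """Histogram distances between atoms matching ``key_spec`` over all
    structures.

    ``key_spec`` is ``(res_name_a, atom_a, res_name_b, atom_b)``; ``"*"``
    matches any residue type.  Pairs are taken between distinct residues,
    each unordered pair counted once.
    """
    res_a, atom_a, res_b, atom_b = key_spec
    dists: list[float] = []
    for rec in structures:
        sel_a = [(i, a) for i, a in enumerate(rec.atoms)
                 if a.name == atom_a and (res_a == "*" or a.res_name == res_a)]
        sel_b = [(i, a) for i, a in enumerate(rec.atoms)
                 if a.name == atom_b and (res_b == "*" or a.res_name == res_b)]
        seen: set[tuple[int, int]] = set()
        for i, ai in sel_a:
            for j, aj in sel_b:
                if (ai.chain_id, ai.res_index) == (aj.chain_id, aj.res_index):
                    continue
                pair = (min(i, j), max(i, j))
                if pair in seen:
                    continue
                seen.add(pair)
                dists.append(float(np.linalg.norm(ai.position - aj.position)))
    return histogram_distances(dists, bin_width=bin_width, key=key_spec)


def normalize_radial(hist: RadialHistogram) -> np.ndarray:
    """Normalize counts against the homogeneous density in the cutoff sphere:
    g(r) = counts / (N_pairs · shell_fraction).  The identity
    Σ g·shell_fraction = 1 holds by construction."""
    if hist.n_pairs == 0:
        raise ValueError("cannot normalize an empty histogram")
    g = hist.counts / (hist.n_pairs * hist.shell_fractions())
    hist.g = g
    return g


def histogram_angles(angles_deg: Sequence[float],
                     bin_width: float = DEFAULT_ANGULAR_BIN,
                     key: tuple = ("samples",)) -> AngularHistogram:
    """Circular histogram over (−180, 180] with right-closed bins: an angle
    exactly at −180° wraps into the first bin."""
    if bin_width <= 0 or abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-9:
        raise ValueError("bin width must divide 360")
    n_bins = int(round(360.0 / bin_width))
    edges = -180.0 + bin_width * np.arange(n_bins + 1)
    a = np.asarray(angles_deg, dtype=float)
    a = (a - (-180.0)) % 360.0          # (−180,180] → (0,360], −180 → 0
    idx = np.ceil(a / bin_width).astype(int) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    hist = AngularHistogram(key=key, edges_deg=edges, counts=counts,
                            empty=counts.sum() == 0)
    if hist.empty:
        logger.warning("histogram_angles: no angles for key %s", key)
        return hist
    hist.g = counts / (counts.sum() * bin_width)   # density per degree
    return hist


def accumulate_angular(structures: Sequence[sio.StructureRecord], key_spec: tuple,
                       bin_width: float = DEFAULT_ANGULAR_BIN) -> AngularHistogram:
    """Histogram one named torsion of one residue type over all structures.

    ``key_spec`` is ``(res_name, torsion_name)``; ``"*"`` matches any residue
    type.  Torsion definitions are chosen by polymer kind automatically.
    """
    res_name, torsion_name = key_spec
    defs = [d for d in (*sio.PROTEIN_TORSIONS, *sio.DNA_TORSIONS)
            if d.name == torsion_name]
    if not defs:
        raise ValueError(f"unknown torsion name: {torsion_name}")
    angles: list[float] = []
    for rec in structures:
        df = sio.extract_torsion_series(rec, defs)
        if df.empty:
            continue
        if res_name != "*":
            res_lookup = {(a.chain_id, a.res_index): a.res_name for a in rec.atoms}
            keep = [res_lookup[(c, r)] == res_name
                    for c, r in zip(df["chain"], df["residue"])]
            df = df[keep]
        angles.extend(df["angle_deg"].tolist())
    return histogram_angles(angles, bin_width=bin_width, key=key_spec)


# --------------------------------------------------------------------------
# Boltzmann inversion and interpolation
# --------------------------------------------------------------------------

@dataclass
class PmfTable:
    """A binned p-PMF curve over a distance or torsion coordinate.

    Distance tables use bin centers in nm; torsion tables store centers in
    radians internally (degrees at serialization boundaries).  ``capped``
    flags bins whose density hit the floor g_min during inversion.
    """

    key: tuple
    kind: Literal["distance", "torsion"]
    centers: np.ndarray
    w: np.ndarray                    # kJ/mol, min-shifted to 0
    temperature: float
    g_floor: float
    capped: np.ndarray
    interpolation_order: int = 3
    _spline: CubicSpline | None = field(default=None, repr=False, compare=False)
    _uniform: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.w)):
            raise ValueError("p-PMF values must be finite (use a g floor)")

    def spline(self) -> CubicSpline:
        if self._spline is None:
            if self.kind == "torsion":
                x = np.concatenate([self.centers, [self.centers[0] + 2 * math.pi]])
                y = np.concatenate([self.w, [self.w[0]]])
                self._spline = CubicSpline(x, y, bc_type="periodic")
            else:
                self._spline = CubicSpline(self.centers, self.w, bc_type="natural")
        return self._spline

    def shifted(self, delta: float) -> "PmfTable":
        """Copy with a constant added to every w (test hook for the shared
        offset δw; interpolated derivatives are unchanged)."""
        return PmfTable(key=self.key, kind=self.kind, centers=self.centers.copy(),
                        w=self.w + delta, temperature=self.temperature,
                        g_floor=self.g_floor, capped=self.capped.copy())


def boltzmann_invert(hist: RadialHistogram | AngularHistogram,
                     temperature: float = 300.0,
                     g_floor: float = DEFAULT_G_FLOOR) -> PmfTable:
    """Invert a normalized distribution into a p-PMF: w = −kT ln(max(g, g_min)),
    shifted so min w = 0.  Floored bins carry the cap value and a flag."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if hist.g is None:
        if isinstance(hist, RadialHistogram):
            normalize_radial(hist)
        else:
            raise ValueError("histogram not normalized")
    g = np.asarray(hist.g, dtype=float)
    if np.all(g == 0):
        raise ValueError("all-zero distribution cannot be inverted")
    capped = g < g_floor
    kT = KB * temperature
    w = -kT * np.log(np.maximum(g, g_floor))
    w = w - w.min()
    if isinstance(hist, RadialHistogram):
        return PmfTable(key=hist.key, kind="distance", centers=hist.centers.copy(),
                        w=w, temperature=temperature, g_floor=g_floor, capped=capped)
    centers = np.radians(hist.centers_deg)
    return PmfTable(key=hist.key, kind="torsion", centers=centers, w=w,
                    temperature=temperature, g_floor=g_floor, capped=capped)


def interpolate(table: PmfTable, x: float) -> tuple[float, float]:
    """Continuous (w, dw/dx) at coordinate ``x`` (nm, or radians for
    torsions).  Distances are clamped to the tabulated support and held flat
    beyond it (zero derivative: no information, no force); torsions are
    evaluated periodically.  Evaluates the cubic-spline piece directly from
    its polynomial coefficients (cheap enough for per-step engine use)."""
    if len(table.centers) == 0:
        raise ValueError("empty table")
    sp = table.spline()
    outside = False
    if table.kind == "torsion":
        lo = table.centers[0]
        xx = (x - lo) % (2 * math.pi) + lo
    else:
        xx = min(max(x, table.centers[0]), table.centers[-1])
        outside = xx != x
    if table._uniform is None:
        xb = np.ascontiguousarray(sp.x)
        coef = np.ascontiguousarray(sp.c)
        steps = np.diff(xb)
        uniform = bool(np.allclose(steps, steps[0], rtol=1e-9))
        table._uniform = (uniform, float(xb[0]),
                          1.0 / float(steps[0]) if uniform else 0.0,
                          xb.tolist(), coef.tolist())
    uniform, x0, inv_h, xb, coef = table._uniform
    n_iv = len(xb) - 2
    if uniform:
        i = int((xx - x0) * inv_h)
    else:
        i = int(np.searchsorted(sp.x, xx)) - 1
    i = 0 if i < 0 else (n_iv if i > n_iv else i)
    t = xx - xb[i]
    c0, c1, c2, c3 = coef[0][i], coef[1][i], coef[2][i], coef[3][i]
    w = ((c0 * t + c1) * t + c2) * t + c3
    dw = 0.0 if outside else (3.0 * c0 * t + 2.0 * c1) * t + c2
    return w, dw


# --------------------------------------------------------------------------
# sequence-keyed library
# --------------------------------------------------------------------------

ONE_TO_THREE = {v: k for k, v in sio.THREE_TO_ONE.items() if len(k) == 3
                and not k.startswith("D")}
ONE_TO_THREE_DNA = {"A": "DA", "G": "DG", "C": "DC", "T": "DT"}


@dataclass
class LibraryEntry:
    """One biasable coordinate of a target bound to its p-PMF table."""

    kind: Literal["distance", "torsion"]
    label: str
    sites: tuple                      # ((res_index, atom_name), ...) or bead ids
    table: PmfTable


@dataclass
class PmfLibrary:
    """Mapping from the biasable coordinates of a target to p-PMF tables."""

    entries: list[LibraryEntry] = field(default_factory=list)
    gaps: list[str] = field(default_factory=list)
    kind: str = "protein"

    def __len__(self) -> int:
        return len(self.entries)

    def torsion_entries(self) -> list[LibraryEntry]:
        return [e for e in self.entries if e.kind == "torsion"]

    def distance_entries(self) -> list[LibraryEntry]:
        return [e for e in self.entries if e.kind == "distance"]


def build_library(sequence: str, tables: Mapping[str, PmfTable],
                  kind: Literal["protein", "dna"] = "protein") -> PmfLibrary:
    """Deterministically map every biasable torsion and declared atom pair of
    a target sequence to a table.

    Table keys: torsions ``"RES:torsion"`` (e.g. ``"ALA:phi"``); pairs
    ``"RES1.AT1-RES2.AT2"``.  Missing tables become entries in the gap
    report; the corresponding coordinate simply stays unbiased.
    """
    lib = PmfLibrary(kind=kind)
    one_to_three = ONE_TO_THREE if kind == "protein" else ONE_TO_THREE_DNA
    res3: list[str | None] = []
    for ch in sequence:
        r3 = one_to_three.get(ch.upper())
        if r3 is None:
            lib.gaps.append(f"unknown residue {ch!r}")
        res3.append(r3)
    n = len(res3)

    if kind == "protein":
        torsion_sites = {
            "phi": lambda i: ((i - 1, "C"), (i, "N"), (i, "CA"), (i, "C")),
            "psi": lambda i: ((i, "N"), (i, "CA"), (i, "C"), (i + 1, "N")),
        }
        applicable = {"phi": range(2, n + 1), "psi": range(1, n)}
    else:
        torsion_sites = {
            "alpha": lambda i: ((i - 1, "O3'"), (i, "P"), (i, "O5'"), (i, "C5'")),
            "beta": lambda i: ((i, "P"), (i, "O5'"), (i, "C5'"), (i, "C4'")),
            "gamma": lambda i: ((i, "O5'"), (i, "C5'"), (i, "C4'"), (i, "C3'")),
            "delta": lambda i: ((i, "C5'"), (i, "C4'"), (i, "C3'"), (i, "O3'")),
            "epsilon": lambda i: ((i, "C4'"), (i, "C3'"), (i, "O3'"), (i + 1, "P")),
            "zeta": lambda i: ((i, "C3'"), (i, "O3'"), (i + 1, "P"), (i + 1, "O5'")),
        }
        applicable = {"alpha": range(2, n + 1), "beta": range(1, n + 1),
                      "gamma": range(1, n + 1), "delta": range(1, n + 1),
                      "epsilon": range(1, n), "zeta": range(1, n)}

    for tname, rng in applicable.items():
        for i in rng:
            r3 = res3[i - 1]
            if r3 is None:
                continue
            key = f"{r3}:{tname}"
            table = tables.get(key)
            if table is None:
                if key not in lib.gaps:
                    lib.gaps.append(key)
                continue
            lib.entries.append(LibraryEntry(
                kind="torsion", label=f"{tname}@{i}",
                sites=torsion_sites[tname](i), table=table))

    # pair tables: apply every provided pair key to every matching residue pair
    for key, table in tables.items():
        if table.kind != "distance":
            continue
        try:
            part_a, part_b = key.split("-")
            ra, atom_a = part_a.split(".")
            rb, atom_b = part_b.split(".")
        except ValueError:
            continue
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                pa, pb = res3[i - 1], res3[j - 1]
                if pa is None or pb is None:
                    continue
                if {(pa, pb), (pb, pa)} & {(ra, rb)}:
                    lib.entries.append(LibraryEntry(
                        kind="distance", label=f"{atom_a}{i}-{atom_b}{j}",
                        sites=((i, atom_a), (j, atom_b)), table=table))
    if lib.gaps:
        logger.info("build_library: %d unbiased coordinates (missing tables): %s",
                    len(lib.gaps), lib.gaps)
    return lib


def library_for_topology(topology, torsion_table: PmfTable | None = None,
                         pair_table: PmfTable | None = None) -> PmfLibrary:
    """Bind a toy topology's declared biasable coordinates to tables; the
    toy-engine counterpart of the sequence-keyed editing step."""
    lib = PmfLibrary(kind="toy")
    if torsion_table is not None:
        for quad in topology.biasable_torsions:
            lib.entries.append(LibraryEntry(kind="torsion",
                                            label=f"dihedral{quad}",
                                            sites=tuple(quad), table=torsion_table))
    if pair_table is not None:
        for pair in topology.biasable_pairs:
            lib.entries.append(LibraryEntry(kind="distance",
                                            label=f"pair{pair}",
                                            sites=tuple(pair), table=pair_table))
    return lib


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def write_pmf_table(table: PmfTable, path: str | Path) -> None:
    """Delimited-text serialization: header line then (center, w, capped)
    rows; torsion centers written in degrees."""
    with open(Path(path), "w") as fh:
        fh.write(f"# key={'|'.join(map(str, table.key))} kind={table.kind} "
                 f"temperature={table.temperature} g_floor={table.g_floor}\n")
        fh.write("center\tw_kJ_mol\tcapped\n")
        centers = (np.degrees(table.centers) if table.kind == "torsion"
                   else table.centers)
        for c, w, f in zip(centers, table.w, table.capped):
            fh.write(f"{c:.8g}\t{w:.10g}\t{int(f)}\n")


def read_pmf_table(path: str | Path) -> PmfTable:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(item.split("=", 1) for item in header.split())
        fh.readline()
        rows = [line.split() for line in fh if line.strip()]
    centers = np.array([float(r[0]) for r in rows])
    w = np.array([float(r[1]) for r in rows])
    capped = np.array([bool(int(r[2])) for r in rows])
    kind = meta["kind"]
    if kind == "torsion":
        centers = np.radians(centers)
    return PmfTable(key=tuple(meta["key"].split("|")), kind=kind, centers=centers,
                    w=w, temperature=float(meta["temperature"]),
                    g_floor=float(meta["g_floor"]), capped=capped)
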