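"""Reusable study drivers: the double-well escape experiment.

The toy analog of a torsion-barrier escape study: a 5-bead chain whose
0-1-2-3 dihedral carries a symmetric 8 kT double well (minima at 0° and
180°).  The chain starts in the trans basin; knowledge-based tables whose
minima sit on that populated basin destabilize it through the Ω-partition
gradient, and the median first-passage time out of the basin is measured
over seeds for a grid of coupling strengths α.  Trajectories that never
escape within the run are censored at the run length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fixture_gen
from .analysis import CrossingSpec, first_passage_time
from .geometry import dihedral_batch
from .hybrid_engine import HybridCoupling, ToyTopology, run_pmf_enriched
from .pmf_builder import PmfLibrary, PmfTable, library_for_topology

#: escape definition: leave the trans basin (|φ| = 180° at the start) and
#: cross well past the 90° barrier top, to |φ| < 75°
ESCAPE_BEYOND_DEG = 105.0     # on the 180 − |φ| scale

DEFAULT_ALPHAS = (0.0, 1e-3, 1e-2, 1e-1)
DEFAULT_EPSILON = 20.0
DEFAULT_N_STEPS = 60_000
DEFAULT_DT = 0.004            # ps


def toy_bias_tables(temperature: float = 300.0) -> tuple[PmfTable, PmfTable]:
    """Synthetic p-PMF tables for the toy escape study.

    The torsion table has its minimum at ±180° (the populated trans basin)
    and the pair table a harmonic minimum at a near-contact 1–4 distance, so
    the partition gradient destabilizes the starting basin.  Only the
    direction field matters: the renormalization fixes the bias magnitude to
    α·‖∇H(A)‖ regardless of table steepness.
    """
    cen = np.radians(np.arange(-177.5, 180.0, 5.0))
    w = 5.0 * (1.0 + np.cos(cen))
    w -= w.min()
    torsion = PmfTable(key=("toy", "dihedral"), kind="torsion", centers=cen,
                       w=w, temperature=temperature, g_floor=1e-6,
                       capped=np.zeros(w.shape, dtype=bool))
    rcen = np.arange(0.01, 2.5, 0.02)
    wr = 20.0 * (rcen - 0.45) ** 2
    wr -= wr.min()
    pair = PmfTable(key=("toy", "pair"), kind="distance", centers=rcen, w=wr,
                    temperature=temperature, g_floor=1e-6,
                    capped=np.zeros(wr.shape, dtype=bool))
    return torsion, pair


def make_escape_system(barrier_kT: float = 8.0
                       ) -> tuple[ToyTopology, PmfLibrary]:
    """The 5-bead double-well chain with its bias library (2 biasable
    dihedrals, 3 biasable 1–4+ pairs)."""
    topology = fixture_gen.make_toy_chain(5, preset="double_well",
                                          barrier_kT=barrier_kT)
    torsion_table, pair_table = toy_bias_tables()
    library = library_for_topology(topology, torsion_table=torsion_table,
                                   pair_table=pair_table)
    return topology, library


def escape_time(topology: ToyTopology, library: PmfLibrary, alpha: float,
                seed: int, n_steps: int = DEFAULT_N_STEPS,
                dt: float = DEFAULT_DT, epsilon: float = DEFAULT_EPSILON,
                monitor_interval: int = 10) -> float:
    """First-passage time (ps) of the double-well dihedral out of the trans
    basin for one seed; inf when censored at the run length."""
    quad = np.array([[0, 1, 2, 3]])
    series: list[float] = []

    def monitor(step, state):
        phi = math.degrees(dihedral_batch(state.positions, quad)[0][0])
        series.append(180.0 - abs(phi))
        if 180.0 - abs(phi) > ESCAPE_BEYOND_DEG:
            return False

    coupling = HybridCoupling(alpha=alpha, epsilon=epsilon)
    run_pmf_enriched(topology, library, coupling, n_steps, dt, seed,
                     log_interval=max(n_steps, 1), callback=monitor,
                     callback_interval=monitor_interval)
    spec = CrossingSpec(target_above=ESCAPE_BEYOND_DEG)
    return first_passage_time(series, dt * monitor_interval, spec)


@dataclass
class EscapeStudy:
    """Median escape times per coupling strength."""

    table: pd.DataFrame          # columns: alpha, median_tau, n_censored
    run_length: float            # ps

    def medians_censored(self) -> np.ndarray:
        """Medians with censored entries replaced by the run length."""
        return np.where(np.isinf(self.table["median_tau"]),
                        self.run_length, self.table["median_tau"])

    def acceleration(self) -> float:
        """Run-length-censored unbiased median over the largest-α median."""
        med = self.medians_censored()
        return float(med[0] / med[-1])


def double_well_escape_study(alphas=DEFAULT_ALPHAS, n_seeds: int = 20,
                             n_steps: int = DEFAULT_N_STEPS,
                             dt: float = DEFAULT_DT, seed: int = 0,
                             epsilon: float = DEFAULT_EPSILON) -> EscapeStudy:
    """Median first-passage times over seeds for an increasing α grid."""
    topology, library = make_escape_system()
    rows = []
    for alpha in alphas:
        taus = [escape_time(topology, library, alpha, seed * 1000 + s,
                            n_steps=n_steps, dt=dt, epsilon=epsilon)
                for s in range(n_seeds)]
        rows.append({"alpha": alpha, "median_tau": float(np.median(taus)),
                     "n_censored": int(sum(math.isinf(t) for t in taus))})
    return EscapeStudy(table=pd.DataFrame(rows), run_length=n_steps * dt)
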