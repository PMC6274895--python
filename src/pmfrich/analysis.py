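"""Analysis layer: free-energy surfaces, order parameters, conformer-class
assignment, transition kinetics, and escape-time acceleration.

All operations here are deterministic functions of their inputs.  Free
energies use the modal-reference convention ΔF = −kT·ln(p/p_max), so the
most probable bin sits at 0 and everything else is ≥ 0 (reported in kT).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

NON_ASSIGNED = "NANT"


# --------------------------------------------------------------------------
# free-energy surfaces and order parameters
# --------------------------------------------------------------------------

@dataclass
class FreeEnergySurface:
    """Binned probabilities and ΔF = −ln(P/P_max) in kT over 1 or 2 order
    parameters; empty bins carry +inf and are flagged."""

    edges: tuple[np.ndarray, ...]
    counts: np.ndarray
    probabilities: np.ndarray
    delta_f_kt: np.ndarray
    empty_bins: np.ndarray


def free_energy_surface(samples, bins=50) -> FreeEnergySurface:
    """Histogram a 1-D series or an (n, 2) array of order-parameter pairs
    and convert to ΔF in kT with the modal bin at zero."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no samples")
    if samples.ndim == 1:
        counts, edges = np.histogram(samples, bins=bins)
        edges = (edges,)
    elif samples.ndim == 2 and samples.shape[1] == 2:
        counts, ex, ey = np.histogram2d(samples[:, 0], samples[:, 1], bins=bins)
        edges = (ex, ey)
    else:
        raise ValueError("samples must be 1-D or (n, 2)")
    counts = counts.astype(float)
    p = counts / counts.sum()
    empty = counts == 0
    with np.errstate(divide="ignore"):
        df = -np.log(np.where(empty, np.nan, p) / p.max())
    df = np.where(empty, np.inf, df)
    return FreeEnergySurface(edges=edges, counts=counts, probabilities=p,
                             delta_f_kt=df, empty_bins=empty)


def rmsd(coords: np.ndarray, reference: np.ndarray,
         selection: Sequence[int] | None = None) -> float:
    """Least-squares-superposed RMSD (nm): optimal rotation after centering."""
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is not None:
        coords = coords[list(selection)]
        reference = reference[list(selection)]
    if coords.shape != reference.shape:
        raise ValueError("coordinate sets must have equal shapes")
    if len(coords) < 3:
        raise ValueError("need at least 3 atoms for superposition")
    a = coords - coords.mean(axis=0)
    b = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(b, a)
    a_rot = rot.apply(a)
    return float(np.sqrt(np.mean(np.sum((a_rot - b) ** 2, axis=1))))


def radius_of_gyration(coords: np.ndarray,
                       masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration about the center of mass (nm)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or len(coords) < 1:
        raise ValueError("need at least one atom")
    m = (np.ones(len(coords)) if masses is None
         else np.asarray(masses, dtype=float))
    total = m.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (m[:, None] * coords).sum(axis=0) / total
    return float(np.sqrt((m * np.sum((coords - com) ** 2, axis=1)).sum() / total))


# --------------------------------------------------------------------------
# conformer classes
# --------------------------------------------------------------------------

@dataclass
class ConformerCentroidTable:
    """User-supplied conformer-class centroids in torsion space (degrees).

    ``centroids`` maps class label → reference torsion vector; ``radii``
    maps label → acceptance radius.  A nearest-centroid surrogate for
    external structural-alphabet assignments: vectors farther than the
    nearest class radius go to the non-assigned class.
    """

    centroids: Mapping[str, np.ndarray]
    radii: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(self.centroids) == 0:
            raise ValueError("empty centroid table")
        dims = {len(np.atleast_1d(v)) for v in self.centroids.values()}
        if len(dims) != 1:
            raise ValueError("centroid vectors must share one dimensionality")
        for lbl, r in self.radii.items():
            if r <= 0:
                raise ValueError(f"radius for {lbl} must be positive")

    @property
    def dimension(self) -> int:
        return len(np.atleast_1d(next(iter(self.centroids.values()))))


def wrapped_distance_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance in torsion space with periodic components."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    d = np.minimum(d, 360.0 - d)
    return float(np.sqrt(np.sum(d * d)))


def assign_classes(torsion_vectors: np.ndarray,
                   table: ConformerCentroidTable) -> list[str]:
    """Nearest-centroid class per torsion vector (degrees); vectors beyond
    the nearest class radius — or with missing components — are NANT."""
    torsion_vectors = np.atleast_2d(np.asarray(torsion_vectors, dtype=float))
    if torsion_vectors.shape[1] != table.dimension:
        raise ValueError("torsion vector dimensionality does not match table")
    labels = []
    for vec in torsion_vectors:
        if not np.all(np.isfinite(vec)):
            labels.append(NON_ASSIGNED)
            continue
        best, best_d = None, math.inf
        for lbl, cen in table.centroids.items():
            d = wrapped_distance_deg(vec, cen)
            if d < best_d:
                best, best_d = lbl, d
        if best_d <= table.radii[best]:
            labels.append(best)
        else:
            labels.append(NON_ASSIGNED)
    return labels


def class_partition(labels: pd.DataFrame) -> pd.DataFrame:
    """ΔF(class, step) in kT from a (time × step-index) label table.

    Per step-index column, class probabilities are referenced to the modal
    class: ΔF = −ln(p/p_max).  Classes never seen in a step are absent
    (NaN).  Invariant under permutation of the time axis.
    """
    out = {}
    for col in labels.columns:
        p = labels[col].value_counts(normalize=True)
        out[col] = -np.log(p / p.max())
    return pd.DataFrame(out).sort_index()


# --------------------------------------------------------------------------
# kinetics
# --------------------------------------------------------------------------

@dataclass
class TransitionRateMatrix:
    """Mean waiting times τ_ik and log-frequencies ln ν_ik = −ln τ_ik."""

    classes: list[str]
    tau: pd.DataFrame            # NaN where never observed (τ = ∞)
    counts: pd.DataFrame

    def log_frequency(self) -> pd.DataFrame:
        return -np.log(self.tau)


def transition_rates(labels: Sequence[str], dt: float) -> TransitionRateMatrix:
    """First-passage dwell kinetics of a label series.

    τ_ik is the mean time spent in class i immediately before a transition
    to class k; ν_ik = 1/τ_ik.  Never-observed pairs are absent (the τ = ∞,
    no-transition case).
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least two frames")
    dwell_sums: dict[tuple[str, str], float] = {}
    dwell_counts: dict[tuple[str, str], int] = {}
    run_start = 0
    for t in range(1, len(labels)):
        if labels[t] != labels[t - 1]:
            pair = (labels[t - 1], labels[t])
            dwell = (t - run_start) * dt
            dwell_sums[pair] = dwell_sums.get(pair, 0.0) + dwell
            dwell_counts[pair] = dwell_counts.get(pair, 0) + 1
            run_start = t
    classes = sorted(set(labels))
    tau = pd.DataFrame(np.nan, index=classes, columns=classes)
    counts = pd.DataFrame(0, index=classes, columns=classes)
    for (i, k), s in dwell_sums.items():
        tau.loc[i, k] = s / dwell_counts[(i, k)]
        counts.loc[i, k] = dwell_counts[(i, k)]
    return TransitionRateMatrix(classes=classes, tau=tau, counts=counts)


# --------------------------------------------------------------------------
# escape times
# --------------------------------------------------------------------------

@dataclass
class CrossingSpec:
    """First-passage definition: series must start below ``start_below`` (if
    given) and τ is the first time the value exceeds ``target_above``."""

    target_above: float
    start_below: float | None = None


@dataclass
class EscapeResult:
    tau_biased: float
    tau_reference: float
    acceleration: float
    n_censored_biased: int = 0
    n_censored_reference: int = 0


def first_passage_time(series: Sequence[float], dt: float,
                       spec: CrossingSpec) -> float:
    """First time the series exceeds the target; inf if it never does
    (censored).  A series already beyond the target at t = 0 returns 0."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    if spec.start_below is not None and series[0] >= spec.start_below \
            and series[0] <= spec.target_above:
        raise ValueError("series does not start in the required basin")
    hits = np.nonzero(series > spec.target_above)[0]
    return float(hits[0] * dt) if hits.size else math.inf


def escape_time_and_acceleration(biased_series: Sequence[Sequence[float]],
                                 reference_series: Sequence[Sequence[float]],
                                 dt: float, spec: CrossingSpec) -> EscapeResult:
    """Median first-passage times over seeds and the acceleration factor
    n = τ_reference/τ_biased; non-crossing trajectories enter the medians as
    inf (censored)."""
    tb = [first_passage_time(s, dt, spec) for s in biased_series]
    tr = [first_passage_time(s, dt, spec) for s in reference_series]
    med_b = float(np.median(tb))
    med_r = float(np.median(tr))
    if med_b == 0.0:
        accel = math.inf
    elif math.isinf(med_r) and math.isinf(med_b):
        accel = 1.0
    else:
        accel = med_r / med_b
    return EscapeResult(tau_biased=med_b, tau_reference=med_r,
                        acceleration=accel,
                        n_censored_biased=sum(math.isinf(t) for t in tb),
                        n_censored_reference=sum(math.isinf(t) for t in tr))
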