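# pmfrich

Knowledge-based **PMF-enriched sampling** for biomolecular simulation, at
desk scale.

Structure databases encode which conformations proteins and DNA actually
adopt, but their entries come from heterogeneous experiments, so no true
Boltzmann ensemble underlies pooled statistics.  This package implements
the full chain of the PMF-enriched method around that obstacle:

1. **Pseudo-PMFs** — pair-distance and backbone-torsion distributions are
   accumulated from structure sets (PDB format) under a *quasi-homogeneity*
   approximation (one reference volume, V = (4/3)π·2.5³ nm³) and
   Boltzmann-inverted, w = −kT·ln g.  Each table carries an unknown
   additive offset δw.
2. **The Ω partition** — a normalized (softmax) partition over the active
   p-PMF values, Ω_i = e^(−βw_i)/Σ_j e^(−βw_j).  Any offset shared by the
   tables cancels exactly, so the *gradient of Ω* is a usable bias even
   though the w values themselves are not.  Analytic gradients, including
   cross-terms and the Cartesian pair/torsion mapping, are exact.
3. **A renormalized hybrid Hamiltonian** —
   ∇H(C) = ∇H(A)/(1+α) + α·(‖∇H(A)‖/‖∇H(B)‖)·∇H(B), with a fluctuating
   coupling α(t) of long-run mean α: the bias is a controlled fraction of
   the reference gradient, never a wall in energy space.
4. **A toy Langevin engine** (BAOA) with bead-chain topologies, a seeded
   synthetic-data generator (wrapped-Gaussian torsion ensembles, Boltzmann
   pair-distance samples, double-well chains), a **path-sampling**
   comparator (adaptive bias + well-tempered deposits along the action
   variable L = ∮p dq), and an **analysis layer**: free-energy landscapes,
   RMSD/Rg, nearest-centroid conformer classes, transition kinetics
   ln ν = −ln τ, and first-passage escape times with censoring.

Everything runs on one CPU in minutes; no downloads, no external force
fields.

## Worked example

Build a torsion p-PMF from a synthetic helical ensemble, then measure how
the coupling strength α accelerates escape from an 8 kT double well:

```python
import numpy as np
from pmfrich import fixture_gen, pmf_builder as pb
from pmfrich.experiments import double_well_escape_study

records = fixture_gen.make_torsion_ensemble(
    400, {"phi": -57.0, "psi": -47.0}, torsion_sigmas=15.0, seed=7)
hist = pb.accumulate_angular(records, ("ALA", "phi"))
table = pb.boltzmann_invert(hist, temperature=300.0)
print(f"phi p-PMF: {len(table.centers)} bins, "
      f"minimum at {np.degrees(table.centers[np.argmin(table.w)]):.1f} deg, "
      f"barrier to flat region {table.w[~table.capped].max():.2f} kJ/mol")

study = double_well_escape_study(n_seeds=6, n_steps=30_000, seed=1)
print(study.table.to_string(index=False))
print(f"acceleration factor (censored at {study.run_length:.0f} ps): "
      f"{study.acceleration():.1f}x")
```

prints

```
phi p-PMF: 72 bins, minimum at -57.5 deg, barrier to flat region 13.66 kJ/mol
 alpha  median_tau  n_censored
 0.000         inf           3
 0.001         inf           6
 0.010         inf           4
 0.100        44.6           1
acceleration factor (censored at 120 ps): 2.7x
```

The recovered p-PMF has its minimum at the generator's Φ mean (−57°).  In
the escape study, weak couplings mostly never cross the barrier within the
run (`median_tau = inf`, the no-transition case, counted at the run length),
while α = 0.1 escapes in tens of picoseconds.  The full study conditions
(20 seeds, 240 ps runs) give a sharper picture and are what
`scripts/acceptance.py` reruns.

A thin CLI wraps the same calls: `pmfrich build-pmf`, `pmfrich simulate`,
`pmfrich path-sample`, `pmfrich analyze` (see `--help`).

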