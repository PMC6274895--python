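# Methods

## The model

`pmfrich` implements knowledge-based *PMF-enriched sampling*: a molecular
system governed by a reference Hamiltonian H(A) (a force field) is coupled
to an auxiliary Hamiltonian H(B) built from the statistics of a structure
database, so that the dynamics is enriched with conformations that the
database considers probable, without materially perturbing the total energy.

### Pseudo-potentials of mean force

For a set of structures, pair-distance distributions g(r) (per residue-type
pair and atom-name pair, up to a 2.5 nm cutoff) and torsion distributions
g(θ) (Φ/Ψ for proteins; α, β, γ, δ, ε, ζ, χ for DNA) are accumulated and
Boltzmann-inverted,

    w(r) = −kB·T · ln g(r),        w(θ) = −kB·T · ln g(θ).

Because the source structures come from heterogeneous experiments (different
particle numbers, volumes, and conditions), no true Boltzmann ensemble
underlies the pooled histograms.  The *quasi-homogeneity* approximation
treats every structure as sharing one particle number and one reference
volume — here the cutoff sphere V = (4/3)π·2.5³ nm³ — giving
*pseudo*-PMFs that each carry an unknown additive offset δw, assumed
constant within the cutoff.

Radial histograms are normalized against the homogeneous density in the
cutoff sphere: g(r) = counts / (N_pairs · [V(r+δr) − V(r)]/V_cut) with exact
spherical-shell volumes.  This removes the r² Jacobian, so Boltzmann
inversion of a synthetic ensemble drawn from density ∝ r²e^(−βu(r)) recovers
u(r) up to an additive constant — the recovery test asserts RMSE < 0.25 kT
on well-populated bins at 10⁵ samples.  The angular counterpart checks the
near-minimum curvature of the inverted wrapped-Gaussian profile against
kT/σ² (σ = 15°): since −ln g of a wrapped Gaussian is exactly quadratic,
the quadratic is fitted over ±1.5σ with 2° bins and 3000 structures — the
wider window conditions the fit without bias, and the estimator then
concentrates well inside the 15% comparison band.  Empty bins are floored at a density
g_min = 10⁻⁶ (configurable) and flagged: unvisited regions become high but
finite plateaus rather than infinite walls, and the reference force field
dominates there after renormalization.

### The Ω partition and its gradient

The offsets δw would poison any bias built from the w values directly.  The
method instead forms a normalized partition over the p-PMF values active at
the current configuration,

    Ω_i = e^(−β w_i) / Σ_j e^(−β w_j),   Σ_i Ω_i = 1,

evaluated separately for the radial set {w(r_ij)} and the angular set
{w(θ_k)}, and re-evaluated from scratch at every step.  A constant offset
shared by every w cancels between numerator and denominator, so Ω and every
gradient derived from it are exactly invariant under δw — the property the
error-cancellation tests assert to 1e−12 for offsets up to ±100 kJ/mol.

The applied bias is the gradient of Ω.  With J_ij = ∂Ω_i/∂x_j
= β Ω_i Ω_j w′_j − δ_ij β Ω_i w′_i (the quotient-rule derivative; the cross
term carries a positive sign), the per-coordinate bias is by default the
total derivative of Ω_i with all coordinates co-varying,
g_i = −β Ω_i w′_i + β Ω_i Σ_j Ω_j w′_j, which matches the printed two-term
structure of the published gradient; a diagonal-only mode
(−β Ω_i (1−Ω_i) w′_i) is available by flag.  Both are validated against
central finite differences, including the Cartesian mapping (pair terms act
equal-and-opposite along the inter-atom unit vector; torsion terms through
the four-atom dihedral gradient, which is translation- and torque-free).

Note one consequence of this sign convention (∇H(B) = dΩ/dx, applied force
= −gradient): the bias force points *up* the local p-PMF slope, so a
partition whose minima coincide with the currently populated basin
destabilizes that basin.  That is how the escape study below drives barrier
crossings: the synthetic "database" tables place their minima on the
occupied trans basin and on a compact pair-distance target.

### Renormalized hybrid Hamiltonian

The bias enters only as a renormalized fluctuation:

    ∇H(C) = ∇H(A)/(1+α) + α·(‖∇H(A)‖/‖∇B_rad‖)·∇B_rad
                        + α·(‖∇H(A)‖/‖∇B_ang‖)·∇B_ang,

with global Euclidean norms over the biased atoms.  Each bias term therefore
has norm exactly α(t)·‖∇H(A)‖ (asserted at every logged step to 1e−12
relative), a zero-norm term contributes nothing, and α = 0 reproduces the
unbiased gradient bitwise — the engine keeps the thermostat and the α(t)
random streams separate so an α = 0 run is bit-identical to an unbiased run
with the same seed.  The radial and angular terms are renormalized
independently (a joint mode exists).  Norms are global rather than per-atom:
per-atom normalization would change the direction field of the bias, which
is defined by the p-PMF geometry.

The coupling fluctuates: α(t) = α(1−ξ)ε with ξ ~ U[0,1] ("literal" mode,
empirical mean αε/2), or that draw rescaled by 2/ε so the long-run mean is
exactly α ("mean-preserving", the default, since the stated contract is
⟨α(t)⟩ = α).  The two published defining equations are mutually inconsistent
for general ε; in the mean-preserving mode the width parameter cancels and
α(t) ~ U[0, 2α] regardless of ε — we keep ε in the interface for the
literal mode and for fidelity to the published parameter set
(ε ∈ {1, 10, 20, 25}).

### Integrator

Dynamics is Langevin (BAOA splitting: full kick, half drift,
Ornstein–Uhlenbeck momentum refresh, half drift), which shares
configurational averages with BAOAB and is unconditionally stable at toy
scale; equipartition on a stiff harmonic bond is verified to 5%.  This
deliberately replaces the published explicit-solvent setup (Nosé–Hoover,
PME, SETTLE/LINCS), which is out of scope here.  Units: kJ/mol, nm, ps, amu,
kB = 0.008314462618 kJ/mol/K, T = 300 K throughout.

## Toy systems and the synthetic-data generator

The generators stand in for the database-scale structure sets and for the
production molecular systems; they are first-class, tested code.

* **Torsion ensembles** — backbone-only polypeptides rebuilt from torsions
  by NeRF with ideal bond lengths/angles (N–CA 1.458 Å, CA–C 1.525 Å,
  C–N 1.329 Å; N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°; ω = 180°), so
  extracted torsions equal the wrapped-Gaussian draws exactly.  An
  idealized DNA dinucleotide builder exposes β, γ, δ, ε, ζ, χ (residue 1)
  and α, β, γ, δ, χ (residue 2).  The generators emulate torsion
  *statistics* only — no sidechains, solvent, packing, or sequence
  correlations — so passing recovery tests demonstrates the estimator
  pipeline, not fidelity to real crystallographic ensembles.
* **Pair ensembles** — distances drawn by inverse-CDF sampling from
  ∝ r² e^(−βu(r)) on (0, 2.5] nm for a stated u(r): exact ground truth for
  the radial pipeline.
* **Toy chains** — bead chains with harmonic bonds (k = 8000 kJ/mol/nm²,
  r₀ = 0.153 nm), harmonic angles (150 kJ/mol/rad², 111°), short-range r⁻¹²
  repulsion, and dihedral terms.  The *dialanine analog* carries a
  symmetric double well U(φ) = B·sin²φ (minima 0°/180°, barrier exactly B)
  on its first dihedral.  Because a softmax over a single coordinate has a
  vanishing gradient, the escape study uses a 5-bead chain: two biasable
  dihedrals and three biasable 1–4⁺ pairs.

Every generator derives one RNG stream per call as
`default_rng([seed, SALT])` with a fixed per-function salt, making runs
bit-reproducible and mutually independent.

## The escape-time study

Study conditions, fixed once from a physical pilot of the unbiased toy:
barrier 8 kT at 300 K, dt = 0.004 ps, friction 2 ps⁻¹, run length 60 000
steps (240 ps), 20 seeds per coupling, α grid {0, 10⁻³, 10⁻², 10⁻¹} with
ε = 20, escape defined as the 0-1-2-3 dihedral leaving the trans basin past
|φ| < 75°.  At these conditions the unbiased chain crosses the barrier in
well under half of the runs (median censored at the run length — the
published "τ = ∞, no transition" behaviour of the weakest coupling), while
the strongest coupling escapes in tens of picoseconds; the acceptance check
asserts a non-increasing median across the grid and ≥ 3× acceleration at
the largest α.  Numbers in this study are medians; censored entries count
the run length, which only understates the true acceleration.

## Path sampling

The comparator method biases the on-the-fly action variable
L = ∮p dq per atom and Cartesian axis, dL = (p+dp)·dq, with NR parallel
biases on time grids τ1_i = i·τ1 (adaptive-bias force) and τ2_i = i·τ2
(well-tempered Gaussian deposition along σ = L).  The adaptive force is the
coarse-grained derivative η′·Δ(rate)/τ1 with η′ a ±1 square wave per window
(zero mean by construction; a seeded random-sign variant exists) — the
η′-weighted term of the exact derivative is kept and the dη′/dτ term
dropped as ≈ 0, following the published approximation.  Deposits use
componentwise widths δσ = |σ(t_b) − σ(t_b′)| (fallback width before two
samples exist: max(0.1·max|σ|, 10⁻³)), the product-form kernel over
components (a summed form is optional), and damped heights
W·exp(−Φ/ΔE)·‖Δσ‖/max(‖σ‖, clamp); the clamp guards the division for σ
near zero, which the published height rule leaves unspecified.  The
combined bias force is renormalized against ∇H(A) exactly as in the hybrid
engine, so the α = 0 bitwise contract and the bias-magnitude bound carry
over unchanged.

## Analysis layer

Free-energy surfaces use ΔF = −kT·ln(p/p_max) (modal-reference convention:
the most probable bin is 0 and ΔF ≥ 0; reported in kT), over 1-D or 2-D
order parameters, and per (conformer class × sequence step) partitions.
RMSD uses least-squares superposition (optional `superpose=False` for the
raw Eckart-frame-free value); Rg is mass-weighted.  Conformer assignment is
a nearest-centroid surrogate in wrapped torsion space against a
*user-supplied* centroid table with per-class acceptance radii and a
non-assigned class ("NANT"); reproducing any external structural-alphabet
protocol is explicitly not claimed.  Transition kinetics uses first-passage
dwell accounting: τ_ik is the mean time in class i immediately before a
transition to k, ν_ik = 1/τ_ik, reported as ln ν; never-observed pairs are
absent (τ = ∞).  Escape times are first-passage times of a scalar series
past a target threshold, censored (∞) when no crossing occurs; the
acceleration factor is the ratio of median reference to median biased
escape time.

## Numerical choices

* Softmax evaluated after subtracting min w (exact by shift invariance).
* p-PMF tables: cubic-spline interpolation (periodic for torsions, natural
  for distances); outside a distance table's support the value is held flat
  with zero derivative — no extrapolated forces.  Tables are min-shifted to
  w = 0, which Ω ignores but makes tables comparable.
* Default bins: 0.02 nm radial, 5° angular.  Angular bins are right-closed
  on (−180°, 180]; −180° wraps into the first bin.
* Dihedral angles: atan2 formulation, range (−180°, 180°], matching the
  single-precision reference implementation in MDAnalysis to ~1e-5°.  The
  signed dihedral is invariant under reversal of the atom order and
  antisymmetric under mirror reflection.
* Degenerate geometry (coincident atoms, collinear dihedral frames) skips
  that coordinate's bias contribution with a log message rather than
  aborting the run; the toy repulsion caps its force below 0.6σ.
* Inner-loop kernels (toy forces, batched dihedrals) are numba-compiled
  with an arithmetically equivalent numpy fallback; the two paths agree to
  1e-12 and a test asserts it.

## Known limitations

* The quasi-homogeneity error is modeled as a single additive constant; the
  method cancels exactly that, and nothing beyond it (the secondary,
  conformation-dependent selection error discussed with the published
  method is out of scope of the toy studies).
* Acceptance is property-based at toy scale: the published
  explicit-solvent escape times and acceleration factors for dialanine,
  TrpCage, and B-DNA require AMBER-family MD, external PDB accessions and
  the external conformer-class definitions, and are not reproduced here.
* The per-position ("sequence-indexed") radial key mode mirrors the
  published matrices but is exercised only lightly; the transferable
  residue-type keying is the default.
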