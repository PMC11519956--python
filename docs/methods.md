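# Methods

## The model

Each lipid is three beads: one hydrophilic head (H) bonded to two
hydrophobic tails (T) by harmonic bonds (r0 = 1.0 nm) with a harmonic
T–H–T angle (θ0 = 30°).  Solvent is implicit: the hydrophobic effect is
carried entirely by an attractive tail–tail pair potential, while H–H
and H–T contacts are excluded-volume only.  In GROMACS units (nm, ps,
kJ/mol, amu; kB = 0.0083144621 kJ/mol/K):

    U_TT(r)    = (ε/5.5) [ 0.5 (r_min/r)^6 − 6 (r_min/r)^0.5 ]
    U_HH/HT(r) = (0.4 ε/5.5) · 0.5 (r_min/r)^6

The 1/5.5 normalization pins the TT well depth at exactly −ε at
r = r_min.  The six free parameters — ε, r_min, the shift onset r1, the
cutoff rc, k_bond, k_angle — are the genome the genetic algorithm
optimizes.  The released optimum is ε = 5.788 kBT (at 315 K),
r_min = 1.095 nm, r1 = 1.729 nm, rc = 2.5 nm, k_bond = 1997 kJ/mol/nm²,
k_angle = 264 kJ/mol/rad².

**Force shift.**  Each power-law term c/r^α (α = 6 repulsion, α = 0.5
attraction) is truncated with the GROMACS force-switch: between r1 and
rc the term's force αc/r^(α+1) gains a cubic correction
c·α[A(r−r1)² + B(r−r1)³] whose coefficients are chosen so the force and
its first derivative vanish at rc; the potential is the integral of the
shifted force, offset so V(rc) = 0.  Note the α prefactor on the
polynomial: `shift_coefficients` returns the bare (A, B) expressions,
and the assembled `PairTerm` scales them by α — without that factor the
force would not vanish at the cutoff.  The same treatment at α = 12/6
produces the mixed-resolution LJ tables.

**Masses and exclusions.**  Bead masses are not part of the published
model; we use 253.4 amu per bead (the POPC molar mass 760.1 split
equally), configurable through `LipidTopology`.  All intramolecular
pairs (1–2 and 1–3) are excluded from nonbonded terms: the two bonded
pairs sit at 1.0 nm, deep on the repulsive wall, and the two tails of a
gel-straight lipid approach each other closely; including those terms
would re-parametrize the bonded constants implicitly.

## Dynamics

Langevin dynamics with the symmetric BAOAB splitting (half kick, half
drift, exact Ornstein–Uhlenbeck velocity refresh, half drift, half
kick).  At γ = 0 it reduces to velocity Verlet, so microcanonical checks
exercise the production code path.  Default friction γ = 1 ps⁻¹ (the
1 ps thermostat relaxation of the stated protocol); both equilibration
and production use the Langevin thermostat (the original protocol
equilibrates with Nosé–Hoover, but the target properties are equilibrium
averages and insensitive to which canonical thermostat produced them).

**Timestep guidance.**  The stated production timestep is 0.15 ps.  With
k_bond = 1997 and 253.4 amu beads the bond period is 1.58 ps, i.e. ~10
steps per period: marginal.  Two measured consequences, both documented
rather than hidden: (i) in NVE (γ = 0) the system heats secularly at
~5×10⁻² of the kinetic energy per 10⁴ steps — microcanonical use
requires dt ≤ 0.03 ps (~50 steps/period), where the drift is < 10⁻³;
(ii) the BAOAB full-step kinetic temperature reads ~3% low at dt = 0.15
(0.5% at dt = 0.075).  The configurational O(dt²) bias
is not negligible either: at dt = 0.15 the tensionless area per lipid
reads 0.54–0.56 nm² depending on the seed (the effectively cooler
ensemble sits closer to the ordered phase), while at dt = 0.075 the
seeds agree at ~0.560 nm².  The desk-scale property protocols therefore
integrate at dt = 0.075; dt = 0.15 remains the default where speed
matters more than the last few percent of accuracy, and conservation/
equipartition tests run at the smaller steps noted above.

**Pressure coupling.**  Semi-isotropic Berendsen: Lx and Ly are scaled
jointly by μ = [1 − (κ·dt/τ_p)(P_ref − P_lat)]^(1/2) with
P_lat = (Pxx+Pyy)/2, κ = 10⁻⁵ bar⁻¹, τ_p = 1 ps, P_ref = 1 bar; Lz is
fixed (κ_z = 0).  The joint-area exponent 1/2 is first-order equivalent
to the usual 1/3-per-dimension form.  μ is clamped to ±2% per step as a
stability guard.  Berendsen rescaling damps box fluctuations without a
compensating stochastic term, so fluctuation-based observables (the
compressibility K_A in particular) converge slowly and are systematically
on the stiff side; this mirrors the published protocol rather than
improving on it.

**Neighbor search.**  Periodic k-d tree (scipy) with a 0.3 nm Verlet
skin, rebuilt when any bead's Euclidean displacement exceeds half the
skin.  Forces, energies, and the per-axis virial Σ r_ij,α F_ij,α are
accumulated in one numba kernel (a pure-numpy fallback is the reference
implementation; both are tested against a hand-written O(N²) loop).
The pressure tensor is P_αα = (2 KE_α + W_α)/V.  Boxes must satisfy
L > 2 rc for the minimum-image convention; with the 2.5 nm cutoff this
means ≥ ~40 lipids per leaflet at fluid densities, so the smallest test
patches use a reduced-cutoff parameter set instead.

## Estimators

* **Area per lipid**: ⟨Lx·Ly⟩ / N_leaflet from a tensionless-coupled run;
  block-averaged standard error (5 blocks, as for all estimators).
* **Area compressibility**: K_A = kB·T / (4 var(Lx)) in mN/m; block
  bootstrap for the uncertainty.
* **Line tension**: γL = −(Lx·Lz/2)(Pyy − (Pxx+Pzz)/2), converted with
  1 bar·nm² = 0.1 pN, on a fixed-box strip periodic in y with two free
  edges in x (vacuum margins 2 rc).  The ½ accounts for the two edges.
  The estimator refuses non-ribbon geometries.
* **Bending modulus**: every bead is mapped to its nearest node of an
  N×N grid (N = ⌊L/1 nm⌋, min 8; the parameter-free mapping variant);
  empty nodes (rare at this resolution) are filled by iterative periodic
  four-neighbor averaging, and >30% empty nodes is an error.  Per frame
  the grid is mean-subtracted and FFT'd with the u(r) = Σ u_q e^{iqr}
  convention (u_q = FFT/N²); |u_q|² is frame-averaged and then averaged
  over exact-|q| shells — binning different magnitudes together would
  bias the steep q⁻⁴ fit upward (a ~60% effect at the first shell).
  kc (in kBT) comes from the one-parameter least squares of
  S(q) = 1/(L² kc q⁴) over q ≤ min(0.8 nm⁻¹, 0.4 q_Nyquist), the
  continuum-regime window.
* **Transition temperature**: per-temperature enthalpy plateaus (mean of
  the series tail) from two-phase (gel|fluid) starts that suppress the
  nucleation barrier; the transition zone is the adjacent temperature
  pair with the largest plateau jump, significant when it exceeds 5× the
  pooled plateau standard error (our criterion; none is published), and
  the reported temperature is the zone midpoint.  "Enthalpy" for an
  implicit-solvent fixed-Lz system is reported as E_pot + E_kin +
  P_ref·V (set-point PV term; the instantaneous virial pressure is too
  noisy to integrate).
* **Lateral RDF**: g(r) = n(r, r+Δr)/(ρ·2πrΔr) with lateral minimum-image
  distances, Δr = 0.05 nm, tail beads by default; partner density uses
  (n−1)/A so an ideal gas is exactly 1.
* **Density profile**: mass-weighted z histogram relative to the
  instantaneous selection COM, Δz = 0.1 nm, head beads by default.
* **EMD**: 1-D Wasserstein-1 as the bin-width-weighted sum of |ΔCDF| on a
  shared grid; a resampling helper interpolates references onto the
  simulated grid.  Verified against a transport LP and scipy.

## The genetic algorithm

Cost = Σ₅ 0.15·(sim/target − 1)² + Σ₂ 0.125·EMD (weights sum to 1).
Point targets: APL 0.68 nm², K_A 230 mN/m, line tension 10 pN, bending
modulus 12 kBT, transition 270 K; acceptance bands 0.55–0.77, 180–330,
6.5–30, 8–42, 250–315.  Tiers the evaluator did not produce are skipped,
so partial tiers score on the same scale.

Design choices where the published description is ambiguous or silent:

* **Selection fitness**: fitness-proportionate selection applied to raw
  costs would favor *high* costs; we use F = 1/(cost + 10⁻⁶), which
  realizes the stated favor-the-low-cost intent, with cumulative-
  probability inversion.
* **Mutation trigger**: per-gene Bernoulli with probability pm (default
  0.1, the published 5–15% range).  The literal accept-if-N(0,1)<0.05
  rule would fire ~52% of the time, contradicting the stated 0.001–0.05
  probability range, so the conventional reading is used.
* **Adaptive σ**: per-gene standard deviation across the previous
  generation, floored at 1% of the gene's bound range so mutation never
  collapses entirely.
* **Bounds** (unpublished): ε 2–10 kBT, r_min 0.7–1.4, r1 1.2–2.2,
  rc 1.8–3.0 nm, k_bond 500–5000, k_angle 50–1000; a violated
  r_min < r1 < rc ordering is repaired by sorting the three values into
  the three slots.
* **Elitism** (e.g. e = 2) is available but off by default; the
  published loop has none.  Unfit genomes (failed or non-finite
  evaluations) are replaced by fresh uniform genomes.
* **Termination**: mean cost of the best decile below the threshold, or
  the iteration cap ("best genomes" is not quantified in the source
  protocol; the decile is our choice).
* **Protocol tiers**: "smoke" (36 lipids/leaflet, 800+1500 steps, APL
  only), "desk" (64/leaflet, 2000+8000 steps, adds K_A, line tension and
  the two distributions), "paper" (512/leaflet, 40k+400k steps, all
  seven properties — hours per genome, intended for real parametrization
  campaigns).  The tier is recorded in every report.

## Synthetic generators

The fixtures module generates exactly the statistical models the
estimators invert: Gaussian Fourier amplitudes with variance
1/(L² kc q⁴) (Hermitian-symmetrized, q = 0 removed) for the bending
pipeline; i.i.d. Gaussian box lengths for the fluctuation formula;
plateau-plus-jump enthalpy series; clipped-Gaussian tilt angles; and
smooth sum-of-Gaussians reference curves for the RDF and density
comparisons (synthetic stand-ins with fluid-bilayer features — a first
coordination peak near one bead diameter, a bimodal head density — since
no higher-resolution reference data ship with the package; the EMD
machinery is agnostic to the reference source).  Closure tests on these
fixtures validate estimator algebra and statistics.  They do not
validate physics: real membranes couple undulations to area
fluctuations, show protrusion modes at high q, and have correlated noise
in time, none of which the generators emulate.

## Problem sizes and observed behavior

The test suite and the acceptance script run desk-scale problems: 64
lipids per leaflet for tensionless runs (~45k steps), a 128-lipid ribbon
(~30k steps), 500-frame 64² synthetic surfaces, and a population-8
two-gene GA on the smoke tier.  At these sizes, with the released
parameter set, the tensionless area per lipid is ~0.56 nm² at dt = 0.075
(inside the accepted 0.55–0.77 band, below the 0.68 point target — the
unpublished simulation details this package had to choose, bead masses
and intramolecular exclusions above all, shift the equation of state at
the few-percent level), and the ribbon
line tension measures far above the 6.5–30 pN band (~10² pN): the edge
reconstructs (head beads enrich ~2× at the rim) but the pressure
anisotropy remains large at these sizes and times.  Both numbers are
reported as computed; neither estimator is adjusted toward its target.
K_A from Berendsen-coupled box fluctuations needs far longer series than
the desk protocol provides and its desk-scale value should be read as an
order of magnitude only.

## Known limitations

* Not a general MD engine: no constraints, no electrostatics, no
  explicit solvent, no parallel decomposition; single orthorhombic box.
* Berendsen coupling gives non-canonical box fluctuations (see above).
* The line tension and transition temperature of the actual model at
  publication scale require runs far beyond the bundled protocols.
* The mixed-resolution path generates tables, observables and run
  bundles but delegates actual peptide-membrane MD to an external
  engine; the internal test path stands a rigid bead rod in for the
  peptide.
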