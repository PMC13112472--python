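# Methods

This note documents the models, estimators, numerical choices, and the
synthetic validation systems implemented in `gaspore`, and what the
passing tests do and do not establish about real simulation data.

## Units, frame, and constants

Coordinates are Å, energies kcal/mol, times ns, temperatures K, charges in
elementary units.  The pore axis is +z; when structures are prepared for
profiling, z = 0 is placed at the host's center of mass.  R =
1.987204×10⁻³ kcal/(mol·K); the default temperature is 310 K, giving RT =
0.61603 kcal/mol; the Coulomb constant is 332.0636 kcal·Å/(mol·e²).

## Insertion free-energy maps (implicit ligand sampling)

A rigid probe is inserted over a regular grid covering the region of
interest.  Each 1 Å cell (default spacing) holds a 3×3×3 lattice of
insertion subsites; at each subsite the probe is placed in 10 orientations
(defaults mirror common practice for diatomic probes).  The map value is

ΔG(cell) = −RT ln [ mean over frames × subsites × orientations of e^(−E/RT) ],

the arithmetic mean of Boltzmann factors — the probability interpretation
of inserting into a vacuum reference p₀ = 1.  Design choices:

* **Energy model.** Lennard-Jones with CHARMM-type switching between 10 and
  12 Å, Coulomb shifted to zero at 12 Å, Lorentz–Berthelot combining, and
  minimum-image convention when a box is present.  Shifted-cutoff
  electrostatics (rather than Ewald) is adequate here because the intended
  probes are neutral with small partial charges; the module warns when a
  probe with sizable charges (|q| > 0.1 e, e.g. CO₂) is mapped, since
  orientation-implicit sampling is unreliable for polar ligands in any
  case.
* **Energy cap.** E is capped at 100 kcal/mol; the Boltzmann factor is
  floored correspondingly and cells where every trial pose hit the cap are
  flagged, never reported as −∞/+∞ surprises.
* **Orientations.** A deterministic Fibonacci sphere by default, so maps
  are bit-reproducible without a seed; uniform random orientations are
  available by passing a seed.  n = 1 means "+z" by convention.  For linear
  probes the roll angle about the orientation axis is immaterial; for
  general rigid probes it is fixed deterministically and documented in the
  code.
* **Segments.** Frames can be partitioned into contiguous segments
  (per-segment maps retained); segment mean and sample SD provide block
  error bars for maps and projected profiles.
* **1D projection.** Per z-layer, the Boltzmann-weighted mean of
  e^(−ΔG/RT) over (x, y) cells within a pore radius (default 5 Å) of the
  axis; a min-over-xy mode is available.  When profiles are referenced to
  bulk at the 1D level, the projection's lateral average cancels exactly
  against the reference for laterally separable fields — the package's
  cross-method comparison uses this route.
* **Bulk reference.** ΔG_sol = −RT ln ⟨e^(−ΔG/RT)⟩ over a stated bulk
  sub-box (or bulk z-segment of a 1D profile); subtracting it converts
  insertion free energies to bulk-referenced partitioning free energies.

The bundled probe models are an O₂ two-site rigid molecule (bond 1.21 Å,
partial charges ±0.02 e) and a linear CO₂ three-site model (C–O 1.16 Å,
+0.6 e on C, −0.3 e per O) with CHARMM-style LJ parameters.

## Occupancy (flooding) analysis

Probe positions are histogrammed along z inside a counting cylinder about
the pore axis (default radius 5 Å — the choice is echoed in every output
header because counts depend on it).  Densities are per Å³; the bulk
density comes from z-slabs on both sides of the pore, by default restricted
to the same cylinder cross-section so that for laterally confined systems
the ratio p_i/p_sol reduces to the axial Boltzmann weight.  Then
ΔG_sol(i) = −RT ln(p_i/p_sol).  Zero-count bins are reported as the bound a
half-count would imply and flagged — never interpolated, which would
fabricate barrier heights.  Per-bin errors are Poisson-propagated
(RT·√(1/n_i + 1/n_bulk)); these underestimate the true error for
autocorrelated samples, so barrier-level uncertainties in the cross-method
comparison come from contiguous block decomposition instead.

Diagnostics: `convergence_check` compares profiles at intermediate time
fractions with the full-trajectory profile (max-abs and RMS deviation,
barrier-location shift); `symmetry_check` histograms in-pore occupancy on a
square (x, y) grid and scores the worst 90° rotation mismatch, normalized
by mean occupancy (≈0 for a fourfold-symmetric channel, ≥1 for occupancy
piled into one quadrant).

Permeation events are counted by a per-ligand state machine over
{bulk_top, pore, bulk_bottom, elsewhere}.  A state change must persist
`debounce` consecutive frames to commit (default 1 = every visit counts; the
default is documented because crossing counts are sensitive to it).  An
entry is a committed transition into the pore from either bulk slab; a full
crossing requires entry from one slab and exit to the opposite one; pore
visits entered from "elsewhere" neither count as entries nor seed
crossings.  Entries are reported both as events and as unique entrant
molecules, since the two conventions differ whenever a molecule re-enters.

## Umbrella sampling and WHAM

Windows are planned as z₀ = z_min + i·spacing with both endpoints included
and non-integral spans rejected (no silent truncation); the harmonic force
constant defaults to 10 kcal/mol/Å² and window spacing to 0.5 Å.
`discard_equilibration` retains the trailing part of each series (default:
the last 2.5 of 3 ns, or any stated fraction).  WHAM uses half-open
0.25 Å bins with the bias evaluated at bin centers, F initialized to 0, and
a convergence tolerance of 10⁻⁷ kcal/mol on max|ΔF_j|.

Numerics: the entire solver works in log space, because biases evaluated
far from a window's samples reach hundreds of kcal/mol and their Boltzmann
factors under/overflow in linear space.  The self-consistent equations are
the stationarity conditions of a convex likelihood in F_j/RT; the solver
minimizes that likelihood directly (L-BFGS with analytic gradient, gauge
fixed by F₁ = 0) and then polishes with the plain fixed-point update until
the stated stopping rule holds — the same fixed point as naive iteration,
reached orders of magnitude faster.  Empty bins inside the sampled range
are flagged and excluded (G = +∞ there); adjacent windows sharing <5% of
their counts trigger an overlap warning; non-convergence raises with the
final residual.  `reference_to_bulk` shifts G so its Boltzmann average over
a stated bulk z-range is zero, and is idempotent and shift-invariant.

A known resolution limit, deliberately retained: where the underlying
potential varies by many RT within one histogram bin (the steep arms of the
synthetic double-well rise hundreds of kcal/mol), bin-center WHAM and any
bin-averaged reference diverge by construction.  Recovery claims are
therefore stated over the thermally relevant range (reference PMF within
10 kcal/mol of the wells — several times the barrier scale); inside that
range the recovery RMSD is ~0.1 kcal/mol at 91 × 5000 samples, as the
acceptance checks compute.

## Pore geometry, truncation, dihedrals

The pore radius at z is r(z) = max over the slice plane of
[min over atoms of (|p − aᵢ| − vdwᵢ)].  Per slice the maximization uses a
deterministic multi-start local search: a 5×5 coarse grid (±2 Å about the
axis) plus the previous slice's center, the three best starts refined by
Nelder–Mead — no annealing RNG, so profiles are exactly reproducible.  The
sphere center is the *local* maximum near the axis; far off-axis the
clearance grows again outside the channel wall, which is why both the
profiler and its dense-grid test oracle search near the axis.  The axis is
fixed parallel to +z (the channels of interest sit on a symmetry axis);
HOLE's adaptive axis walk is not implemented.  Defaults: 0.25 Å slice step,
10 Å radius cap (capped slices flagged), hydrogens excluded (switchable);
Bondi-style element radii (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å) are
bundled with per-run override.  Trajectory-averaged profiles report the
per-slice mean and sample SD over frames.

Alanine truncation removes side-chain atoms beyond Cβ, renames the residue
ALA, and leaves every retained atom's position and order untouched; glycine
(no Cβ) and proline (ring through the backbone) are rejected by name, and
alanine input passes through unchanged.  Enlarging substitutions would
require rotamer construction and are out of scope — the CLI refuses them.

χ1/χ2 use the standard atan2 dihedral construction, degrees in
(−180°, 180°], with γ/δ atom-name resolution across residue types (Trp χ2
is defined on Cδ1).  The implementation is verified against an independent
rotate-to-axis construction (1e−9°) and cross-checked against MDAnalysis
(which evaluates in single precision).

## Synthetic systems: what they emulate and what they do not

The generators stand in for the expensive molecular-dynamics inputs of a
real study:

* **Analytic potentials** U(x,y,z) = U_z(z) + ½k_r(x²+y²) on a box
  (Gaussian barrier, harmonic well, double-well h[((z−c)/a)²−1]²,
  composites) play the role of the protein environment along the pore.
  Separability is what makes the quadrature oracle exact and the lateral
  factors cancel in every referenced profile.
* **Flooding trajectories** are independent per-ligand Metropolis chains
  (Gaussian proposals auto-tuned toward ~40% acceptance during a 10%
  burn-in; acceptance outside [0.1, 0.9] after tuning is logged).  Only
  equilibrium occupancies matter to the estimators under test, so no
  integrator, timestep, or kinetics enter; probe–probe interactions are
  deliberately absent (real flooding at ~0.5 M concentration is not ideal).
  Consequently, passing tests validate estimator correctness on Boltzmann
  samples — not force fields, not sampling adequacy of real MD, and not
  kinetic observables.
* **Umbrella windows** are 1D Metropolis chains under U_z plus the window
  bias, initialized at their window centers (a steered-MD seeding protocol
  is out of scope) with sample times spanning a nominal 3 ns window.
* **Host ensembles** for insertion maps are i.i.d. Gaussian jitters of a
  static structure — conformational diversity without dynamics.
* **Channel fixtures** are rings of atoms (≥8 per ring, so the discrete
  ring approximates a circle) with known open radii, and pseudo-protein
  variants whose named residues (backbone + Cβ at large radius, bulky side
  chains projecting inward) give the truncation mechanism a geometric
  ground truth.
* **Scripted trajectories** move ligands through named region states so
  entry/crossing counts are known by construction, including boundary-
  rattling cases that exercise the debounce rule.
* **The quadrature oracle** integrates e^(−U_z/RT) by dense midpoint rule
  per bin and over the bulk ranges; it shares no code with any estimator.

All stochastic generators are reproducible under a fixed seed.  The
pipeline derives per-stage seeds from one global seed via SHA-256, so a
config rerun is byte-identical.

## Scale choices

Desk-scale defaults were chosen so the full validation battery (unit,
property, and acceptance layers) completes in well under a minute of
compute apiece: the cross-method comparison uses 10⁵ flooding samples (500
chains × 200 recorded sweeps, stride 10) and 73 windows × 2000 samples
(stride 4); the WHAM recovery benchmark uses the study-style ladder of 91
half-Å windows × 5000 samples; the consistency ladder uses 1.25×10⁴ →
2×10⁵ samples in 4× steps with 3 replicate seeds per rung.  Barrier
heights are estimated by a parabola fit over ±2 Å around the argmax bin —
the single noisiest-bin maximum is upward-biased, and using one common peak
estimator for every route (including the oracle) makes residual shape
mismatch common-mode.

## Known limitations

* Electrostatics are cutoff-shifted; no Ewald/PME.  Insertion maps for
  strongly polar probes are flagged, not refused.
* The pore axis must be pre-aligned with z; curved or tilted pores are not
  profiled correctly.
* Occupancy referencing assumes the bulk slabs are genuinely bulk-like
  (same lateral confinement as the pore region when the cylinder
  convention is used).
* WHAM error bars are optional block estimates; no MBAR, no 2D reaction
  coordinates.
* Truncation is the only supported mutagenesis; no rotamer building.
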