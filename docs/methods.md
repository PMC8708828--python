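# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic generator does and does not
emulate, and the known limitations.

## Units and conventions

Coordinates and distances in ångström, energies in kJ/mol, charges in
elementary charge units, times in picoseconds. Lennard-Jones parameters are
stored per atom as half-Rmin (`lj_rmin`, so the pair minimum is
`rmin_a + rmin_b`, the convention of CHARMM parameter files) and well depth
`lj_epsilon ≥ 0`, combined geometrically. The Coulomb constant is
k_e = 1389.35 kJ mol⁻¹ Å e⁻² with relative permittivity 1. The prime
carbon C15′ is encoded `C15P` because the prime character is not portable
in PDB atom-name columns. Residue numbering is preserved as read. DCD
headers store the frame spacing in ps directly in the `delta` field on
files this package writes; a uniform 1 ps spacing is the fallback.

## Membrane penetration (thickness, depth, RPD)

Phosphates are split by the sign of Z − ⟨Z⟩ into two leaflets; MP2 is the
leaflet whose mean Z is nearer the protein centre of geometry, since the
defining property of MP2 is "the side the protein inserted into" and the
centre of geometry is the simplest deterministic proxy. Frames are
canonicalised so the protein approaches from below (whole-frame Z mirror if
needed), which makes thickness positive by construction and all three
metrics mirror-invariant. Leaflet membership is recomputed every frame
(lipids could in principle flip; recomputation is the safer contract).
Hydrogens are excluded from the protein Z maximum (heavy-atom convention
adopted uniformly). Means are reported with sample SD (ddof = 1).

## RMSF and ΔRMSF

RMSF uses a two-pass iterative-mean reference: all frames are superposed
(Kabsch, proper rotation enforced via the SVD sign correction) onto frame 1,
averaged, then re-superposed onto that mean and re-averaged. The reference
is the mean structure rather than frame 1 because the RMSF definition is a
dispersion about the mean. Residue-level RMSF is the unweighted mean of the
residue's per-atom RMSF values (mass-weighting is a defensible alternative;
unweighted is simpler for bead fixtures and is the documented choice).
ΔRMSF is formed on the residue intersection only; residues present in one
profile are reported as missing, never as zero, so absence cannot be
mistaken for rigidity.

## Nonbonded interaction energy

U_ab is the exact cross-set double sum — for a nonbonded-only model the
intra-set terms of U − U_a − U_b cancel algebraically, and the suite
verifies the identity against a brute-force scripted partition at 1e-9
relative. An optional plain distance cutoff is provided for parity with
MD practice; it is simple truncation, documented as not equivalent to the
Ewald treatment a simulation engine would use, and the default evaluates
every pair. There is no element-specific code path: Fe²⁺ interacts through
the same Coulomb + 12-6 terms as every other atom (unbonded ion scheme).

## SASA

Shrake–Rupley with a deterministic golden-spiral point set (no RNG), 960
points by default for analytic accuracy, 240 where speed matters
(interface time series, per-atom ASA for the slab model). Validation:
isolated sphere to 0.5% of 4π(r+probe)², two-sphere overlap to 1% of the
spherical-cap closed form, cross-checked against an independent
Shrake–Rupley implementation on random clusters.

## Poisson–Boltzmann polar solvation

Linearized PB, ∇·(ε∇φ) − κ̄²φ = −4π k_e ρ, on a uniform grid:

* Dielectric map evaluated at **face midpoints** from the signed distance
  to the nearest atom surface, harmonically interpolated from ε_in to
  ε_out over a one-grid-cell ramp centred on the boundary. This placement
  was selected over node-based and sharp-face alternatives because it
  converges fastest on the Born ion (1.9% at 0.8 Å, 0.7% at 0.4 Å) and
  refines monotonically.
* Charges spread trilinearly; Dirichlet boundary values from the analytic
  screened-Coulomb sum of the charge set; red-black SOR (ω = 1.9,
  relative-update tolerance 1e-5, hard iteration cap with a clear error).
* ΔG_polar = ½Σqφ in the dielectric map minus the same quantity from a
  uniform-ε_in solve on the identical grid, which cancels the grid
  self-energy. When ε_in = ε_out and the ionic strength is zero the two
  linear systems are identical, so the difference is returned as exactly
  0 without solving.
* Defaults ε_in = 2.0, ε_out = 78.54, zero ionic strength, 0.8 Å spacing,
  ≥ 6 Å charge-to-boundary margin (enforced). Ionic strength enters as
  κ̄² = 8π(k_e/RT)·I with I in mol/L, applied in the solvent region only.
* Atom radii for the dielectric map (and SASA in MM/PBSA) are the stored
  half-Rmin values; a dedicated PB radius set can be supplied through PQR
  input instead.

## MM/PBSA

Single-trajectory protocol: complex, receptor and ligand geometries are
taken from the same frame. ΔMM_gas is the cross-set nonbonded energy
(identical to U_ab in this nonbonded model); ΔG_polar and ΔG_nonpolar are
complex − receptor − ligand differences, each entity solved on a grid of
the same extent (derived from the complex) for comparability.
ΔG_nonpolar = γ·SASA + b with γ = 0.0227 kJ mol⁻¹ Å⁻², b = 0 by default —
common MM/PBSA practice; both are configuration keys because no single
convention is universal. TΔS is reported as an explicit zero column rather
than omitted, making the entropy policy visible in every output. The
binding energies of chemically similar ligands are intended to be
*compared*; absolute values depend on the unreported dielectric/radius
conventions of any given study and are not a validation surface.

## Interface contacts

Contact area is the both-sides buried area SASA(P) + SASA(M) − SASA(P∪M);
the single-sided variant (half) is available by flag. The both-sides
convention is the default because its magnitude corresponds to the
2250–3250 Å² scale reported for a two-helix contact footprint. Hydrogen
bonds use heavy D–A distance ≤ 3.5 Å and D–H···A angle ≥ 150°; these are
conventions, fully configurable. Donor/acceptor perception for synthetic
systems comes from the fixture manifest, decoupling chemistry perception
from detection geometry; name-based rules (N/O donors with attached H, N/O
acceptors) serve for real files.

## Cleavage-site assignment

Each cleavable bond is scored by the mean of its two carbon–Fe distances
(C7=C8, C9=C10, C15=C15′); the minimum wins, and a best-to-second gap at
or below the tie tolerance (default 0.3 Å, within typical printed
precision) yields "ambiguous". Scoring the bond rather than single carbons
makes the call a property of the double bond being cleaved and reproduces
the implied site of every bundled reference row. Trajectory-level calls
use mean distances, not per-frame majority vote, matching how such tables
report one distance set per complex.

## Implicit-slab insertion

ΔG_transfer(pose) = Σ σ(residue)·ASA_atom·f(z): σ is a residue-level
transfer coefficient (kJ mol⁻¹ Å⁻², shipped scale derived from the
Kyte–Doolittle index scaled by −0.0125 so hydrophobic burial is
favourable; configurable), ASA is computed once on the isolated protein
(pose-independent approximation), and f(z) is 1 in the slab core, 0
outside, linear over the `interface_smoothing` ramp inside the slab edge.
The optimiser is an exhaustive, deterministic depth × tilt × azimuth grid
(default 0.2 Å depth step) rather than a stepped descent: trivially
testable against a scripted argmin and cheap at analysis scale. Ties keep
the first pose in scan order, i.e. the smallest azimuth among degenerate
mirror poses. The non-inserted pose (ΔG = 0) is always in the search, so
the reported optimum is ≤ 0 whenever any favourable pose exists. This is a
deliberately simplified positioning model, not a full implicit-solvation
treatment; published per-protein angles (28–39°), depths (5.2–7.0 Å) and
transfer energies (−48.5 to −64.4 kJ/mol) for the CCD4 study system are
qualitative reference magnitudes for it, not validation targets.

## Synthetic systems

The generator emulates only the features the analyses consume:

* a planar two-leaflet bilayer of one-phosphate-plus-two-tail-bead lipids
  on a jittered lattice, phosphate planes 39 Å apart by default (the
  pre-equilibrated POPC starting thickness) and 68 Å² per lipid headgroup;
* a bead-per-residue protein whose two helix spans (hydrophobic LEU beads)
  protrude from a polar globular shell and penetrate one leaflet in the
  combined fixture, with the highest protein heavy atom placed exactly at
  the requested depth above the MP2 plane;
* a carotenoid-like ligand whose labelled carbons sit at fixed recorded
  distances from an Fe²⁺ bead (defaults place C9/C10 nearest);
* frame sequences with prescribed per-residue isotropic Gaussian
  amplitudes (expected RMSF = σ√3) plus optional accumulated rigid drift.

Every generator is a pure function of its spec and seed, and a JSON
manifest records the ground truth (leaflet labels, true thickness and
depth, per-residue sigmas, carbon–Fe distances, donor/acceptor indices).
What the fixtures do **not** emulate: lipid chemistry and force-field
realism, solvent structure, correlated protein dynamics, finite-size and
electrostatic artefacts of real MD. Passing tests therefore demonstrate
algorithmic correctness of the analyses on systems with known answers, not
fidelity of any particular simulation.

## Problem sizes in the shipped checks

The bundled checks run at deliberately small scale: 16–128 lipids per
leaflet, a 40-residue bead protein, 2000-frame Gaussian fixtures for RMSF
recovery, Born-ion grids up to 41³ points (0.4 Å spacing) and a
12-bead amphipathic probe for the slab optimiser — sizes chosen so the
whole suite completes in well under a minute while keeping every
statistical bound meaningful (3·SE sampling bounds, 5% Monte-Carlo
tolerances at 2000 frames).

## Known limitations

* The PB solver is linear, single-grid SOR: adequate for the small
  per-frame systems of MM/PBSA post-processing, not a multigrid production
  solver for large biomolecules.
* The plain cutoff option for U_ab is truncation, not Ewald; with the
  default (no cutoff) the full double sum is exact for the model.
* Slab insertion ignores electrostatics and membrane curvature, and the
  per-atom ASA is frozen in the unbound pose.
* Six rows of the bundled interaction-energy reference table have
  components that sum 0.01 kJ/mol away from their stated totals
  (transcription-level rounding in the source data); the worked-example
  report flags them rather than hiding them.
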