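# memscan

Quantitative analysis of protein–membrane–carotenoid molecular-dynamics
trajectories, built around the system in which it matters most: plant
carotenoid cleavage dioxygenases (CCD4), non-heme Fe²⁺ enzymes that dock
onto the thylakoid membrane through two amphipathic α-helices, extract
carotenoids from the bilayer and cleave one double bond of the polyene
chain. `memscan` re-implements the complete post-processing pipeline such a
study needs — no simulation engine required — and ships a synthetic-system
generator with known ground truth so every stage is testable offline.

## What it computes

**Membrane penetration geometry.** The bilayer phosphates, projected on the
membrane normal Z, are split into two leaflet sets: MP2 on the side where
the protein inserts, MP1 opposite. Per frame

```
Thickness_t = ⟨Z_MP1⟩_t − ⟨Z_MP2⟩_t
Depth_t     = Max(Z_prot, heavy atoms)_t − ⟨Z_MP2⟩_t
RPD_t       = 100 · Depth_t / Thickness_t
```

**Fluctuation contrast.** Per-residue RMSF about the iteratively refined
mean structure after Kabsch superposition, and the membrane-vs-solvent
contrast ΔRMSF_i = ⟨RMSF_i⟩_memb − ⟨RMSF_i⟩_sol (negative = the membrane
rigidifies the region).

**Interaction-energy partition.** The ligand–receptor nonbonded energy
U_ab = U − U_a − U_b, evaluated as the cross-set sum of 12-6 Lennard-Jones
(CHARMM combining rules, half-Rmin storage) and Coulomb terms
(k_e = 1389.35 kJ mol⁻¹ Å e⁻²), split into ELECT and VDW components. The
Fe²⁺ centre participates through these same nonbonded terms only (unbonded
scheme).

**MM/PBSA binding free energy.**

```
ΔG_binding = ⟨ΔMM_gas + ΔG_polar + ΔG_nonpolar − TΔS⟩,   TΔS ≡ 0 by policy
```

with ΔG_polar from an in-repo finite-difference linearized
Poisson–Boltzmann solver (red-black SOR, analytic Dirichlet boundaries,
Born-ion validated) and ΔG_nonpolar = γ·SASA + b from a deterministic
Shrake–Rupley implementation.

**Interface contacts.** Buried contact surface area
SASA(P) + SASA(M) − SASA(P∪M), geometric hydrogen bonds (D–A ≤ 3.5 Å,
D–H···A ≥ 150°, configurable) and contacting-residue lists (< 4.5 Å).

**Active-site profiling.** Distances from the labelled carotenoid carbons
C7, C8, C9, C10, C15, C15′ (encoded `C15P`) to Fe²⁺; cleavage-site
assignment by the double bond whose carbons sit closest (C7=C8 / C9=C10
asymmetric, C15=C15′ symmetric); substrate ranking by binding score.

**Implicit-slab insertion.** Rigid-body minimisation of
ΔG_transfer = Σ σ(residue)·ASA_atom·f(z) over an exhaustive
depth × tilt × azimuth grid (default 0.2 Å depth steps) against a
hydrophobic slab, reporting the optimal depth, the angle of the first
principal inertia axis to the membrane plane and the contacting/outside
residue partition.

## Worked example

Analyse a synthetic membrane–protein–carotenoid system (39 Å initial
phosphate separation, protein inserted 10 Å past the MP2 leaflet plane,
0.5 Å lipid jitter, 20 frames of 0.25 Å per-residue Gaussian dynamics):

```python
from memscan import AnalysisConfig, run_analysis
from memscan.synthetic_systems import (FluctuationSpec,
                                       make_membrane_protein_fixture,
                                       make_trajectory)

system, manifest = make_membrane_protein_fixture(jitter_sigma=0.5, seed=1)
n_res = len(system.residue_index_map())
traj, _ = make_trajectory(system, FluctuationSpec(
    per_residue_sigma=[0.25] * n_res, n_frames=20, seed=1))
summary = run_analysis(AnalysisConfig(output_dir="demo_out"),
                       system=system, traj=traj)
```

which prints (via the summary dict):

```
thickness  39.12 +/- 0.05 A
depth      10.32 +/- 0.15 A
RPD        26.38 +/- 0.38 %
Uab total  -0.86 +/- 0.38 kJ/mol   (elect 0.06, vdw -0.92)
cleavage site: C9=C10 asymmetric
contact area 756.2 A^2
```

The thickness recovers the generator's 39 Å construction to within lipid
jitter; the depth and relative penetration track the 10 Å insertion; the
fixture ligand, whose C9/C10 carbons sit nearest the Fe²⁺ bead, is called
an asymmetric C9=C10 cleaver. The same stages are available from the shell
(`memscan synth`, `memscan membrane`, `memscan uab`, `memscan mmpbsa`,
`memscan interface`, `memscan site`, `memscan insert`, `memscan run`,
`memscan paper-check`); outputs are TSV time series plus one JSON summary.

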