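"""Synthetic bilayer / protein / ligand systems with known ground truth.

The generators build coarse-bead stand-ins for the study system: a planar
two-leaflet phospholipid bilayer whose phosphate planes start 39 angstrom
apart, a globular protein carrying two amphipathic helices that protrude into
one leaflet, and a linear carotenoid-like ligand whose labelled carbons
(C7, C8, C9, C10, C15, C15P) sit at fixed, recorded distances from an Fe2+
bead.  Every generator is a pure function of its spec (same seed, same
output) and returns ``(object, manifest)`` where the manifest is a plain
JSON-serialisable dict of ground-truth quantities (true thickness, leaflet
labels, true per-residue sigmas, true carbon-Fe distances, donor/acceptor
indices) for test assertions.

These are analysis fixtures, not force-field-quality models: one bead per
residue / lipid head, fixture charges and LJ parameters, no lipid chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core_model import AtomRecord, MolecularSystem, Trajectory, combine_systems

__all__ = [
    "BilayerSpec",
    "FluctuationSpec",
    "RigidDrift",
    "make_bilayer",
    "make_protein_and_ligand",
    "make_trajectory",
    "make_membrane_protein_fixture",
    "default_param_table",
]

# Fixture nonbonded parameters: (charge e, half-Rmin A, epsilon kJ/mol)
_FIXTURE_PARAMS: Dict[Tuple[str, str], Tuple[float, float, float]] = {
    ("LIP", "P"): (-0.80, 2.15, 0.50),
    ("LIP", "C1"): (0.40, 2.00, 0.40),
    ("LIP", "C2"): (0.40, 2.00, 0.40),
    ("SER", "CA"): (-0.10, 2.00, 0.30),
    ("SER", "HD"): (0.10, 0.80, 0.10),
    ("LEU", "CA"): (0.00, 2.10, 0.45),
    ("LIG", "C7"): (-0.05, 1.99, 0.35),
    ("LIG", "C8"): (0.05, 1.99, 0.35),
    ("LIG", "C9"): (-0.05, 1.99, 0.35),
    ("LIG", "C10"): (0.05, 1.99, 0.35),
    ("LIG", "C15"): (-0.05, 1.99, 0.35),
    ("LIG", "C15P"): (0.05, 1.99, 0.35),
    ("FE2", "FE"): (2.00, 1.10, 0.04),
}

# Carbon-Fe offsets of the fixture ligand (angstrom).  Distances mimic a
# carotenoid resting with its C9=C10 bond closest to the catalytic iron.
_LIGAND_FE_DISTANCES: Dict[str, float] = {
    "C7": 8.2, "C8": 7.1, "C9": 6.3, "C10": 6.0, "C15": 8.0, "C15P": 9.2,
}


def default_param_table() -> Dict[Tuple[str, str], Tuple[float, float, float]]:
    """The fixture nonbonded parameter table (copy)."""
    return dict(_FIXTURE_PARAMS)


@dataclass
class BilayerSpec:
    """Geometry of the synthetic bilayer patch.

    ``phosphate_separation`` is the initial phosphate-plane distance
    (39 angstrom, the pre-equilibrated POPC starting thickness).  ``area``
    defaults to 68 A^2 per lipid, a typical fluid-phase POPC headgroup area;
    the full-scale patch (102 x 140 A) is scaled down via lipid count.
    """

    n_lipids_per_leaflet: int = 64
    phosphate_separation: float = 39.0
    area: Optional[float] = None
    jitter_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phosphate_separation <= 0:
            raise ValueError("phosphate_separation must be > 0")
        if self.n_lipids_per_leaflet < 4:
            raise ValueError("need at least 4 lipids per leaflet")


@dataclass
class FluctuationSpec:
    """Per-residue isotropic Gaussian displacement amplitudes for frames."""

    per_residue_sigma: Sequence[float]
    n_frames: int = 100
    dt_ps: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.per_residue_sigma):
            raise ValueError("sigmas must be >= 0")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


@dataclass
class RigidDrift:
    """Rigid motion accumulated per frame: frame i gets i x translation and
    i x rotation (degrees, about ``axis`` through ``center``)."""

    translation: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: float = 0.0
    axis: str = "z"
    center: Optional[Tuple[float, float, float]] = None


def make_bilayer(spec: BilayerSpec) -> Tuple[MolecularSystem, dict]:
    """Build a two-leaflet coarse bilayer centred on the Z=0 midplane.

    Each lipid is a phosphate bead "P" on its leaflet plane plus two tail
    beads toward the midplane.  Phosphate planes sit at +/- separation/2
    before jitter.  Groups: "membrane", "phosphates".
    """
    n = spec.n_lipids_per_leaflet
    area = spec.area if spec.area is not None else 68.0 * n
    nx = int(np.ceil(np.sqrt(n)))
    spacing = np.sqrt(area) / nx
    if spacing < 5.0:
        raise ValueError(
            f"area {area:.0f} A^2 too small for {n} lipids/leaflet "
            f"(lattice spacing {spacing:.2f} < 5 A)")
    rng = np.random.default_rng(spec.seed)
    half = spec.phosphate_separation / 2.0
    records: List[AtomRecord] = []
    phosphate_idx: List[int] = []
    leaflet_labels: List[str] = []  # per phosphate, "upper"/"lower"
    serial = 1
    resid = 1
    for leaflet_sign, label in ((+1.0, "upper"), (-1.0, "lower")):
        placed = 0
        for iy in range(nx):
            for ix in range(nx):
                if placed >= n:
                    break
                x = (ix - (nx - 1) / 2.0) * spacing
                y = (iy - (nx - 1) / 2.0) * spacing
                zp = leaflet_sign * half
                beads = [("P", np.array([x, y, zp])),
                         ("C1", np.array([x, y, zp - leaflet_sign * 4.0])),
                         ("C2", np.array([x, y, zp - leaflet_sign * 8.0]))]
                for name, pos in beads:
                    if spec.jitter_sigma > 0:
                        pos = pos + rng.normal(0.0, spec.jitter_sigma, 3)
                    q, rmin, eps = _FIXTURE_PARAMS[("LIP", name)]
                    records.append(AtomRecord(
                        serial=serial, name=name, residue_name="LIP",
                        residue_id=resid, chain="M",
                        element="P" if name == "P" else "C",
                        coords=pos, charge=q, lj_rmin=rmin, lj_epsilon=eps))
                    if name == "P":
                        phosphate_idx.append(serial - 1)
                        leaflet_labels.append(label)
                    serial += 1
                resid += 1
                placed += 1
    system = MolecularSystem(records, groups={
        "membrane": list(range(len(records))),
        "phosphates": phosphate_idx,
    })
    manifest = {
        "kind": "bilayer",
        "n_lipids_per_leaflet": n,
        "phosphate_separation": spec.phosphate_separation,
        "jitter_sigma": spec.jitter_sigma,
        "seed": spec.seed,
        "phosphate_indices": [int(i) for i in phosphate_idx],
        "phosphate_leaflets": leaflet_labels,
        "n_atoms": len(records),
    }
    return system, manifest


def make_protein_and_ligand(
    n_residues: int = 40,
    helix_spans: Sequence[Tuple[int, int]] = ((21, 30), (31, 40)),
    ligand: str = "carotenoid-like",
    seed: int = 0,
    n_donors: int = 3,
    ligand_fe_distances: Optional[Dict[str, float]] = None,
) -> Tuple[MolecularSystem, dict]:
    """Build a bead protein with two membrane-facing helices plus the ligand.

    The globular body is a bead-per-residue spherical shell around the local
    origin; residues inside ``helix_spans`` form two straight helix-like rods
    protruding toward -Z (lower Z than the globular mean by construction).
    Helix residues are named LEU (hydrophobic), body residues SER (polar);
    the first ``n_donors`` body residues carry an extra HD hydrogen bead so
    that hydrogen-bond donors exist with recorded indices.

    The ligand is a linear run of beads C7, C8, C9, C10, C15, C15P whose
    Euclidean distances from the single FE bead equal
    ``ligand_fe_distances`` (defaults recorded in the manifest).
    Groups: "protein", "ligand", "fe".
    """
    if ligand != "carotenoid-like":
        raise ValueError(f"unknown ligand kind {ligand!r}")
    spans = [tuple(s) for s in helix_spans]
    for lo, hi in spans:
        if lo < 1 or hi > n_residues or lo > hi:
            raise ValueError(f"helix span {(lo, hi)} outside [1, {n_residues}]")
    for a in range(len(spans)):
        for b in range(a + 1, len(spans)):
            if spans[a][0] <= spans[b][1] and spans[b][0] <= spans[a][1]:
                raise ValueError(f"overlapping helix spans {spans[a]} {spans[b]}")
    helix_res = {r for lo, hi in spans for r in range(lo, hi + 1)}
    body_res = [r for r in range(1, n_residues + 1) if r not in helix_res]

    rng = np.random.default_rng(seed)
    records: List[AtomRecord] = []
    protein_idx: List[int] = []
    donor_pairs: List[Tuple[int, int]] = []
    serial = 1

    def add(name, resname, resid, element, pos, chain="P"):
        nonlocal serial
        q, rmin, eps = _FIXTURE_PARAMS[(resname, name)]
        records.append(AtomRecord(
            serial=serial, name=name, residue_name=resname, residue_id=resid,
            chain=chain, element=element, coords=np.asarray(pos, float),
            charge=q, lj_rmin=rmin, lj_epsilon=eps))
        serial += 1
        return serial - 2  # zero-based index of the added atom

    # Globular body: Fibonacci shell, radius scaled to residue count.
    radius = max(6.0, 2.2 * len(body_res) ** (1 / 3) * 2.0)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for k, resid in enumerate(body_res):
        t = (k + 0.5) / len(body_res)
        z = 1.0 - 2.0 * t
        r_xy = np.sqrt(max(0.0, 1.0 - z * z))
        theta = golden * k
        pos = radius * np.array([r_xy * np.cos(theta), r_xy * np.sin(theta), z])
        i = add("CA", "SER", resid, "C", pos)
        protein_idx.append(i)
        if len(donor_pairs) < n_donors:
            h = add("HD", "SER", resid, "H", pos + np.array([1.0, 0.0, 0.0]))
            protein_idx.append(h)
            donor_pairs.append((i, h))

    # Helix rods: straight runs descending below the body (-Z), 1.5 A rise
    # per residue, the two rods offset +/- 3.5 A in X.
    for s, (lo, hi) in enumerate(spans):
        x0 = (-3.5 if s % 2 == 0 else 3.5)
        for k, resid in enumerate(range(lo, hi + 1)):
            pos = np.array([x0, 1.5 * (s - 0.5), -radius - 1.5 * (k + 1)])
            i = add("CA", "LEU", resid, "C", pos)
            protein_idx.append(i)

    # Ligand + Fe: Fe sits near the body centre; labelled carbons placed on a
    # line through Fe with exact recorded distances.
    fe_pos = np.array([0.0, 0.0, 2.0])
    fe_i = add("FE", "FE2", n_residues + 1, "Fe", fe_pos, chain="L")
    distances = dict(ligand_fe_distances or _LIGAND_FE_DISTANCES)
    ligand_idx: List[int] = []
    direction = np.array([1.0, 0.0, 0.0])
    for name in ("C7", "C8", "C9", "C10", "C15", "C15P"):
        pos = fe_pos + distances[name] * direction
        i = add(name, "LIG", n_residues + 2, "C", pos, chain="L")
        ligand_idx.append(i)

    system = MolecularSystem(records, groups={
        "protein": protein_idx,
        "ligand": ligand_idx,
        "fe": [fe_i],
    })
    body_mean_z = float(np.mean(
        [records[i].coords[2] for i in protein_idx
         if records[i].residue_name == "SER"]))
    manifest = {
        "kind": "protein_ligand",
        "n_residues": n_residues,
        "helix_spans": [list(s) for s in spans],
        "helix_residues": sorted(helix_res),
        "seed": seed,
        "donor_pairs": [[int(d), int(h)] for d, h in donor_pairs],
        "ligand_fe_distances": {k: float(v) for k, v in distances.items()},
        "fe_index": int(fe_i),
        "ligand_indices": [int(i) for i in ligand_idx],
        "body_mean_z": body_mean_z,
        "n_atoms": len(records),
    }
    return system, manifest


def _rotation_matrix(axis: str, angle_deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(angle_deg)), np.sin(np.deg2rad(angle_deg))
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])
    if axis == "x":
        return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])
    raise ValueError(f"unknown axis {axis!r}")


def make_trajectory(system: MolecularSystem, fluct: FluctuationSpec,
                    drift: Optional[RigidDrift] = None) -> Tuple[Trajectory, dict]:
    """Frames = base coords + per-residue isotropic Gaussian noise + drift.

    ``per_residue_sigma`` must list one sigma per distinct residue, in order
    of first appearance; all atoms of a residue share its sigma each frame.
    Drift applies i-times the per-frame rigid motion to frame i.
    """
    resmap = system.residue_index_map()
    resids = list(resmap)
    if len(fluct.per_residue_sigma) != len(resids):
        raise ValueError(
            f"need {len(resids)} sigmas (one per residue), "
            f"got {len(fluct.per_residue_sigma)}")
    sigma_atom = np.zeros(system.n_atoms)
    for s, rid in zip(fluct.per_residue_sigma, resids):
        sigma_atom[resmap[rid]] = s
    rng = np.random.default_rng(fluct.seed)
    base = system.coords
    frames = np.empty((fluct.n_frames, system.n_atoms, 3))
    for i in range(fluct.n_frames):
        coords = base + rng.normal(0.0, 1.0, base.shape) * sigma_atom[:, None]
        if drift is not None:
            if drift.rotation_deg != 0.0:
                center = (np.asarray(drift.center, float) if drift.center
                          is not None else base.mean(axis=0))
                rot = _rotation_matrix(drift.axis, drift.rotation_deg * i)
                coords = (coords - center) @ rot.T + center
            coords = coords + np.asarray(drift.translation, float) * i
        frames[i] = coords
    times = np.arange(fluct.n_frames, dtype=float) * fluct.dt_ps
    traj = Trajectory(system=system, frames=frames, times=times)
    manifest = {
        "kind": "trajectory",
        "n_frames": fluct.n_frames,
        "dt_ps": fluct.dt_ps,
        "seed": fluct.seed,
        "residue_ids": [int(r) for r in resids],
        "per_residue_sigma": [float(s) for s in fluct.per_residue_sigma],
        "drift": None if drift is None else {
            "translation": list(drift.translation),
            "rotation_deg": drift.rotation_deg, "axis": drift.axis},
        "expected_rmsf": [float(s * np.sqrt(3.0))
                          for s in fluct.per_residue_sigma],
    }
    return traj, manifest


def make_membrane_protein_fixture(
    phosphate_separation: float = 39.0,
    protein_max_z_above_mp2: float = 10.0,
    n_lipids_per_leaflet: int = 36,
    jitter_sigma: float = 0.0,
    seed: int = 0,
) -> Tuple[MolecularSystem, dict]:
    """Combined bilayer + inserted protein/ligand system with exact geometry.

    The protein is translated so that its highest heavy atom sits exactly
    ``protein_max_z_above_mp2`` above the lower (protein-side, MP2) phosphate
    plane; the expected thickness, depth and relative penetration depth are
    recorded in the manifest.
    """
    bilayer, bman = make_bilayer(BilayerSpec(
        n_lipids_per_leaflet=n_lipids_per_leaflet,
        phosphate_separation=phosphate_separation,
        jitter_sigma=jitter_sigma, seed=seed))
    protein, pman = make_protein_and_ligand(seed=seed)
    # The standalone protein has its helices on -Z; the membrane sits above
    # the protein here, so mirror the protein to point the helices at the
    # leaflet it penetrates, then shift so that the highest protein heavy
    # atom sits exactly at mp2_plane + target depth.
    protein.coords[:, 2] *= -1.0
    mp2_plane = -phosphate_separation / 2.0
    prot_idx = protein.groups["protein"]
    heavy = protein.heavy_mask()
    prot_heavy = [i for i in prot_idx if heavy[i]]
    max_z = protein.coords[prot_heavy, 2].max()
    shift = (mp2_plane + protein_max_z_above_mp2) - max_z
    protein.coords[:, 2] += shift
    combined = combine_systems(bilayer, protein)
    manifest = {
        "kind": "membrane_protein",
        "bilayer": bman,
        "protein": pman,
        "protein_z_shift": float(shift),
        "true_thickness": phosphate_separation,
        "true_depth": protein_max_z_above_mp2,
        "true_rpd": 100.0 * protein_max_z_above_mp2 / phosphate_separation,
    }
    return combined, manifest
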