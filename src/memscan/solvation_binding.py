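"""Solvent-accessible surface area, Poisson-Boltzmann polar solvation and
MM/PBSA binding free energies.

SASA uses the Shrake-Rupley rolling-probe construction with a deterministic
golden-spiral point set (no RNG): each atom's sphere of radius r_i + probe is
sampled at ``n_points``; points buried inside any neighbour's expanded sphere
are removed and the accessible fraction is converted to area.

The polar solvation term solves the linearized Poisson-Boltzmann equation

    div( eps(x) grad phi ) - kbar^2(x) phi = -4 pi k_e rho

on a uniform grid by red-black successive over-relaxation, with the solute
interior at ``eps_in``, the exterior at ``eps_out`` (linear smoothing of the
dielectric over one grid cell at the molecular boundary), charges spread to
the grid trilinearly, and analytic Debye-Hueckel/Coulomb Dirichlet boundary
values.  The reaction-field energy

    dG_polar = E[eps map] - E[uniform eps_in],   E = 1/2 sum_i q_i phi(x_i)

subtracts the grid self-energy through the uniform-dielectric reference
solve on the identical grid.  When ``eps_in == eps_out`` and the ionic
strength is zero the two linear systems are identical, so the difference is
exactly zero and is returned without solving.

MM/PBSA (single-trajectory protocol) combines, per frame,

    dG_binding = dMM_gas + dG_polar + dG_nonpolar - T dS

with dMM_gas the cross-set nonbonded energy (complex minus parts),
dG_nonpolar = gamma * SASA + beta per species, and T dS = 0 by policy
(reported explicitly as zero, never dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core_model import MolecularSystem, Trajectory
from .nonbonded_energetics import COULOMB_CONSTANT, interaction_energy

__all__ = [
    "SasaResult",
    "PbGrid",
    "MmpbsaConfig",
    "BindingReport",
    "sphere_points",
    "sasa",
    "pb_solve",
    "solvation_terms",
    "mmpbsa_binding",
]

# RT at 298.15 K, kJ/mol (for the Debye screening length).
_RT = 2.4789
# mol/L -> particles per cubic angstrom
_MOLAR_TO_PER_A3 = 6.02214076e-4


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere point set (n >= 1)."""
    k = np.arange(n) + 0.5
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = np.pi * (3.0 - np.sqrt(5.0)) * np.arange(n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SasaResult:
    total: float
    per_atom: np.ndarray
    probe_radius: float


def sasa(frame: np.ndarray, radii: np.ndarray, probe: float = 1.4,
         n_points: int = 960) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area (angstrom^2)."""
    frame = np.asarray(frame, float)
    radii = np.asarray(radii, float)
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        raise ValueError("all atoms need positive radii for SASA")
    if n_points < 92:
        raise ValueError("n_points must be >= 92")
    n = len(frame)
    expanded = radii + probe
    pts = sphere_points(n_points)
    tree = cKDTree(frame)
    rmax = expanded.max()
    per_atom = np.zeros(n)
    for i in range(n):
        neigh = [j for j in tree.query_ball_point(frame[i],
                                                  expanded[i] + rmax)
                 if j != i]
        surface = frame[i] + expanded[i] * pts
        if neigh:
            neigh = np.asarray(neigh, int)
            # drop neighbours that cannot touch this atom's expanded sphere
            d = np.linalg.norm(frame[neigh] - frame[i], axis=1)
            neigh = neigh[d < expanded[i] + expanded[neigh]]
        if len(neigh):
            d2 = np.sum((surface[:, None, :] - frame[neigh][None, :, :]) ** 2,
                        axis=2)
            buried = np.any(d2 < (expanded[neigh] ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    return SasaResult(total=float(per_atom.sum()), per_atom=per_atom,
                      probe_radius=probe)


# ---------------------------------------------------------------------------
# Finite-difference linearized Poisson-Boltzmann
# ---------------------------------------------------------------------------

@dataclass
class PbGrid:
    """Grid and dielectric settings for the PB solve.

    ``extent`` (angstrom, per axis) is derived from the charge cloud plus
    ``margin`` when not given.  ``eps_in``/``eps_out`` follow the common
    molecular/aqueous convention (2 / 78.54); ionic strength in mol/L enters
    through the Debye screening term (default 0).
    """

    spacing: float = 0.8
    extent: Optional[Tuple[float, float, float]] = None
    margin: float = 8.0
    eps_in: float = 2.0
    eps_out: float = 78.54
    ionic_strength: float = 0.0
    tol: float = 1e-5
    max_iter: int = 20000
    omega: float = 1.9

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if not (self.eps_out >= self.eps_in >= 1.0):
            raise ValueError("need eps_out >= eps_in >= 1")
        if self.margin < 6.0:
            raise ValueError("grid margin must be >= 6 angstrom")


def _grid_axes(coords: np.ndarray, radii: np.ndarray,
               grid: PbGrid) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = 0.5 * (coords.min(axis=0) + coords.max(axis=0))
    if grid.extent is not None:
        half = 0.5 * np.asarray(grid.extent, float)
    else:
        half = (coords.max(axis=0) - coords.min(axis=0)) / 2.0 \
            + radii.max() + grid.margin
    lo = center - half
    n = np.ceil(2.0 * half / grid.spacing).astype(int) + 1
    axes = [lo[d] + np.arange(n[d]) * grid.spacing for d in range(3)]
    for d in range(3):
        if coords[:, d].min() - lo[d] < 6.0 - 1e-9 or \
                lo[d] + (n[d] - 1) * grid.spacing - coords[:, d].max() < 6.0 - 1e-9:
            raise ValueError("charged atoms need >= 6 angstrom grid margin")
    return axes[0], axes[1], axes[2]


def _spread_charges(coords, charges, xs, ys, zs, h) -> np.ndarray:
    rho = np.zeros((len(xs), len(ys), len(zs)))
    fx = (coords[:, 0] - xs[0]) / h
    fy = (coords[:, 1] - ys[0]) / h
    fz = (coords[:, 2] - zs[0]) / h
    i0 = np.floor(fx).astype(int)
    j0 = np.floor(fy).astype(int)
    k0 = np.floor(fz).astype(int)
    tx, ty, tz = fx - i0, fy - j0, fz - k0
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                w = (np.where(di, tx, 1 - tx) * np.where(dj, ty, 1 - ty)
                     * np.where(dk, tz, 1 - tz))
                np.add.at(rho, (i0 + di, j0 + dj, k0 + dk), charges * w)
    return rho


def _trilinear(phi, coords, xs, ys, zs, h) -> np.ndarray:
    fx = (coords[:, 0] - xs[0]) / h
    fy = (coords[:, 1] - ys[0]) / h
    fz = (coords[:, 2] - zs[0]) / h
    i0 = np.floor(fx).astype(int)
    j0 = np.floor(fy).astype(int)
    k0 = np.floor(fz).astype(int)
    tx, ty, tz = fx - i0, fy - j0, fz - k0
    out = np.zeros(len(coords))
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                w = (np.where(di, tx, 1 - tx) * np.where(dj, ty, 1 - ty)
                     * np.where(dk, tz, 1 - tz))
                out += w * phi[i0 + di, j0 + dj, k0 + dk]
    return out


def _boundary_potential(coords, charges, xs, ys, zs, eps, kappa) -> np.ndarray:
    """Dirichlet boundary values: screened-Coulomb sum on the grid faces."""
    phi = np.zeros((len(xs), len(ys), len(zs)))
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    mask = np.zeros(phi.shape, dtype=bool)
    mask[0], mask[-1] = True, True
    mask[:, 0], mask[:, -1] = True, True
    mask[:, :, 0], mask[:, :, -1] = True, True
    pts = np.column_stack([gx[mask], gy[mask], gz[mask]])
    vals = np.zeros(len(pts))
    for q, c in zip(charges, coords):
        d = np.linalg.norm(pts - c, axis=1)
        vals += COULOMB_CONSTANT * q * np.exp(-kappa * d) / (eps * d)
    phi[mask] = vals
    return phi


def _solve_grid(eps_x, eps_y, eps_z, source, kbar2_h2, phi, tol, max_iter,
                omega) -> Tuple[np.ndarray, int, float]:
    """Red-black SOR on the 7-point variable-coefficient stencil."""
    nx, ny, nz = phi.shape
    den = (eps_x[:-1, 1:-1, 1:-1] + eps_x[1:, 1:-1, 1:-1]
           + eps_y[1:-1, :-1, 1:-1] + eps_y[1:-1, 1:, 1:-1]
           + eps_z[1:-1, 1:-1, :-1] + eps_z[1:-1, 1:-1, 1:]
           + kbar2_h2[1:-1, 1:-1, 1:-1])
    ii, jj, kk = np.meshgrid(np.arange(1, nx - 1), np.arange(1, ny - 1),
                             np.arange(1, nz - 1), indexing="ij")
    parity = (ii + jj + kk) % 2
    masks = [parity == 0, parity == 1]
    src = source[1:-1, 1:-1, 1:-1]
    scale = max(np.abs(phi).max(), 1.0)
    for it in range(max_iter):
        max_delta = 0.0
        for m in masks:
            num = (eps_x[:-1, 1:-1, 1:-1] * phi[:-2, 1:-1, 1:-1]
                   + eps_x[1:, 1:-1, 1:-1] * phi[2:, 1:-1, 1:-1]
                   + eps_y[1:-1, :-1, 1:-1] * phi[1:-1, :-2, 1:-1]
                   + eps_y[1:-1, 1:, 1:-1] * phi[1:-1, 2:, 1:-1]
                   + eps_z[1:-1, 1:-1, :-1] * phi[1:-1, 1:-1, :-2]
                   + eps_z[1:-1, 1:-1, 1:] * phi[1:-1, 1:-1, 2:]
                   + src)
            new = num / den
            interior = phi[1:-1, 1:-1, 1:-1]
            delta = np.where(m, new - interior, 0.0)
            interior += omega * delta
            max_delta = max(max_delta, float(np.abs(delta).max()))
        scale = max(np.abs(phi).max(), 1.0)
        if max_delta < tol * scale:
            return phi, it + 1, max_delta
    raise RuntimeError(
        f"PB solver did not converge in {max_iter} iterations "
        f"(last relative update {max_delta / scale:.3e})")


def pb_solve(frame: np.ndarray, charges: np.ndarray, radii: np.ndarray,
             grid: Optional[PbGrid] = None) -> float:
    """Polar (reaction-field) solvation free energy, kJ/mol.

    Two linear solves on the same grid -- the dielectric-map system and a
    uniform ``eps_in`` reference -- whose charge-potential energies are
    subtracted, removing the grid self-energy.
    """
    grid = grid or PbGrid()
    frame = np.asarray(frame, float)
    charges = np.asarray(charges, float)
    radii = np.asarray(radii, float)
    if np.any(~np.isfinite(charges)):
        raise ValueError("all atoms need finite charges for the PB solve")
    if not np.any(charges != 0.0):
        return 0.0
    if grid.eps_in == grid.eps_out and grid.ionic_strength == 0.0:
        return 0.0  # identical systems; difference is exactly zero
    h = grid.spacing
    xs, ys, zs = _grid_axes(frame, radii, grid)
    shape = (len(xs), len(ys), len(zs))

    # Dielectric map evaluated at face midpoints: signed distance to the
    # solute surface, harmonically interpolated eps over a one-cell ramp
    # centred on the boundary (second-order accurate boundary placement).
    tree = cKDTree(frame)

    def _signed_distance(pts: np.ndarray) -> np.ndarray:
        d, i = tree.query(pts, k=min(len(frame), 8))
        d = np.atleast_2d(d.T).T
        i = np.atleast_2d(i.T).T
        return (d - radii[i]).min(axis=1)

    def _face_eps(axis: int) -> np.ndarray:
        ax = [xs, ys, zs]
        mids = [a.copy() for a in ax]
        mids[axis] = 0.5 * (mids[axis][:-1] + mids[axis][1:])
        gx, gy, gz = np.meshgrid(*mids, indexing="ij")
        s = _signed_distance(
            np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]))
        t_face = np.clip(s / h + 0.5, 0.0, 1.0).reshape(gx.shape)
        return 1.0 / ((1.0 - t_face) / grid.eps_in + t_face / grid.eps_out)

    kappa2 = 0.0
    if grid.ionic_strength > 0.0:
        # kbar^2 = 8 pi (k_e / RT) I, I in mol/L converted to A^-3;
        # applied only in the solvent region (scaled by solvent fraction).
        kappa2 = (8.0 * np.pi * COULOMB_CONSTANT / _RT
                  * grid.ionic_strength * _MOLAR_TO_PER_A3)
    kappa = np.sqrt(kappa2 / grid.eps_out) if kappa2 > 0 else 0.0

    rho = _spread_charges(frame, charges, xs, ys, zs, h)
    # stencil source: 4 pi k_e q_node / h (equation pre-multiplied by h^2)
    source = 4.0 * np.pi * COULOMB_CONSTANT * rho / h

    # Solvent-dielectric solve
    ex, ey, ez = _face_eps(0), _face_eps(1), _face_eps(2)
    kbar2_h2 = np.zeros(shape)
    if kappa2 > 0:
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        s_node = _signed_distance(
            np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]))
        solvent_frac = np.clip(s_node / h + 0.5, 0.0, 1.0).reshape(shape)
        kbar2_h2 = kappa2 * solvent_frac * h * h  # screening outside solute
    phi0 = _boundary_potential(frame, charges, xs, ys, zs, grid.eps_out, kappa)
    phi_solv, _, _ = _solve_grid(ex, ey, ez, source, kbar2_h2, phi0,
                                 grid.tol, grid.max_iter, grid.omega)
    e_solv = 0.5 * float(np.sum(
        charges * _trilinear(phi_solv, frame, xs, ys, zs, h)))

    # Uniform eps_in reference on the identical grid
    exu = np.full(ex.shape, grid.eps_in)
    eyu = np.full(ey.shape, grid.eps_in)
    ezu = np.full(ez.shape, grid.eps_in)
    phi0r = _boundary_potential(frame, charges, xs, ys, zs, grid.eps_in, 0.0)
    phi_ref, _, _ = _solve_grid(exu, eyu, ezu, source, np.zeros(shape), phi0r,
                                grid.tol, grid.max_iter, grid.omega)
    e_ref = 0.5 * float(np.sum(
        charges * _trilinear(phi_ref, frame, xs, ys, zs, h)))
    return e_solv - e_ref


# ---------------------------------------------------------------------------
# MM/PBSA
# ---------------------------------------------------------------------------

@dataclass
class MmpbsaConfig:
    """Tunables of the MM/PBSA estimate.

    ``gamma``/``beta`` parametrise the SASA-linear nonpolar term
    (kJ mol^-1 A^-2 and kJ/mol); atom radii for both SASA and the dielectric
    map are the stored half-Rmin values.
    """

    eps_in: float = 2.0
    eps_out: float = 78.54
    spacing: float = 0.8
    ionic_strength: float = 0.0
    gamma: float = 0.0227
    beta: float = 0.0
    probe: float = 1.4
    sasa_points: int = 240
    cutoff: Optional[float] = None
    stride: int = 1

    def pb_grid(self, extent=None) -> PbGrid:
        return PbGrid(spacing=self.spacing, extent=extent, eps_in=self.eps_in,
                      eps_out=self.eps_out, ionic_strength=self.ionic_strength)


@dataclass
class BindingReport:
    """Per-frame MM/PBSA terms and their mean +/- sample SD (kJ/mol)."""

    times: np.ndarray
    mm_gas: np.ndarray
    g_polar: np.ndarray
    g_nonpolar: np.ndarray
    t_ds: np.ndarray  # zero by policy, reported explicitly

    @property
    def g_binding(self) -> np.ndarray:
        return self.mm_gas + self.g_polar + self.g_nonpolar - self.t_ds

    def summary(self) -> dict:
        out = {}
        for key in ("mm_gas", "g_polar", "g_nonpolar", "t_ds", "g_binding"):
            x = getattr(self, key)
            sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
            out[key] = {"mean": float(np.mean(x)), "sd": sd}
        return out


def _radii_for(system: MolecularSystem, idx: np.ndarray) -> np.ndarray:
    radii = system.lj_rmin[idx]
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        bad = idx[~np.isfinite(radii) | (radii <= 0)][0]
        raise ValueError(
            f"atom serial {int(system.serials[bad])} has no usable radius")
    return radii


def solvation_terms(frame: np.ndarray, system: MolecularSystem, selection,
                    config: Optional[MmpbsaConfig] = None,
                    extent=None) -> Tuple[float, float]:
    """(polar, nonpolar) solvation terms for one atom selection, kJ/mol."""
    config = config or MmpbsaConfig()
    idx = np.asarray(selection, int)
    radii = _radii_for(system, idx)
    g_polar = pb_solve(frame[idx], system.charges[idx], radii,
                       config.pb_grid(extent))
    area = sasa(frame[idx], radii, probe=config.probe,
                n_points=config.sasa_points).total
    return g_polar, config.gamma * area + config.beta


def mmpbsa_binding(traj: Trajectory, receptor, ligand,
                   config: Optional[MmpbsaConfig] = None) -> BindingReport:
    """Single-trajectory MM/PBSA over receptor/ligand atom sets."""
    config = config or MmpbsaConfig()
    receptor = np.asarray(receptor, int)
    ligand = np.asarray(ligand, int)
    if receptor.size == 0 or ligand.size == 0:
        raise ValueError("receptor and ligand selections must be nonempty")
    if np.intersect1d(receptor, ligand).size:
        raise ValueError("receptor and ligand must be disjoint")
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    both = np.concatenate([receptor, ligand])
    frames = range(0, traj.n_frames, max(config.stride, 1))
    idx = list(frames)
    mm = np.empty(len(idx))
    gp = np.empty(len(idx))
    gnp = np.empty(len(idx))
    for k, i in enumerate(idx):
        frame = traj.frames[i]
        e = interaction_energy(frame, traj.system, receptor, ligand,
                               config.cutoff)
        mm[k] = e.total
        # shared grid extent from the complex for comparable solves
        radii_c = _radii_for(traj.system, both)
        span = (frame[both].max(axis=0) - frame[both].min(axis=0)
                + 2.0 * (radii_c.max() + 8.0))
        extent = tuple(float(s) for s in span)
        gp_c, gnp_c = solvation_terms(frame, traj.system, both, config, extent)
        gp_r, gnp_r = solvation_terms(frame, traj.system, receptor, config,
                                      extent)
        gp_l, gnp_l = solvation_terms(frame, traj.system, ligand, config,
                                      extent)
        gp[k] = gp_c - gp_r - gp_l
        gnp[k] = gnp_c - gnp_r - gnp_l
    return BindingReport(times=traj.times[idx].copy(), mm_gas=mm, g_polar=gp,
                         g_nonpolar=gnp, t_ds=np.zeros(len(idx)))
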