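"""Active-site geometry: carotenoid carbon to Fe2+ distances, cleavage-site
assignment and substrate ranking.

Carotenoid cleavage dioxygenases break one of three double bonds of the
polyene chain: C7=C8 or C9=C10 (asymmetric cleavage, producing apocarotenoids
such as beta-citraurin) or the central C15=C15' bond (symmetric cleavage).
The putative site is read off the geometry of the bound substrate: the bond
whose two carbons sit, on average, closest to the catalytic Fe2+ is called.
The prime carbon C15' is encoded as ``C15P`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple, Union

import numpy as np

from .core_model import MolecularSystem, Trajectory

__all__ = [
    "CARBON_LABELS",
    "CLEAVAGE_BONDS",
    "SiteDistances",
    "CleavageCall",
    "carbon_fe_distances",
    "assign_cleavage_site",
    "rank_substrates",
]

CARBON_LABELS = ("C7", "C8", "C9", "C10", "C15", "C15P")

# Cleavable double bonds and their flanking carbons; C15=C15P is the
# symmetric (central) site.
CLEAVAGE_BONDS: Dict[str, Tuple[str, str]] = {
    "C7=C8": ("C7", "C8"),
    "C9=C10": ("C9", "C10"),
    "C15=C15P": ("C15", "C15P"),
}


@dataclass
class SiteDistances:
    """Carbon-to-Fe distances (angstrom) keyed by carbon label.

    When computed over a trajectory, ``distances`` holds the per-label means
    and ``series`` the per-frame values.
    """

    distances: Dict[str, float]
    series: Optional[Dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        missing = [l for l in CARBON_LABELS if l not in self.distances]
        if missing:
            raise ValueError(f"missing carbon labels: {missing}")
        if any(v < 0 for v in self.distances.values()):
            raise ValueError("distances must be >= 0")


@dataclass
class CleavageCall:
    site: str  # "C7=C8", "C9=C10", "C15=C15P" or "ambiguous"
    mode: str  # "asymmetric", "symmetric" or "ambiguous"
    bond_scores: Dict[str, float]


def _label_indices(system: MolecularSystem, ligand) -> Dict[str, int]:
    ligand = np.asarray(ligand, int)
    out = {}
    for label in CARBON_LABELS:
        hits = [int(i) for i in ligand if str(system.names[i]) == label]
        if not hits:
            raise ValueError(f"labelled carbon {label!r} not found in ligand")
        out[label] = hits[0]
    return out


def carbon_fe_distances(traj_or_frame: Union[Trajectory, np.ndarray],
                        system: Optional[MolecularSystem] = None,
                        ligand=None, fe: Optional[int] = None) -> SiteDistances:
    """Euclidean C-Fe distance per labelled carbon.

    Accepts a single frame (with ``system``) or a whole trajectory, in which
    case per-frame series and their means are returned.
    """
    if isinstance(traj_or_frame, Trajectory):
        traj = traj_or_frame
        system = traj.system
        labels = _label_indices(system, ligand)
        fe = int(fe)
        series = {}
        for label, i in labels.items():
            d = np.linalg.norm(traj.frames[:, i] - traj.frames[:, fe], axis=1)
            series[label] = d
        means = {l: float(d.mean()) for l, d in series.items()}
        return SiteDistances(distances=means, series=series)
    frame = np.asarray(traj_or_frame, float)
    if system is None:
        raise ValueError("system required for single-frame input")
    labels = _label_indices(system, ligand)
    fe = int(fe)
    dist = {l: float(np.linalg.norm(frame[i] - frame[fe]))
            for l, i in labels.items()}
    return SiteDistances(distances=dist)


def assign_cleavage_site(d: SiteDistances,
                         tie_tolerance: float = 0.3) -> CleavageCall:
    """Call the cleavage site from carbon-Fe distances.

    Each bond is scored by the mean distance of its two carbons; the minimum
    wins.  If the best and second-best scores differ by at most
    ``tie_tolerance`` (angstrom) the call is ambiguous.
    """
    scores = {bond: (d.distances[a] + d.distances[b]) / 2.0
              for bond, (a, b) in CLEAVAGE_BONDS.items()}
    ordered = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    best, second = ordered[0], ordered[1]
    if second[1] - best[1] <= tie_tolerance:
        return CleavageCall(site="ambiguous", mode="ambiguous",
                            bond_scores=scores)
    mode = "symmetric" if best[0] == "C15=C15P" else "asymmetric"
    return CleavageCall(site=best[0], mode=mode, bond_scores=scores)


def rank_substrates(reports: Mapping[str, float],
                    mode: str = "mmpbsa") -> List[Tuple[str, float, bool]]:
    """Rank ligands by binding score, most negative (best) first.

    ``reports`` maps ligand label to a score in kJ/mol (interaction energy
    or MM/PBSA estimate; ``mode`` is recorded semantics only).  Ties are
    broken lexicographically and flagged.  Returns a list of
    ``(ligand, score, tied_with_neighbour)``.
    """
    if mode not in ("uab", "mmpbsa"):
        raise ValueError(f"unknown ranking mode {mode!r}")
    if not reports:
        raise ValueError("empty report map")
    items = sorted(reports.items(), key=lambda kv: (kv[1], kv[0]))
    out = []
    for i, (name, score) in enumerate(items):
        tied = ((i > 0 and items[i - 1][1] == score)
                or (i + 1 < len(items) and items[i + 1][1] == score))
        out.append((name, float(score), tied))
    return out
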