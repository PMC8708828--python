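"""Core data model, file I/O and atom selection.

Conventions used throughout the package:

* Coordinates are in angstrom, energies in kJ/mol, charges in elementary
  charge units, times in picoseconds.
* Lennard-Jones parameters are stored per atom as ``lj_rmin`` (the half-Rmin
  value, so that the pair minimum distance is ``rmin_a + rmin_b`` -- the
  convention of CHARMM parameter files, which list Rmin/2) and ``lj_epsilon``
  (well depth, kJ/mol, combined geometrically).
* The prime in the carotenoid atom name C15' is not representable in PDB
  atom-name columns; it is encoded as ``C15P`` in all files and selections.
* Residue numbering is preserved exactly as read; no renumbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

__all__ = [
    "AtomRecord",
    "MolecularSystem",
    "Trajectory",
    "SelectionError",
    "ParseError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_params",
    "write_params",
    "apply_params",
    "select_atoms",
    "combine_systems",
]

# Elements recognised when inferring from the leading characters of an atom
# name.  Two-letter symbols are matched first.  Names whose leading letters
# match no entry raise instead of guessing.
_TWO_LETTER = {"FE", "CL", "NA", "MG", "ZN", "BR", "CA"}
_ONE_LETTER = {"C", "N", "O", "H", "P", "S", "F", "K"}


class ParseError(ValueError):
    """A structure/trajectory/parameter file failed to parse."""


class SelectionError(ValueError):
    """A selection expression is syntactically or semantically invalid."""


@dataclass
class AtomRecord:
    """One atom: identity, coordinates and optional nonbonded parameters."""

    serial: int
    name: str
    residue_name: str
    residue_id: int
    chain: str
    element: str
    coords: np.ndarray
    charge: Optional[float] = None
    lj_rmin: Optional[float] = None  # half-Rmin, angstrom
    lj_epsilon: Optional[float] = None  # kJ/mol, >= 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be 3 finite reals")
        if self.lj_epsilon is not None and self.lj_epsilon < 0:
            raise ValueError(f"atom {self.serial}: lj_epsilon must be >= 0")


def infer_element(name: str) -> str:
    """Infer an element symbol from an atom name (e.g. ``C15P`` -> ``C``)."""
    stripped = name.strip().lstrip("0123456789").upper()
    if stripped[:2] in _TWO_LETTER:
        return stripped[:2].capitalize() if len(stripped[:2]) == 2 else stripped[:2]
    if stripped[:1] in _ONE_LETTER:
        return stripped[:1]
    raise ParseError(f"cannot infer element from atom name {name!r}")


class MolecularSystem:
    """An ordered set of atoms plus named atom-index groups.

    Atom attributes are stored as parallel numpy arrays for vectorised
    analysis; :meth:`atom` materialises individual :class:`AtomRecord` views.
    Missing charges / LJ parameters are held as NaN internally.
    """

    def __init__(self, atoms: Sequence[AtomRecord],
                 groups: Optional[Mapping[str, Sequence[int]]] = None):
        if len(atoms) == 0:
            raise ValueError("a MolecularSystem needs at least one atom")
        self.serials = np.array([a.serial for a in atoms], dtype=int)
        if len(np.unique(self.serials)) != len(atoms):
            raise ValueError("atom serials must be unique")
        self.names = np.array([a.name for a in atoms], dtype=object)
        self.residue_names = np.array([a.residue_name for a in atoms], dtype=object)
        self.residue_ids = np.array([a.residue_id for a in atoms], dtype=int)
        self.chains = np.array([a.chain for a in atoms], dtype=object)
        self.elements = np.array([a.element for a in atoms], dtype=object)
        self.coords = np.array([a.coords for a in atoms], dtype=float)
        self.charges = np.array(
            [np.nan if a.charge is None else a.charge for a in atoms], dtype=float)
        self.lj_rmin = np.array(
            [np.nan if a.lj_rmin is None else a.lj_rmin for a in atoms], dtype=float)
        self.lj_epsilon = np.array(
            [np.nan if a.lj_epsilon is None else a.lj_epsilon for a in atoms],
            dtype=float)
        self.groups: Dict[str, np.ndarray] = {}
        for gname, idx in (groups or {}).items():
            idx = np.asarray(sorted(idx), dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= len(atoms)):
                raise ValueError(f"group {gname!r} has out-of-range indices")
            self.groups[gname] = idx

    @property
    def n_atoms(self) -> int:
        return len(self.serials)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serials[i]), name=str(self.names[i]),
            residue_name=str(self.residue_names[i]),
            residue_id=int(self.residue_ids[i]), chain=str(self.chains[i]),
            element=str(self.elements[i]), coords=self.coords[i].copy(),
            charge=None if np.isnan(self.charges[i]) else float(self.charges[i]),
            lj_rmin=None if np.isnan(self.lj_rmin[i]) else float(self.lj_rmin[i]),
            lj_epsilon=None if np.isnan(self.lj_epsilon[i])
            else float(self.lj_epsilon[i]),
        )

    @property
    def atoms(self) -> List[AtomRecord]:
        return [self.atom(i) for i in range(self.n_atoms)]

    def heavy_mask(self) -> np.ndarray:
        """Boolean mask of non-hydrogen atoms."""
        return np.array([e.upper() != "H" for e in self.elements], dtype=bool)

    def residue_index_map(self) -> Dict[int, np.ndarray]:
        """Map residue_id -> atom indices (order of first appearance)."""
        out: Dict[int, List[int]] = {}
        for i, rid in enumerate(self.residue_ids):
            out.setdefault(int(rid), []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}


@dataclass
class Trajectory:
    """Ordered coordinate frames (n_frames x n_atoms x 3, angstrom) with times (ps)."""

    system: MolecularSystem
    frames: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.system.n_atoms \
                or self.frames.shape[2] != 3:
            raise ValueError(
                f"frames must be (n_frames, {self.system.n_atoms}, 3); "
                f"got {self.frames.shape}")
        if len(self.times) != len(self.frames):
            raise ValueError("one time per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)


# ---------------------------------------------------------------------------
# Structure I/O
# ---------------------------------------------------------------------------

def _system_to_atom_array(system: MolecularSystem):
    import biotite.structure as struc

    arr = struc.AtomArray(system.n_atoms)
    arr.coord = np.asarray(system.coords, dtype=np.float32)
    arr.atom_name = system.names.astype(str)
    arr.res_name = system.residue_names.astype(str)
    arr.res_id = system.residue_ids.copy()
    arr.chain_id = system.chains.astype(str)
    arr.element = system.elements.astype(str)
    return arr


def write_structure(system: MolecularSystem, path) -> None:
    """Write a PDB file (ATOM records, MODEL-free single structure)."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_system_to_atom_array(system))
    pdb.write(str(path))


def write_pqr(system: MolecularSystem, path) -> None:
    """Write a whitespace-delimited PQR file (charge + radius columns).

    The radius column holds ``lj_rmin`` (half-Rmin) and is read back into the
    same field; missing values are written as 0.0.
    """
    with open(path, "w") as fh:
        for i in range(system.n_atoms):
            q = 0.0 if np.isnan(system.charges[i]) else system.charges[i]
            r = 0.0 if np.isnan(system.lj_rmin[i]) else system.lj_rmin[i]
            x, y, z = system.coords[i]
            fh.write(
                f"ATOM {int(system.serials[i]):6d} {str(system.names[i]):<4s} "
                f"{str(system.residue_names[i]):<4s} {int(system.residue_ids[i]):5d} "
                f"{x:10.4f} {y:10.4f} {z:10.4f} {q:8.4f} {r:7.4f}\n")
        fh.write("END\n")


def _read_pdb(path) -> MolecularSystem:
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure()  # AtomArrayStack; MODEL 1 = index 0
    except Exception as exc:  # biotite raises on malformed records
        raise ParseError(f"{path}: {exc}") from exc
    if stack.array_length() == 0:
        raise ParseError(f"{path}: zero atoms")
    arr = stack[0]
    atoms = []
    for i in range(arr.array_length()):
        elem = str(arr.element[i]).strip()
        name = str(arr.atom_name[i]).strip()
        atoms.append(AtomRecord(
            serial=i + 1, name=name,
            residue_name=str(arr.res_name[i]).strip(),
            residue_id=int(arr.res_id[i]),
            chain=str(arr.chain_id[i]).strip() or "A",
            element=elem if elem else infer_element(name),
            coords=np.asarray(arr.coord[i], dtype=float)))
    return MolecularSystem(atoms)


def _read_pqr(path) -> MolecularSystem:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
    if len(u.atoms) == 0:
        raise ParseError(f"{path}: zero atoms")
    atoms = []
    for i, a in enumerate(u.atoms):
        name = str(a.name).strip()
        try:
            chain = str(a.segid).strip() or "A"
        except Exception:
            chain = "A"
        atoms.append(AtomRecord(
            serial=i + 1, name=name, residue_name=str(a.resname).strip(),
            residue_id=int(a.resid), chain=chain,
            element=infer_element(name),
            coords=np.asarray(a.position, dtype=float),
            charge=float(a.charge), lj_rmin=float(a.radius)))
    return MolecularSystem(atoms)


def read_structure(path, format: Optional[str] = None) -> MolecularSystem:
    """Read a PDB or PQR file into a :class:`MolecularSystem`.

    Multi-MODEL PDB files yield the system of MODEL 1.  PQR charge and radius
    columns populate ``charge`` and ``lj_rmin``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "pqr":
        return _read_pqr(path)
    raise ValueError(f"unsupported structure format: {fmt!r}")


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path, format: Optional[str] = None) -> None:
    """Write frames to DCD (CHARMM/NAMD dialect) or multi-MODEL PDB.

    For DCD the header ``delta`` stores the frame spacing in ps directly
    (uniform spacing assumed; the first frame time is not representable).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "dcd":
        from MDAnalysis.lib.formats.libdcd import DCDFile

        dt = float(traj.times[1] - traj.times[0]) if traj.n_frames > 1 else 1.0
        with DCDFile(str(path), "w") as fh:
            fh.write_header(remarks="memscan trajectory", natoms=traj.system.n_atoms,
                            istart=0, nsavc=1, delta=dt, is_periodic=0)
            for frame in traj.frames:
                fh.write(np.asarray(frame, dtype=np.float32))
    elif fmt == "pdb":
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        arr = _system_to_atom_array(traj.system)
        stack = struc.stack([arr] * traj.n_frames)
        stack.coord = np.asarray(traj.frames, dtype=np.float32)
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))
    else:
        raise ValueError(f"unsupported trajectory format: {fmt!r}")


def read_trajectory(path, system: MolecularSystem,
                    format: Optional[str] = None) -> Trajectory:
    """Read a DCD or multi-MODEL PDB trajectory for an existing system.

    Frame times come from the DCD header spacing when present, else uniform
    1 ps spacing starting at 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "dcd":
        from MDAnalysis.lib.formats.libdcd import DCDFile

        with DCDFile(str(path)) as fh:
            header = dict(fh.header)
            frames = np.array([frame.xyz.copy() for frame in fh], dtype=float)
        dt = float(header.get("delta", 0.0)) * max(int(header.get("nsavc", 1)), 1)
        if dt <= 0:
            dt = 1.0
    elif fmt == "pdb":
        from biotite.structure.io.pdb import PDBFile

        stack = PDBFile.read(str(path)).get_structure()
        frames = np.asarray(stack.coord, dtype=float)
        dt = 1.0
    else:
        raise ValueError(f"unsupported trajectory format: {fmt!r}")
    if frames.ndim != 3 or frames.shape[1] != system.n_atoms:
        raise ParseError(
            f"{path}: trajectory has {frames.shape[1] if frames.ndim == 3 else '?'} "
            f"atoms per frame but the system has {system.n_atoms}")
    times = np.arange(len(frames), dtype=float) * dt
    return Trajectory(system=system, frames=frames, times=times)


# ---------------------------------------------------------------------------
# Nonbonded parameter tables
# ---------------------------------------------------------------------------

def read_params(path) -> Dict[Tuple[str, str], Tuple[float, float, float]]:
    """Read a parameter table keyed by (residue_name, atom_name).

    Schema: whitespace/TSV with columns ``residue atom charge rmin epsilon``
    (header line optional, detected by non-numeric third column).  Charge in e,
    rmin = half-Rmin in angstrom, epsilon in kJ/mol.  Duplicate keys: last one
    wins with a warning.
    """
    table: Dict[Tuple[str, str], Tuple[float, float, float]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ParseError(
                    f"{path}:{lineno}: expected 5 columns "
                    "(residue atom charge rmin epsilon)")
            try:
                triple = (float(parts[2]), float(parts[3]), float(parts[4]))
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ParseError(f"{path}:{lineno}: non-numeric parameter columns")
            key = (parts[0], parts[1])
            if key in table:
                warnings.warn(f"duplicate parameter key {key}; last row wins")
            table[key] = triple
    return table


def write_params(table: Mapping[Tuple[str, str], Tuple[float, float, float]],
                 path) -> None:
    with open(path, "w") as fh:
        fh.write("residue\tatom\tcharge\trmin\tepsilon\n")
        for (res, atom), (q, rmin, eps) in table.items():
            fh.write(f"{res}\t{atom}\t{q:.6f}\t{rmin:.6f}\t{eps:.6f}\n")


def apply_params(system: MolecularSystem,
                 table: Mapping[Tuple[str, str], Tuple[float, float, float]],
                 strict: bool = True) -> None:
    """Populate charge / LJ fields from a parameter table, in place."""
    for i in range(system.n_atoms):
        key = (str(system.residue_names[i]), str(system.names[i]))
        if key not in table:
            if strict:
                raise KeyError(f"no parameters for atom {key}")
            continue
        q, rmin, eps = table[key]
        system.charges[i] = q
        system.lj_rmin[i] = rmin
        system.lj_epsilon[i] = eps


# ---------------------------------------------------------------------------
# Selection language
# ---------------------------------------------------------------------------
#
# Grammar (tiny, deterministic):
#   expr    := or_expr
#   or_expr := and_expr ( "or" and_expr )*
#   and_expr:= not_expr ( "and" not_expr )*
#   not_expr:= "not" not_expr | primary
#   primary := "(" expr ")" | "all" | "none"
#            | "name" VALUE+ | "resname" VALUE+ | "resid" INT+ | "group" NAME
#
# Multiple values after a keyword are OR-ed (CHARMM/VMD style).

_KEYWORDS = {"and", "or", "not", "name", "resname", "resid", "group",
             "all", "none", "(", ")"}


def _tokenize(expression: str) -> List[Tuple[str, int]]:
    tokens: List[Tuple[str, int]] = []
    i, n = 0, len(expression)
    while i < n:
        c = expression[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < n and not expression[j].isspace() and expression[j] not in "()":
            j += 1
        tokens.append((expression[i:j], i))
        i = j
    return tokens


class _Parser:
    def __init__(self, expression: str, system: MolecularSystem):
        self.expression = expression
        self.tokens = _tokenize(expression)
        self.pos = 0
        self.system = system

    def _peek(self) -> Optional[str]:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def _next(self) -> Tuple[str, int]:
        if self.pos >= len(self.tokens):
            raise SelectionError(
                f"unexpected end of selection {self.expression!r}")
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionError("empty selection expression")
        mask = self._or_expr()
        if self.pos != len(self.tokens):
            tok, col = self.tokens[self.pos]
            raise SelectionError(
                f"unexpected token {tok!r} at position {col} in "
                f"{self.expression!r}")
        return mask

    def _or_expr(self) -> np.ndarray:
        mask = self._and_expr()
        while self._peek() == "or":
            self._next()
            mask = mask | self._and_expr()
        return mask

    def _and_expr(self) -> np.ndarray:
        mask = self._not_expr()
        while self._peek() == "and":
            self._next()
            mask = mask & self._not_expr()
        return mask

    def _not_expr(self) -> np.ndarray:
        if self._peek() == "not":
            self._next()
            return ~self._not_expr()
        return self._primary()

    def _values(self) -> List[str]:
        vals = []
        while self._peek() is not None and self._peek() not in _KEYWORDS:
            vals.append(self._next()[0])
        if not vals:
            tok, col = self.tokens[self.pos - 1]
            raise SelectionError(
                f"keyword {tok!r} at position {col} needs at least one value")
        return vals

    def _primary(self) -> np.ndarray:
        tok, col = self._next()
        sysm = self.system
        n = sysm.n_atoms
        if tok == "(":
            mask = self._or_expr()
            closing, ccol = self._next()
            if closing != ")":
                raise SelectionError(f"expected ')' at position {ccol}")
            return mask
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "none":
            return np.zeros(n, dtype=bool)
        if tok == "name":
            vals = set(self._values())
            return np.array([str(x) in vals for x in sysm.names], dtype=bool)
        if tok == "resname":
            vals = set(self._values())
            return np.array([str(x) in vals for x in sysm.residue_names],
                            dtype=bool)
        if tok == "resid":
            try:
                vals = {int(v) for v in self._values()}
            except ValueError as exc:
                raise SelectionError(f"resid values must be integers: {exc}")
            return np.isin(sysm.residue_ids, sorted(vals))
        if tok == "group":
            gname = self._next()[0]
            if gname not in sysm.groups:
                raise SelectionError(
                    f"unknown group {gname!r}; known: {sorted(sysm.groups)}")
            mask = np.zeros(n, dtype=bool)
            mask[sysm.groups[gname]] = True
            return mask
        raise SelectionError(
            f"unknown token {tok!r} at position {col} in {self.expression!r}")


def select_atoms(system: MolecularSystem, expression: str) -> np.ndarray:
    """Resolve a selection expression to a sorted array of atom indices.

    Supported: ``name``, ``resname``, ``resid``, ``group``, ``all``, ``none``,
    boolean ``and``/``or``/``not`` and parentheses.  Deterministic; may be
    empty.
    """
    mask = _Parser(expression, system).parse()
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------

def combine_systems(*systems: MolecularSystem,
                    group_names: Optional[Sequence[Optional[str]]] = None
                    ) -> MolecularSystem:
    """Concatenate systems, re-serialising atoms and offsetting group indices.

    ``group_names[k]`` (when given and not None) adds/extends a group covering
    all atoms of input ``k``.  Existing groups are carried over with offsets;
    name clashes are unioned.
    """
    records: List[AtomRecord] = []
    groups: Dict[str, List[int]] = {}
    offset = 0
    for k, sysm in enumerate(systems):
        for i in range(sysm.n_atoms):
            rec = sysm.atom(i)
            rec.serial = offset + i + 1
            records.append(rec)
        for gname, idx in sysm.groups.items():
            groups.setdefault(gname, []).extend(int(j) + offset for j in idx)
        if group_names is not None and group_names[k] is not None:
            groups.setdefault(group_names[k], []).extend(
                range(offset, offset + sysm.n_atoms))
        offset += sysm.n_atoms
    return MolecularSystem(records, groups)
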