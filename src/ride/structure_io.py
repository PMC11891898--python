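"""Molecular structures, PDB and per-atom area-file I/O.

Coordinates are stored in nm internally; PDB records are Angstrom-native and
converted on read/write.  Only the 20 standard amino acids plus the ACE/NME
(or NMA) capping groups are recognized; anything else raises rather than
guessing.  Area files follow the MSMS-style dialect: whitespace-delimited
rows, first numeric column the 1-based atom index, second the
solvent-excluded area in A^2; header or non-numeric lines are skipped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .constants import (AA3_TO_1, CAP_MASS, CAP_RESIDUES, RESIDUE_MASS,
                        STANDARD_AAS, WATER_MASS)

logger = logging.getLogger(__name__)

ANGSTROM_PER_NM = 10.0

#: key under which cap-group atom areas are accumulated
CAP_KEY = "CAP"


class StructureError(ValueError):
    """Raised for malformed structures or structure files."""


@dataclass
class Atom:
    """A single atom: 1-based serial, names, residue assignment, nm position.

    ``radius`` is unset (None) until a :class:`ride.sesa.RadiusSet` assigns it.
    """
    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray
    radius: Optional[float] = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(
                f"atom {self.serial}: position must be a finite 3-vector")
        self.residue_name = self.residue_name.upper()
        if self.radius is not None and self.radius <= 0:
            raise StructureError(f"atom {self.serial}: radius must be > 0")


@dataclass
class Residue:
    name: str
    index: int
    atom_span: Tuple[int, int]  # [start, stop) indices into Structure.atoms

    @property
    def is_cap(self) -> bool:
        return self.name in CAP_RESIDUES


@dataclass
class Structure:
    """Ordered atoms grouped into ordered residues."""
    atoms: List[Atom]
    residues: List[Residue] = field(default_factory=list)
    label: str = ""

    def __post_init__(self):
        if not self.residues and self.atoms:
            self.residues = _group_residues(self.atoms)
        _validate(self)

    @property
    def sequence(self) -> str:
        """1-letter sequence over the standard residues (caps excluded)."""
        return "".join(AA3_TO_1[r.name] for r in self.residues
                       if r.name in AA3_TO_1)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def radii(self) -> np.ndarray:
        r = [a.radius for a in self.atoms]
        if any(v is None for v in r):
            raise StructureError("radii not assigned; call assign_radii first")
        return np.asarray(r, dtype=float)

    def residue_of_atom(self) -> np.ndarray:
        """Index into ``residues`` for every atom."""
        out = np.empty(len(self.atoms), dtype=int)
        for i, res in enumerate(self.residues):
            out[res.atom_span[0]:res.atom_span[1]] = i
        return out

    def transformed(self, rotation: np.ndarray = None,
                    translation: np.ndarray = None) -> "Structure":
        """Rigidly transformed copy (rotation applied first)."""
        atoms = []
        for a in self.atoms:
            p = a.position
            if rotation is not None:
                p = np.asarray(rotation) @ p
            if translation is not None:
                p = p + np.asarray(translation)
            atoms.append(replace(a, position=p))
        return Structure(atoms, list(self.residues), self.label)


def _group_residues(atoms: Sequence[Atom]) -> List[Residue]:
    residues: List[Residue] = []
    start = 0
    for i in range(1, len(atoms) + 1):
        if i == len(atoms) or (
                atoms[i].residue_index != atoms[start].residue_index
                or atoms[i].chain_id != atoms[start].chain_id):
            residues.append(Residue(atoms[start].residue_name,
                                    atoms[start].residue_index, (start, i)))
            start = i
    return residues


def _validate(s: Structure) -> None:
    covered = 0
    last_index = None
    for res in s.residues:
        lo, hi = res.atom_span
        if lo != covered:
            raise StructureError("residue spans must tile the atom list")
        covered = hi
        if last_index is not None and res.index < last_index:
            raise StructureError("residues must be ordered by index")
        last_index = res.index
        for a in s.atoms[lo:hi]:
            if a.residue_name != res.name:
                raise StructureError(
                    f"atom {a.serial} residue {a.residue_name} does not match "
                    f"its residue record {res.name}")
    if covered != len(s.atoms):
        raise StructureError("every atom must belong to exactly one residue")


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def read_pdb(path, include_hetero: bool = False) -> Structure:
    """Read a PDB file into a :class:`Structure` (coordinates A -> nm).

    ACE/NME/NMA residues are retained and flagged as caps.  HETATM waters and
    ions are ignored unless ``include_hetero`` is set.  Unrecognized residue
    names raise.
    """
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        arr = pdb_file.get_structure(model=1, extra_fields=["atom_id"])
    except Exception as exc:  # biotite reports the offending line
        raise StructureError(f"{path}: could not parse PDB file: {exc}") from exc
    if arr.array_length() == 0:
        raise StructureError(f"{path}: empty structure")

    known = set(STANDARD_AAS) | set(CAP_RESIDUES)
    atoms: List[Atom] = []
    for i in range(arr.array_length()):
        res_name = str(arr.res_name[i]).upper()
        if res_name not in known:
            if arr.hetero[i] and not include_hetero:
                continue
            raise StructureError(
                f"{path}: unrecognized residue '{res_name}' "
                f"(only the 20 standard amino acids and ACE/NME/NMA caps are "
                f"supported)")
        atoms.append(Atom(
            serial=int(arr.atom_id[i]),
            name=str(arr.atom_name[i]),
            element=str(arr.element[i]).capitalize() or _guess_element(
                str(arr.atom_name[i])),
            residue_name=res_name,
            residue_index=int(arr.res_id[i]),
            chain_id=str(arr.chain_id[i]),
            position=arr.coord[i] / ANGSTROM_PER_NM,
        ))
    if not atoms:
        raise StructureError(f"{path}: no recognized atoms")
    return Structure(atoms, label=path.stem)


def write_pdb(s: Structure, path) -> None:
    """Write a :class:`Structure` to PDB (coordinates nm -> A)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = s.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = s.coordinates() * ANGSTROM_PER_NM
    arr.set_annotation("atom_id", np.array([a.serial for a in s.atoms]))
    arr.atom_name = np.array([a.name for a in s.atoms])
    arr.element = np.array([a.element.upper() for a in s.atoms])
    arr.res_name = np.array([a.residue_name for a in s.atoms])
    arr.res_id = np.array([a.residue_index for a in s.atoms])
    arr.chain_id = np.array([a.chain_id for a in s.atoms])
    arr.hetero = np.zeros(n, dtype=bool)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip().lstrip("0123456789")
    return name[:1].capitalize() if name else "X"


# ---------------------------------------------------------------------------
# terminus detection
# ---------------------------------------------------------------------------

def detect_termini(s: Structure) -> str:
    """Classify the backbone terminus mode: ``"capped"`` or ``"zwitterionic"``.

    Capped requires both an ACE and an NME (or NMA) cap residue; a single cap
    is treated conservatively as zwitterionic with a warning.
    """
    if not s.residues:
        raise StructureError("structure has no residues")
    names = {r.name for r in s.residues}
    has_ace = "ACE" in names
    has_nme = bool(names & {"NME", "NMA"})
    if has_ace and has_nme:
        return "capped"
    if has_ace or has_nme:
        warnings.warn("only one terminal cap present; treating the backbone "
                      "as zwitterionic", stacklevel=2)
    return "zwitterionic"


# ---------------------------------------------------------------------------
# per-atom area tables
# ---------------------------------------------------------------------------

@dataclass
class AtomAreaTable:
    """Per-atom solvent-excluded areas in nm^2, keyed by atom serial."""
    areas: Dict[int, float]
    source: str = "internal"  # "internal" | "external_file"

    def __post_init__(self):
        for serial, area in self.areas.items():
            if area < 0:
                raise StructureError(
                    f"atom {serial}: negative area {area}")

    @property
    def total(self) -> float:
        return float(sum(self.areas.values()))


def read_area_file(path, s: Structure) -> AtomAreaTable:
    """Read an MSMS-style per-atom area file paired with ``s`` (A^2 -> nm^2)."""
    path = Path(path)
    rows: List[Tuple[int, float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split()
        try:
            idx = int(float(tokens[0]))
            area = float(tokens[1])
        except (ValueError, IndexError):
            continue  # header / non-numeric line
        if area < 0:
            raise StructureError(f"{path}:{lineno}: negative area {area}")
        rows.append((idx, area))
    if len(rows) != s.n_atoms:
        raise StructureError(
            f"{path}: {len(rows)} area rows but structure has {s.n_atoms} "
            f"atoms")
    areas = {atom.serial: area / ANGSTROM_PER_NM ** 2
             for atom, (_, area) in zip(s.atoms, rows)}
    return AtomAreaTable(areas, source="external_file")


def write_area_file(table: AtomAreaTable, s: Structure, path) -> None:
    """Export per-atom areas in the same MSMS-style dialect (nm^2 -> A^2)."""
    lines = ["# atom_index  ses_area_A2"]
    for i, atom in enumerate(s.atoms, start=1):
        lines.append(f"{i:6d}  {table.areas[atom.serial] * 100.0:12.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# masses and per-type area accumulation
# ---------------------------------------------------------------------------

def molecular_weight(s: Structure) -> float:
    """Molar mass in kg mol^-1.

    Residue masses are summed; zwitterionic chains add one water per chain
    (the free termini), capped chains add the ACE/NME cap masses instead.
    """
    if not s.residues:
        raise StructureError("empty structure")
    total = 0.0
    has_cap = False
    for res in s.residues:
        if res.name in RESIDUE_MASS:
            total += RESIDUE_MASS[res.name]
        elif res.name in CAP_MASS:
            total += CAP_MASS[res.name]
            has_cap = True
        else:
            raise StructureError(f"unknown residue '{res.name}'")
    if not has_cap:
        n_chains = len({(a.chain_id) for a in s.atoms})
        total += WATER_MASS * n_chains
    return total / 1000.0


def accumulate_sesa_by_restype(s: Structure,
                               table: AtomAreaTable) -> Dict[str, float]:
    """Accumulate per-atom SES areas by amino-acid type (Eq-8 input), nm^2.

    Returns a map with all 20 standard types (absent types 0) plus a ``CAP``
    key collecting cap-group atoms; the map total conserves the per-atom
    total.
    """
    out: Dict[str, float] = {aa: 0.0 for aa in STANDARD_AAS}
    out[CAP_KEY] = 0.0
    res_of = s.residue_of_atom()
    for i, atom in enumerate(s.atoms):
        res = s.residues[res_of[i]]
        key = CAP_KEY if res.is_cap else res.name
        try:
            area = table.areas[atom.serial]
        except KeyError:
            raise StructureError(
                f"area table has no entry for atom serial {atom.serial}")
        out[key] += area
    return out
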