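"""Deterministic generators of test inputs.

* ideal peptide conformers (extended, alpha-helix, polyproline II) built
  from internal coordinates with ACE/NME caps on request,
* the N-methylacetamide (NMA) reference molecule,
* sphere clusters with known analytic areas,
* Brownian trajectories with known diffusion coefficients,
* finite-size (L, D_app) series from the periodic-cell model.

All generators are pure functions of their arguments: repeated calls are
bit-identical.  Peptides are heavy-atom only; side chains use a single
canonical rotamer (all free chi torsions trans) from idealized bond lengths
and angles, which is all the surface-area machinery needs.  The proline and
tryptophan rings close only approximately (sub-0.01 nm seam), a documented
limitation of the internal-coordinate templates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .constants import AA1_TO_3
from .dynamics import FiniteSizeSeries, Trajectory, finite_size_D
from .structure_io import Atom, Structure, StructureError

# backbone geometry, nm / degrees
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = (
    0.1458, 0.1525, 0.1329, 0.1231, 0.1530)
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8
_A_N_CA_CB, _A_C_CA_CB = 110.5, 110.1
_T_CB = 123.0  # improper N-C-CA-CB, fixes the side-chain branch geometry

_CONFORMATIONS = {
    "extended": (180.0, 180.0),
    "alpha_helix": (-57.0, -47.0),
    "polyproline": (-75.0, 145.0),
}

# side-chain templates: (name, element, (a, b, c) refs, bond nm, angle deg,
# torsion deg); refs are names of earlier atoms of the same residue.
_SIDE_CHAINS: Dict[str, List[Tuple[str, str, Tuple[str, str, str],
                                   float, float, float]]] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", "O", ("N", "CA", "CB"), 0.1417, 110.8, 180.0)],
    "CYS": [("SG", "S", ("N", "CA", "CB"), 0.1808, 113.8, 180.0)],
    "THR": [("OG1", "O", ("N", "CA", "CB"), 0.1433, 109.6, 180.0),
            ("CG2", "C", ("N", "CA", "CB"), 0.1521, 110.5, -60.0)],
    "VAL": [("CG1", "C", ("N", "CA", "CB"), 0.1527, 110.4, 180.0),
            ("CG2", "C", ("N", "CA", "CB"), 0.1527, 110.4, 60.0)],
    "LEU": [("CG", "C", ("N", "CA", "CB"), 0.1530, 116.3, 180.0),
            ("CD1", "C", ("CA", "CB", "CG"), 0.1521, 110.7, 180.0),
            ("CD2", "C", ("CA", "CB", "CG"), 0.1521, 110.7, 60.0)],
    "ILE": [("CG1", "C", ("N", "CA", "CB"), 0.1530, 110.4, 180.0),
            ("CG2", "C", ("N", "CA", "CB"), 0.1521, 110.5, -60.0),
            ("CD1", "C", ("CA", "CB", "CG1"), 0.1513, 113.8, 180.0)],
    "PRO": [("CG", "C", ("N", "CA", "CB"), 0.1492, 104.5, 30.0),
            ("CD", "C", ("CA", "CB", "CG"), 0.1503, 106.1, -35.0)],
    "MET": [("CG", "C", ("N", "CA", "CB"), 0.1520, 114.1, 180.0),
            ("SD", "S", ("CA", "CB", "CG"), 0.1803, 112.7, 180.0),
            ("CE", "C", ("CB", "CG", "SD"), 0.1791, 100.9, 180.0)],
    "ASP": [("CG", "C", ("N", "CA", "CB"), 0.1516, 112.6, 180.0),
            ("OD1", "O", ("CA", "CB", "CG"), 0.1249, 118.4, 0.0),
            ("OD2", "O", ("CA", "CB", "CG"), 0.1249, 118.4, 180.0)],
    "ASN": [("CG", "C", ("N", "CA", "CB"), 0.1516, 112.6, 180.0),
            ("OD1", "O", ("CA", "CB", "CG"), 0.1231, 120.8, 0.0),
            ("ND2", "N", ("CA", "CB", "CG"), 0.1328, 116.4, 180.0)],
    "GLU": [("CG", "C", ("N", "CA", "CB"), 0.1520, 114.1, 180.0),
            ("CD", "C", ("CA", "CB", "CG"), 0.1516, 112.6, 180.0),
            ("OE1", "O", ("CB", "CG", "CD"), 0.1249, 118.4, 0.0),
            ("OE2", "O", ("CB", "CG", "CD"), 0.1249, 118.4, 180.0)],
    "GLN": [("CG", "C", ("N", "CA", "CB"), 0.1520, 114.1, 180.0),
            ("CD", "C", ("CA", "CB", "CG"), 0.1516, 112.6, 180.0),
            ("OE1", "O", ("CB", "CG", "CD"), 0.1231, 120.8, 0.0),
            ("NE2", "N", ("CB", "CG", "CD"), 0.1328, 116.4, 180.0)],
    "LYS": [("CG", "C", ("N", "CA", "CB"), 0.1520, 114.1, 180.0),
            ("CD", "C", ("CA", "CB", "CG"), 0.1520, 111.3, 180.0),
            ("CE", "C", ("CB", "CG", "CD"), 0.1520, 111.3, 180.0),
            ("NZ", "N", ("CG", "CD", "CE"), 0.1489, 111.9, 180.0)],
    "ARG": [("CG", "C", ("N", "CA", "CB"), 0.1520, 114.1, 180.0),
            ("CD", "C", ("CA", "CB", "CG"), 0.1520, 111.3, 180.0),
            ("NE", "N", ("CB", "CG", "CD"), 0.1461, 112.0, 180.0),
            ("CZ", "C", ("CG", "CD", "NE"), 0.1329, 124.2, 180.0),
            ("NH1", "N", ("CD", "NE", "CZ"), 0.1326, 120.0, 0.0),
            ("NH2", "N", ("CD", "NE", "CZ"), 0.1326, 120.0, 180.0)],
    "HIS": [("CG", "C", ("N", "CA", "CB"), 0.1504, 113.8, 180.0),
            ("ND1", "N", ("CA", "CB", "CG"), 0.1378, 122.7, -90.0),
            ("CD2", "C", ("CA", "CB", "CG"), 0.1354, 129.7, 90.0),
            ("CE1", "C", ("CB", "CG", "ND1"), 0.1320, 108.0, 180.0),
            ("NE2", "N", ("CG", "ND1", "CE1"), 0.1333, 109.0, 0.0)],
    "PHE": [("CG", "C", ("N", "CA", "CB"), 0.1510, 113.8, 180.0),
            ("CD1", "C", ("CA", "CB", "CG"), 0.1390, 120.0, 90.0),
            ("CD2", "C", ("CA", "CB", "CG"), 0.1390, 120.0, -90.0),
            ("CE1", "C", ("CB", "CG", "CD1"), 0.1390, 120.0, 180.0),
            ("CE2", "C", ("CB", "CG", "CD2"), 0.1390, 120.0, 180.0),
            ("CZ", "C", ("CG", "CD1", "CE1"), 0.1390, 120.0, 0.0)],
    "TYR": [("CG", "C", ("N", "CA", "CB"), 0.1510, 113.8, 180.0),
            ("CD1", "C", ("CA", "CB", "CG"), 0.1390, 120.0, 90.0),
            ("CD2", "C", ("CA", "CB", "CG"), 0.1390, 120.0, -90.0),
            ("CE1", "C", ("CB", "CG", "CD1"), 0.1390, 120.0, 180.0),
            ("CE2", "C", ("CB", "CG", "CD2"), 0.1390, 120.0, 180.0),
            ("CZ", "C", ("CG", "CD1", "CE1"), 0.1390, 120.0, 0.0),
            ("OH", "O", ("CD1", "CE1", "CZ"), 0.1364, 119.9, 180.0)],
    "TRP": [("CG", "C", ("N", "CA", "CB"), 0.1510, 113.8, 180.0),
            ("CD1", "C", ("CA", "CB", "CG"), 0.1365, 126.9, 90.0),
            ("CD2", "C", ("CA", "CB", "CG"), 0.1433, 126.7, -90.0),
            ("NE1", "N", ("CB", "CG", "CD1"), 0.1374, 110.2, 180.0),
            ("CE2", "C", ("CG", "CD1", "NE1"), 0.1370, 109.0, 0.0),
            ("CE3", "C", ("CB", "CG", "CD2"), 0.1400, 133.9, 180.0),
            ("CZ2", "C", ("CD1", "NE1", "CE2"), 0.1394, 130.1, 180.0),
            ("CZ3", "C", ("CG", "CD2", "CE3"), 0.1391, 118.8, 180.0),
            ("CH2", "C", ("NE1", "CE2", "CZ2"), 0.1368, 117.5, 180.0)],
}


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float
               ) -> np.ndarray:
    """Natural-extension-reference-frame placement.

    Returns d with |d-c| = bond, angle(b,c,d) = angle and dihedral
    (a,b,c,d) = torsion (IUPAC sign convention).
    """
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(angle),
                        bond * math.sin(angle) * math.cos(torsion),
                        bond * math.sin(angle) * math.sin(torsion)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Dihedral angle p0-p1-p2-p3 in degrees (IUPAC sign convention)."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return math.degrees(math.atan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))


@dataclass(frozen=True)
class PeptideSpec:
    """Specification of an ideal peptide conformer fixture."""
    sequence: str
    conformation: str = "extended"
    capped: bool = True
    seed: int = 0  # reserved for optional jitter; the default builds none

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        unknown = set(self.sequence) - set(AA1_TO_3)
        if unknown:
            raise StructureError(
                f"unknown residue letters: {sorted(unknown)}")
        if self.conformation not in _CONFORMATIONS:
            raise ValueError(f"conformation must be one of "
                             f"{sorted(_CONFORMATIONS)}")


class _Builder:
    def __init__(self):
        self.atoms: List[Atom] = []
        self._serial = 0

    def add(self, name: str, element: str, res_name: str, res_index: int,
            position: np.ndarray) -> np.ndarray:
        self._serial += 1
        self.atoms.append(Atom(self._serial, name, element, res_name,
                               res_index, "A", np.asarray(position)))
        return np.asarray(position, dtype=float)


def build_peptide(spec: PeptideSpec) -> Structure:
    """Build an ideal heavy-atom peptide conformer from internal coordinates.

    Extended: phi = psi = 180; alpha-helix: phi = -57, psi = -47;
    polyproline II: phi = -75, psi = 145.  omega is always 180.  Caps are
    ACE (CH3, C, O) and NME (N, CH3).
    """
    phi, psi = _CONFORMATIONS[spec.conformation]
    residues = [AA1_TO_3[ch] for ch in spec.sequence]
    b = _Builder()

    # seed frame: previous-residue surrogate (ACE cap or the first backbone)
    if spec.capped:
        prev_n = np.array([-0.0470, 0.1380, 0.0])  # torsion reference only
        prev_ca = b.add("CH3", "C", "ACE", 0, np.zeros(3))
        prev_c = b.add("C", "C", "ACE", 0, np.array([0.1522, 0.0, 0.0]))
        res_offset = 1
    else:
        first_n = np.zeros(3)
        first_ca = np.array([_B_N_CA, 0.0, 0.0])
        ang = math.radians(_A_N_CA_C)
        first_c = first_ca + _B_CA_C * np.array(
            [-math.cos(ang), math.sin(ang), 0.0])
        res_offset = 1

    positions: List[Dict[str, np.ndarray]] = []
    for i, res3 in enumerate(residues):
        res_id = i + res_offset
        if i == 0 and not spec.capped:
            n = b.add("N", "N", res3, res_id, first_n)
            ca = b.add("CA", "C", res3, res_id, first_ca)
            c = b.add("C", "C", res3, res_id, first_c)
        else:
            n = place_atom(prev_n, prev_ca, prev_c, _B_C_N, _A_CA_C_N, psi)
            if spec.capped and i == 0:
                # ACE carbonyl O sits opposite the peptide bond
                b.add("O", "O", "ACE", 0,
                      place_atom(prev_n, prev_ca, prev_c, _B_C_O,
                                 _A_CA_C_O, psi + 180.0))
            n = b.add("N", "N", res3, res_id, n)
            ca = b.add("CA", "C", res3, res_id,
                       place_atom(prev_ca, prev_c, n, _B_N_CA, _A_C_N_CA,
                                  180.0))
            c = b.add("C", "C", res3, res_id,
                      place_atom(prev_c, n, ca, _B_CA_C, _A_N_CA_C, phi))
        o = b.add("O", "O", res3, res_id,
                  place_atom(n, ca, c, _B_C_O, _A_CA_C_O, psi + 180.0))
        placed = {"N": n, "CA": ca, "C": c, "O": o}
        if res3 != "GLY":
            placed["CB"] = b.add(
                "CB", "C", res3, res_id,
                place_atom(n, c, ca, _B_CA_CB, _A_C_CA_CB, _T_CB))
        for name, elem, refs, bond, angle, torsion in _SIDE_CHAINS[res3]:
            placed[name] = b.add(
                name, elem, res3, res_id,
                place_atom(placed[refs[0]], placed[refs[1]], placed[refs[2]],
                           bond, angle, torsion))
        positions.append(placed)
        prev_n, prev_ca, prev_c = n, ca, c

    if spec.capped:
        nme_n = b.add("N", "N", "NME", len(residues) + res_offset,
                      place_atom(prev_n, prev_ca, prev_c, _B_C_N,
                                 _A_CA_C_N, psi))
        b.add("CH3", "C", "NME", len(residues) + res_offset,
              place_atom(prev_ca, prev_c, nme_n, 0.1450, _A_C_N_CA, 180.0))
    else:
        b.add("OXT", "O", residues[-1], len(residues) + res_offset - 1,
              place_atom(prev_n, prev_ca, prev_c, 0.1249, 117.0, psi))

    atoms = _reorder_by_residue(b.atoms)
    label = f"{spec.sequence}_{spec.conformation}" + (
        "_capped" if spec.capped else "_zwitterionic")
    return Structure(atoms, label=label)


def _reorder_by_residue(atoms: List[Atom]) -> List[Atom]:
    """Sort atoms into residue order (the builder emits the ACE O late and
    OXT onto the last residue) while keeping within-residue placement
    order; serials are renumbered to file order."""
    order = sorted(range(len(atoms)),
                   key=lambda i: (atoms[i].residue_index, i))
    out = []
    for new_serial, i in enumerate(order, start=1):
        atom = atoms[i]
        atom.serial = new_serial
        out.append(atom)
    return out


def build_nma() -> Structure:
    """The N-methylacetamide reference molecule (CH3-CO-NH-CH3, heavy atoms),
    assembled from the ACE and NME cap templates."""
    b = _Builder()
    prev_n = np.array([-0.0470, 0.1380, 0.0])
    ch3 = b.add("CH3", "C", "ACE", 0, np.zeros(3))
    c = b.add("C", "C", "ACE", 0, np.array([0.1522, 0.0, 0.0]))
    n = place_atom(prev_n, ch3, c, _B_C_N, _A_CA_C_N, 180.0)
    b.add("O", "O", "ACE", 0,
          place_atom(prev_n, ch3, c, _B_C_O, _A_CA_C_O, 0.0))
    n = b.add("N", "N", "NME", 1, n)
    b.add("CH3", "C", "NME", 1,
          place_atom(ch3, c, n, 0.1450, _A_C_N_CA, 180.0))
    return Structure(_reorder_by_residue(b.atoms), label="NMA")


def gen_sphere_cluster(n: int, radius: float, spacing: float) -> Structure:
    """n uniform-radius pseudo-atoms on a cubic grid (SESA test substrate)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    side = int(math.ceil(n ** (1.0 / 3.0)))
    atoms = []
    for serial in range(1, n + 1):
        i = serial - 1
        pos = spacing * np.array([i % side, (i // side) % side,
                                  i // (side * side)], dtype=float)
        atoms.append(Atom(serial, "SPH", "C", "SPH", serial, "A", pos,
                          radius=radius))
    return Structure(atoms, label=f"spheres_{n}")


def gen_brownian_trajectory(d: float, n_steps: int, dt: float,
                            seed: int) -> Trajectory:
    """Ideal Brownian trajectory with diffusion coefficient ``d`` (nm^2/ns).

    Cumulative Gaussian steps with per-axis variance 2 D dt; deterministic
    per seed.  ``dt`` in ps.
    """
    if n_steps < 1 or dt <= 0 or d < 0:
        raise ValueError("need n_steps >= 1, dt > 0, d >= 0")
    rng = np.random.default_rng(seed)
    sd = math.sqrt(2.0 * d * dt / 1000.0)  # nm, per axis
    steps = rng.normal(0.0, sd, size=(n_steps, 3)) if sd > 0 else np.zeros(
        (n_steps, 3))
    positions = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    times = np.arange(n_steps + 1) * dt
    return Trajectory(times, positions, label=f"brownian_D{d}_seed{seed}")


def gen_finite_size_series(d0: float, alpha: float, temperature: float,
                           eta: float, box_lengths: Sequence[float],
                           noise_sd: float = 0.0,
                           seed: Optional[int] = None) -> FiniteSizeSeries:
    """Finite-size series from the periodic-cell model, optionally noisy.

    With noise, each D_app receives seeded Gaussian noise of standard
    deviation ``noise_sd`` and the series records ``noise_sd`` as the
    per-point uncertainty.
    """
    ls = np.asarray(list(box_lengths), dtype=float)
    d_app = np.array([finite_size_D(d0, L, temperature, eta, alpha)
                      for L in ls])
    unc = None
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        d_app = d_app + rng.normal(0.0, noise_sd, size=len(ls))
        unc = np.full(len(ls), noise_sd)
    return FiniteSizeSeries(ls, d_app, unc, temperature, eta)
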