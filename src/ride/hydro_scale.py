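"""The hydrodiffusivity scale: Stokes radii, per-residue coefficients and
additive hydrodynamic-radius assembly.

Each unitless hydrodiffusivity coefficient C measures the squared
hydrodynamic-radius contribution a residue type makes per unit of
solvent-excluded surface area,

    C_solute = (R_H,cappedAA^2 - R_H,NMA^2) / (SESA_cappedAA - SESA_NMA),

where the N-methylacetamide (NMA) molecule — the backbone fragment the
ACE/NME caps amount to — is subtracted so that the coefficient isolates the
residue itself.  A peptide or protein hydrodynamic radius is then assembled
additively over its surface,

    R_H,total^2 = C_term * SESA_term + sum_i C_i * SESA_i,

with a terminus constant C_term chosen by backbone mode: the NMA-derived
coefficient for ACE/NME-capped chains, the ASP/LYS monopeptide average for
zwitterionic backbones (their formal charges proxy the charged termini).
SESA_term is the NMA reference area in both modes.

Scales come in two variants: M, derived from capped monopeptide diffusion
coefficients and extended monomer conformers, and D, derived from capped
decapeptide diffusion coefficients and ideal-helix decamers (which fold
secondary-structure propensity — partial backbone burial — into the
coefficients).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, Optional

import numpy as np

from .constants import (STANDARD_AAS, K_B, stokes_einstein_d,
                        stokes_einstein_radius_nm)

PEPTIDE_TABLE_FILE = "table_peptide_diffusion.tsv"

#: infinitely dilute simulation diffusion coefficient of N-methylacetamide
#: at 310.15 K in TIP3P water, 1e-5 cm^2 s^-1 (shipped MD input)
NMA_D0 = 3.32

_ESTIMATE_KINDS = ("D_app", "D_0", "D_eta", "predicted")


@dataclass(frozen=True)
class PhysicalConstants:
    """Boltzmann constant (CODATA), J K^-1."""
    k_B: float = K_B


@dataclass
class DiffusionEstimate:
    """A diffusion coefficient (1e-5 cm^2 s^-1) with its state point."""
    value: float
    temperature: float        # K
    viscosity: float          # mPa s
    kind: str = "D_0"
    uncertainty: Optional[float] = None

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError(f"diffusion coefficient must be > 0, got "
                             f"{self.value}")
        if self.temperature <= 0 or self.viscosity <= 0:
            raise ValueError("temperature and viscosity must be positive")
        if self.kind not in _ESTIMATE_KINDS:
            raise ValueError(f"kind must be one of {_ESTIMATE_KINDS}")


def stokes_radius(d: DiffusionEstimate) -> float:
    """Hydrodynamic radius in nm via the Stokes-Einstein relation."""
    return stokes_einstein_radius_nm(d.value, d.temperature, d.viscosity)


def stokes_einstein_D(r_h: float, temperature: float, eta: float,
                      kind: str = "predicted") -> DiffusionEstimate:
    """Diffusion coefficient for a hydrodynamic radius (exact inverse of
    :func:`stokes_radius`)."""
    if r_h <= 0 or temperature <= 0 or eta <= 0:
        raise ValueError("radius, temperature and viscosity must be positive")
    return DiffusionEstimate(stokes_einstein_d(r_h, temperature, eta),
                             temperature, eta, kind=kind)


def derive_coefficient(capped_d: DiffusionEstimate, capped_area: float,
                       ref_d: DiffusionEstimate, ref_area: float) -> float:
    """Unitless hydrodiffusivity coefficient from a capped solute and the
    NMA reference (both at the same state point)."""
    if (abs(capped_d.temperature - ref_d.temperature) > 1e-9
            or abs(capped_d.viscosity - ref_d.viscosity) > 1e-9):
        raise ValueError("capped and reference estimates must share one "
                         "temperature and viscosity")
    num = stokes_radius(capped_d) ** 2 - stokes_radius(ref_d) ** 2
    den = capped_area - ref_area
    if den <= 0:
        raise ValueError(f"capped area must exceed the reference area "
                         f"(difference {den:g} nm^2)")
    if num <= 0:
        raise ValueError(
            f"capped solute diffuses faster than the reference (Delta R^2 = "
            f"{num:g} nm^2); physically inconsistent input")
    return num / den


@dataclass
class HydroScale:
    """Per-residue hydrodiffusivity coefficients plus terminus parameters."""
    variant: str                          # "M" | "D"
    coefficients: Dict[str, float]        # AA3 -> C_i, unitless
    c_term_capped: float
    c_term_zwitterionic: float
    sesa_term: float                      # NMA reference area, nm^2
    radius_set_name: str
    temperature: float                    # K
    viscosity: float                      # mPa s

    def __post_init__(self):
        if self.variant not in ("M", "D"):
            raise ValueError("variant must be 'M' or 'D'")
        missing = set(STANDARD_AAS) - set(self.coefficients)
        if missing:
            raise ValueError(f"scale is missing residues: {sorted(missing)}")
        if any(c <= 0 for c in self.coefficients.values()):
            raise ValueError("all coefficients must be positive")
        if self.sesa_term <= 0:
            raise ValueError("SESA_term must be positive")

    def c_term(self, terminus_mode: str) -> float:
        if terminus_mode == "capped":
            return self.c_term_capped
        if terminus_mode == "zwitterionic":
            return self.c_term_zwitterionic
        raise ValueError(f"unknown terminus mode '{terminus_mode}'")

    # -- plain-text persistence ------------------------------------------

    def save(self, path) -> None:
        lines = [
            f"# variant={self.variant} temperature={self.temperature:g} "
            f"viscosity={self.viscosity:g} radii={self.radius_set_name}",
            "# AA\tC",
        ]
        for aa in STANDARD_AAS:
            lines.append(f"{aa}\t{self.coefficients[aa]:.6g}")
        lines.append(f"TERM_CAPPED\t{self.c_term_capped:.6g}")
        lines.append(f"TERM_ZWIT\t{self.c_term_zwitterionic:.6g}")
        lines.append(f"SESA_TERM\t{self.sesa_term:.6g}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path_or_text) -> "HydroScale":
        if isinstance(path_or_text, str) and "\n" in path_or_text:
            text = path_or_text
        else:
            text = Path(path_or_text).read_text()
        meta: Dict[str, str] = {}
        coeffs: Dict[str, float] = {}
        special: Dict[str, float] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        k, v = token.split("=", 1)
                        meta[k] = v
                continue
            key, value = line.split("\t")
            if key in ("TERM_CAPPED", "TERM_ZWIT", "SESA_TERM"):
                special[key] = float(value)
            else:
                coeffs[key] = float(value)
        return cls(variant=meta["variant"], coefficients=coeffs,
                   c_term_capped=special["TERM_CAPPED"],
                   c_term_zwitterionic=special["TERM_ZWIT"],
                   sesa_term=special["SESA_TERM"],
                   radius_set_name=meta.get("radii", ""),
                   temperature=float(meta["temperature"]),
                   viscosity=float(meta["viscosity"]))


def load_shipped_scale(variant: str = "M") -> HydroScale:
    """Load the shipped scale (variant ``"M"`` or ``"D"``)."""
    if variant not in ("M", "D"):
        raise ValueError("variant must be 'M' or 'D'")
    text = (importlib.resources.files("ride") / "data"
            / f"hydro_scale_{variant}.tsv").read_text()
    return HydroScale.load(text)


def load_peptide_table() -> Dict[str, Dict[str, float]]:
    """Shipped mono-/decapeptide D_0 and alpha table (MD inputs).

    Returns AA3 -> {d0_mono, d0_mono_err, alpha_mono, alpha_mono_err,
    d0_deca, d0_deca_err, alpha_deca, alpha_deca_err}.
    """
    text = (importlib.resources.files("ride") / "data"
            / PEPTIDE_TABLE_FILE).read_text()
    lines = [l for l in text.splitlines() if l and not l.startswith("#")]
    header = lines[0].split("\t")[1:]
    out: Dict[str, Dict[str, float]] = {}
    for line in lines[1:]:
        tokens = line.split("\t")
        out[tokens[0]] = {k: float(v) for k, v in zip(header, tokens[1:])}
    return out


def build_scale(d_table: Dict[str, DiffusionEstimate],
                nma_d: DiffusionEstimate,
                area_provider: Callable[..., object],
                variant: str = "M",
                radius_set_name: str = "",
                structure_provider: Optional[Callable[[str], object]] = None
                ) -> HydroScale:
    """Derive a full hydrodiffusivity scale.

    ``d_table`` maps each of the 20 residue types to its capped-peptide
    D_0 estimate (monopeptides for variant M, decapeptides for variant D),
    all at one state point shared with ``nma_d``.  ``area_provider`` maps a
    Structure to a SESAResult; ``structure_provider`` maps a 3-letter code
    to the capped conformer fixture (defaults to the extended monomer or
    ideal-helix decamer builders) and, for the code ``"NMA"``, to the NMA
    reference molecule.
    """
    from . import fixtures

    missing = set(STANDARD_AAS) - set(d_table)
    if missing:
        raise ValueError(f"d_table is missing residues: {sorted(missing)}")
    for aa, d in d_table.items():
        if (abs(d.temperature - nma_d.temperature) > 1e-9
                or abs(d.viscosity - nma_d.viscosity) > 1e-9):
            raise ValueError(f"{aa}: state point differs from the NMA "
                             f"reference")

    if structure_provider is None:
        from .constants import AA3_TO_1

        def structure_provider(code: str):
            if code == "NMA":
                return fixtures.build_nma()
            n_res = 1 if variant == "M" else 10
            conf = "extended" if variant == "M" else "alpha_helix"
            return fixtures.build_peptide(fixtures.PeptideSpec(
                sequence=AA3_TO_1[code] * n_res, conformation=conf,
                capped=True))

    nma_area = area_provider(structure_provider("NMA")).total
    r_nma_sq = stokes_radius(nma_d) ** 2

    coeffs: Dict[str, float] = {}
    for aa in STANDARD_AAS:
        capped_area = area_provider(structure_provider(aa)).total
        coeffs[aa] = derive_coefficient(d_table[aa], capped_area,
                                        nma_d, nma_area)
    return HydroScale(
        variant=variant,
        coefficients=coeffs,
        c_term_capped=r_nma_sq / nma_area,
        c_term_zwitterionic=0.5 * (coeffs["ASP"] + coeffs["LYS"]),
        sesa_term=nma_area,
        radius_set_name=radius_set_name,
        temperature=nma_d.temperature,
        viscosity=nma_d.viscosity,
    )


def assemble_hydrodynamic_radius(type_areas: Dict[str, float],
                                 scale: HydroScale,
                                 terminus_mode: str) -> float:
    """Assemble R_H,total (nm) from per-residue-type SES areas.

    ``type_areas`` must contain only standard residue types (absent types
    count as zero area); cap-group area must already have been folded into
    the terminus convention by the caller (see :mod:`ride.predictor`).
    """
    unknown = {k for k in type_areas if k not in STANDARD_AAS}
    if unknown:
        raise ValueError(
            f"type_areas contains non-standard keys {sorted(unknown)}; "
            f"cap areas must be handled before assembly")
    if any(a < 0 for a in type_areas.values()):
        raise ValueError("areas must be non-negative")
    r_sq = scale.c_term(terminus_mode) * scale.sesa_term
    for aa, area in type_areas.items():
        r_sq += scale.coefficients[aa] * area
    return math.sqrt(r_sq)
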