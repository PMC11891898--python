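"""End-to-end RIDE pipeline: structure -> per-type SESA -> R_H -> D_0.

The prediction composes per-residue-type area accumulation, additive
hydrodynamic-radius assembly and the Stokes-Einstein relation at the chosen
state point, with the NaCl molarity entering as a viscosity scaling and an
optional rescaling to experimental water viscosity.

Cap handling: the terminus term of the assembly stands in for an
NMA-equivalent patch of the molecular surface, so for ACE/NME-capped
structures the measured residue areas are rescaled so that their sum equals
(total SESA - SESA_term).  This keeps the assembly consistent with the way
the per-residue coefficients were derived (whole-molecule area minus the
NMA reference) and makes capped-monomer predictions reproduce the
derivation inputs exactly.  Zwitterionic structures carry no cap atoms; the
terminus constant is purely additive and measured areas are used as-is.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from .hydro_scale import (DiffusionEstimate, HydroScale,
                          assemble_hydrodynamic_radius, stokes_einstein_D)
from .sesa import (DEFAULT_RADIUS_SET, RADIUS_SETS, SESAParams, assign_radii,
                   compute_sesa)
from .structure_io import (CAP_KEY, AtomAreaTable, Structure,
                           accumulate_sesa_by_restype, detect_termini,
                           molecular_weight, read_pdb)
from .viscosity import (SaltModel, eta_at, load_viscosity_table,
                        rescale_to_experiment, salt_adjusted_eta)

logger = logging.getLogger(__name__)


@dataclass
class RidePrediction:
    """A RIDE result: D_0 (and optional D_eta), the assembled radius, and
    the per-type areas and conditions that produced them."""
    d0: DiffusionEstimate
    r_h_total: float                       # nm
    type_areas: Dict[str, float]           # nm^2, as used in the assembly
    scale_variant: str
    terminus_mode: str
    temperature: float
    eta_sim: float
    eta_exp: Optional[float] = None
    salt_molarity: float = 0.0
    d_eta: Optional[DiffusionEstimate] = None
    area_source: str = "internal"
    label: str = ""


def _resolve_viscosity(scale: HydroScale, temperature: float,
                       eta_override: Optional[float],
                       allow_condition_mismatch: bool) -> float:
    if eta_override is not None:
        return eta_override
    if abs(temperature - scale.temperature) < 1e-6:
        return scale.viscosity
    if not allow_condition_mismatch:
        raise ValueError(
            f"requested temperature {temperature} K differs from the "
            f"scale's derivation temperature {scale.temperature} K; pass "
            f"allow_condition_mismatch=True (uses the TIP3P table) or an "
            f"explicit eta_override")
    warnings.warn("temperature differs from the scale state point; using "
                  "the TIP3P viscosity table", stacklevel=3)
    return eta_at(load_viscosity_table("TIP3P"), temperature)


def predict(s: Structure, areas: Optional[AtomAreaTable],
            scale: HydroScale, temperature: Optional[float] = None,
            salt_molarity: float = 0.0, rescale: bool = False,
            eta_override: Optional[float] = None,
            allow_condition_mismatch: bool = False,
            sesa_params: SESAParams = SESAParams(),
            salt_model: SaltModel = SaltModel()) -> RidePrediction:
    """Predict the infinitely dilute diffusion coefficient of a structure.

    When ``areas`` is None the solvent-excluded areas are computed
    internally with the scale's radius set; an externally supplied
    (MSMS-style) area table wins over internal computation.  ``rescale``
    additionally reports D_eta against the experimental water viscosity.
    """
    if temperature is None:
        temperature = scale.temperature
    if salt_molarity < 0:
        raise ValueError("salt molarity must be >= 0")

    if areas is None:
        radius_set = RADIUS_SETS.get(scale.radius_set_name,
                                     DEFAULT_RADIUS_SET)
        assign_radii(s, radius_set)
        areas = compute_sesa(s, sesa_params, radius_set.name).as_area_table()

    mode = detect_termini(s)
    per_type = accumulate_sesa_by_restype(s, areas)
    cap_area = per_type.pop(CAP_KEY)
    type_areas = {aa: a for aa, a in per_type.items() if a > 0}

    if mode == "capped":
        total = cap_area + sum(type_areas.values())
        target = total - scale.sesa_term
        measured = sum(type_areas.values())
        if measured > 0:
            if target <= 0:
                raise ValueError(
                    f"structure SESA ({total:.3f} nm^2) does not exceed the "
                    f"terminus reference area ({scale.sesa_term:.3f} nm^2)")
            factor = target / measured
            type_areas = {aa: a * factor for aa, a in type_areas.items()}
    elif cap_area > 0:
        warnings.warn("cap atoms present in a zwitterionic-mode structure; "
                      "their area is not assigned to any residue type",
                      stacklevel=2)

    r_h = assemble_hydrodynamic_radius(type_areas, scale, mode)
    eta_sim = salt_adjusted_eta(
        _resolve_viscosity(scale, temperature, eta_override,
                           allow_condition_mismatch),
        salt_molarity, salt_model)
    d0 = stokes_einstein_D(r_h, temperature, eta_sim, kind="predicted")

    pred = RidePrediction(
        d0=d0, r_h_total=r_h, type_areas=type_areas,
        scale_variant=scale.variant, terminus_mode=mode,
        temperature=temperature, eta_sim=eta_sim,
        salt_molarity=salt_molarity, area_source=areas.source,
        label=s.label)
    if rescale:
        eta_exp = salt_adjusted_eta(
            eta_at(load_viscosity_table("experimental"), temperature),
            salt_molarity, salt_model)
        pred.eta_exp = eta_exp
        pred.d_eta = rescale_to_experiment(d0, eta_sim, eta_exp)
    return pred


def predict_batch(paths: Sequence, scale: HydroScale, **options):
    """Predict every PDB path; per-row failures are reported, not fatal.

    Returns a pandas DataFrame with one row per input (columns: path, D_0,
    R_H_nm, terminus, error).  Raises only if every row failed.
    """
    import pandas as pd

    rows: List[dict] = []
    n_failed = 0
    for path in paths:
        row = {"path": str(path), "D_0": None, "D_eta": None,
               "R_H_nm": None, "terminus": None, "error": None}
        try:
            s = read_pdb(path)
            pred = predict(s, None, scale, **options)
            row.update(D_0=pred.d0.value, R_H_nm=pred.r_h_total,
                       terminus=pred.terminus_mode,
                       D_eta=pred.d_eta.value if pred.d_eta else None)
        except Exception as exc:
            row["error"] = str(exc)
            n_failed += 1
            logger.warning("prediction failed for %s: %s", path, exc)
        rows.append(row)
    if rows and n_failed == len(rows):
        raise RuntimeError("all batch predictions failed")
    return pd.DataFrame(rows)


def compare_methods(s: Structure, scale: HydroScale, cal=None,
                    simulation_d0: Optional[float] = None,
                    **options) -> Dict[str, dict]:
    """Side-by-side RIDE and Polson mass-relation predictions.

    The Polson column is the pure-water 293.15 K baseline corrected to the
    requested state point with the literal temperature/viscosity ratios;
    its metadata keeps the applied ratios visible.  Differences are signed
    (RIDE - Polson) and in percent of the Polson value; a user-supplied
    simulation D_0 joins the report when given.
    """
    from . import mass_relation

    if cal is None:
        cal = mass_relation.DEFAULT_CALIBRATION
    pred = predict(s, None, scale, **options)
    mass = molecular_weight(s)
    d_polson_base = mass_relation.predict_D(mass, cal)
    eta_exp_293 = eta_at(load_viscosity_table("experimental"), 293.15)
    d_polson, meta = mass_relation.correct_to_state(
        d_polson_base, pred.temperature, pred.eta_sim, eta_exp_293)

    report = {
        "RIDE": {"D_0": pred.d0.value, "R_H_nm": pred.r_h_total,
                 "scale_variant": pred.scale_variant},
        "Polson": {"D_0": d_polson, "D_base_293K": d_polson_base,
                   "mass_kg_mol": mass, **meta},
        "difference": {
            "signed": pred.d0.value - d_polson,
            "percent": 100.0 * (pred.d0.value - d_polson) / d_polson,
        },
    }
    if simulation_d0 is not None:
        report["simulation"] = {"D_0": simulation_d0}
        report["difference"]["RIDE_vs_simulation_percent"] = (
            100.0 * (pred.d0.value - simulation_d0) / simulation_d0)
    return report
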