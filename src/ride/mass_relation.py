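"""Polson-style mass-relation baseline: D = A / M^(1/3).

The cube-root law links molar mass to the diffusion coefficient through the
molecular volume, calibrated on a single reference protein.  The shipped
default calibration derives from the Arc-repressor row of the published
comparison (M = 6.14 kg/mol, D = 0.150e-5 cm^2/s in pure water at
293.15 K) because the original hemoglobin-derived prefactor is not printed;
callers may supply a literature hemoglobin calibration instead.

``correct_to_state`` applies the literal temperature/viscosity composition
D * (T/293.15) / (eta_target/eta_exp_293).  Which experimental viscosity
belongs in the ratio is ambiguous in the source description, so the applied
ratios are returned alongside the value rather than resolved by guessing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

from .constants import T_POLSON_REF


@dataclass(frozen=True)
class MassRelationCalibration:
    """Prefactor A (1e-5 cm^2 s^-1 (kg/mol)^(1/3)) and its provenance."""
    prefactor: float
    reference_mass: float       # kg mol^-1
    reference_d: float          # 1e-5 cm^2 s^-1
    base_temperature: float = T_POLSON_REF

    def __post_init__(self):
        if self.prefactor <= 0:
            raise ValueError("prefactor must be positive")
        expected = self.reference_d * self.reference_mass ** (1.0 / 3.0)
        if abs(self.prefactor - expected) > 1e-9 * expected:
            raise ValueError("prefactor inconsistent with its reference pair")


def calibrate(reference_mass: float, reference_d: float
              ) -> MassRelationCalibration:
    """Calibration from one (M, D) reference pair: A = D * M^(1/3)."""
    if reference_mass <= 0 or reference_d <= 0:
        raise ValueError("reference mass and D must be positive")
    return MassRelationCalibration(
        prefactor=reference_d * reference_mass ** (1.0 / 3.0),
        reference_mass=reference_mass, reference_d=reference_d)


#: default calibration: Arc-repressor reference (pure water, 293.15 K)
DEFAULT_CALIBRATION = calibrate(6.14, 0.150)


def predict_D(mass: float,
              cal: MassRelationCalibration = DEFAULT_CALIBRATION) -> float:
    """D in 1e-5 cm^2 s^-1 for a molar mass in kg mol^-1."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    return cal.prefactor / mass ** (1.0 / 3.0)


def correct_to_state(d_base: float, temperature: float, eta_target: float,
                     eta_exp_293: float
                     ) -> Tuple[float, Dict[str, float]]:
    """Scale a 293.15 K pure-water prediction to a target state point.

    Returns (D, metadata); metadata records the applied T and viscosity
    ratios so the ambiguous ratio composition stays visible to the caller.
    """
    if min(d_base, temperature, eta_target, eta_exp_293) <= 0:
        raise ValueError("all inputs must be positive")
    t_ratio = temperature / T_POLSON_REF
    eta_ratio = eta_target / eta_exp_293
    return d_base * t_ratio / eta_ratio, {
        "T_ratio": t_ratio, "eta_ratio": eta_ratio,
        "eta_target": eta_target, "eta_exp_293": eta_exp_293,
    }
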