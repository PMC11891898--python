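"""Solvent viscosity models.

Temperature tables for simulated TIP3P water and experimental water are
shipped as package data (MD/experimental inputs, not recomputed here) and
interpolated linearly — the tabulated trend over the 5 K spacing is close to
linear.  A linear NaCl relative-viscosity law converts salt molarity into a
viscosity scaling, and a periodic-perturbation estimator recovers shear
viscosity from a steady-state cosine velocity-response profile.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

VISC_TABLE_FILE = "table_viscosity_vs_temperature.tsv"

#: allowed linear extrapolation beyond the table range, K
EXTRAPOLATION_K = 2.5


@dataclass(frozen=True)
class ViscosityTable:
    """Ordered (T, eta) nodes for one solvent model."""
    label: str
    temperatures: np.ndarray  # K, strictly increasing
    viscosities: np.ndarray   # mPa s

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        e = np.asarray(self.viscosities, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "viscosities", e)
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(e <= 0):
            raise ValueError("viscosities must be positive")


def load_viscosity_table(label: str = "TIP3P") -> ViscosityTable:
    """Load a shipped viscosity table: ``"TIP3P"`` or ``"experimental"``."""
    col = {"TIP3P": 1, "experimental": 3}
    if label not in col:
        raise ValueError(f"unknown viscosity table '{label}'")
    text = (importlib.resources.files("ride") / "data"
            / VISC_TABLE_FILE).read_text()
    rows = [line.split("\t") for line in text.splitlines()
            if line and not line.startswith("#")]
    data = np.array(rows[1:], dtype=float)
    return ViscosityTable(label, data[:, 0], data[:, col[label]])


def eta_at(table: ViscosityTable, temperature: float) -> float:
    """Viscosity (mPa s) at ``temperature`` by piecewise-linear interpolation.

    Exact at nodes; up to 2.5 K of linear extrapolation is allowed with a
    warning, beyond that an error is raised.
    """
    t, e = table.temperatures, table.viscosities
    if temperature < t[0] - EXTRAPOLATION_K or temperature > t[-1] + EXTRAPOLATION_K:
        raise ValueError(
            f"temperature {temperature} K far outside the {table.label} "
            f"table range [{t[0]}, {t[-1]}] K")
    if temperature < t[0] or temperature > t[-1]:
        warnings.warn(f"extrapolating the {table.label} viscosity table to "
                      f"{temperature} K", stacklevel=2)
        i = 0 if temperature < t[0] else -2
        slope = (e[i + 1] - e[i]) / (t[i + 1] - t[i])
        return float(e[i] + slope * (temperature - t[i]))
    return float(np.interp(temperature, t, e))


# ---------------------------------------------------------------------------
# salt model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SaltModel:
    """Linear NaCl relative-viscosity law eta(c)/eta(0) = 1 + slope * c.

    The default slope is a least-squares fit to standard experimental
    relative viscosities of aqueous NaCl at 293.15 K; the simulated salt
    trend tracks experiment up to about 1 M, the stated validity limit.
    """
    slope: float = 0.094        # L mol^-1
    validity_limit: float = 1.0  # mol L^-1

    def relative_viscosity(self, molarity: float) -> float:
        if molarity < 0:
            raise ValueError("salt molarity must be >= 0")
        return 1.0 + self.slope * molarity


def salt_adjusted_eta(eta0: float, molarity: float,
                      model: SaltModel = SaltModel()) -> float:
    """Scale a salt-free viscosity (mPa s) to the given NaCl molarity."""
    if molarity > model.validity_limit:
        warnings.warn(
            f"salt concentration {molarity} M exceeds the model validity "
            f"limit of {model.validity_limit} M", stacklevel=2)
    return eta0 * model.relative_viscosity(molarity)


# ---------------------------------------------------------------------------
# simulation -> experiment rescaling
# ---------------------------------------------------------------------------


def rescale_to_experiment(d, eta_sim: float, eta_exp: float):
    """Rescale a simulation D by eta_sim/eta_exp for comparison to experiment.

    Returns a new :class:`~ride.hydro_scale.DiffusionEstimate` of kind
    ``D_eta`` carrying the experimental viscosity.
    """
    if eta_sim <= 0 or eta_exp <= 0:
        raise ValueError("viscosities must be positive")
    return replace(d, value=d.value * eta_sim / eta_exp, kind="D_eta",
                   viscosity=eta_exp,
                   uncertainty=(None if d.uncertainty is None
                                else d.uncertainty * eta_sim / eta_exp))


# ---------------------------------------------------------------------------
# periodic-perturbation viscosity estimator
# ---------------------------------------------------------------------------


@dataclass
class PerturbationProfile:
    """Steady-state velocity response to a cosine acceleration profile.

    ``z`` positions in nm within [0, L_z); ``v_x`` velocity samples in
    nm ps^-1; ``acceleration`` amplitude A in nm ps^-2; ``density`` in
    kg m^-3; ``box_height`` L_z in nm.
    """
    z: np.ndarray
    v_x: np.ndarray
    acceleration: float
    density: float
    box_height: float

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.v_x = np.asarray(self.v_x, dtype=float)
        if self.acceleration <= 0 or self.density <= 0 or self.box_height <= 0:
            raise ValueError("acceleration, density and box height must be "
                             "positive")
        if np.any(self.z < 0) or np.any(self.z >= self.box_height):
            raise ValueError("z positions must lie in [0, box_height)")


def viscosity_from_profile(profile: PerturbationProfile) -> float:
    """Shear viscosity (mPa s) from a periodic-perturbation profile.

    Fits v_x(z) = offset + V cos(2 pi z / L_z) by least squares (the constant
    offset absorbs any drift) and inverts eta = A rho / (V k^2) with
    k = 2 pi / L_z.  A non-positive fitted amplitude signals a non-converged
    or garbage profile and raises.
    """
    if len(profile.z) < 8:
        raise ValueError("need at least 8 z-bins spanning one period")
    k = 2.0 * np.pi / profile.box_height  # nm^-1
    design = np.column_stack([np.ones_like(profile.z),
                              np.cos(k * profile.z)])
    (offset, amplitude), *_ = np.linalg.lstsq(design, profile.v_x, rcond=None)
    if amplitude <= 0:
        raise ValueError(f"fitted response amplitude {amplitude:g} <= 0; "
                         f"profile does not match the imposed perturbation")
    # A[nm/ps^2] rho[kg/m^3] / (V[nm/ps] k^2[nm^-2]) = 1e-6 Pa s
    eta_pa_s = profile.acceleration * profile.density / (amplitude * k * k) * 1e-6
    return eta_pa_s * 1e3  # mPa s


def make_perturbation_profile(eta_mpas: float, box_height: float = 3.0,
                              acceleration: float = 0.005,
                              density: float = 1000.0, n_bins: int = 64,
                              noise_sd: float = 0.0,
                              seed: Optional[int] = None
                              ) -> PerturbationProfile:
    """Synthesize the steady-state profile a fluid of given viscosity yields.

    The generating formula is the exact inverse of
    :func:`viscosity_from_profile`; optional Gaussian noise (relative to the
    amplitude) exercises the estimator's robustness.
    """
    k = 2.0 * np.pi / box_height
    amplitude = acceleration * density / (k * k * eta_mpas * 1e-3) * 1e-6
    z = (np.arange(n_bins) + 0.5) * box_height / n_bins
    v = amplitude * np.cos(k * z)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd * amplitude, size=n_bins)
    return PerturbationProfile(z, v, acceleration, density, box_height)
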