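"""Trajectory-based diffusion: MSD, finite-size model and extrapolation.

An apparent diffusion coefficient D_app measured in a periodic cubic cell of
edge L is depressed below the infinitely dilute D_0 by the hydrodynamic
self-interaction of the solute with its images,

    D_app(L) = D_0 - alpha * k_B T xi_EW / (6 pi eta L),

where xi_EW ~ 2.837298 is the simple-cubic lattice self term (recomputed
here by Ewald summation) and alpha an empirical, solute-dependent scale
factor.  D_app itself comes from the slope of the mean-square displacement
over a short-time window; fitting D_app against 1/L across several box sizes
recovers (D_0, alpha), while the single-box correction adds the 1/L term
back for a caller-supplied alpha — alpha is never guessed silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .constants import D_UNIT, ETA_UNIT, K_B, NM, XI_EW

#: conversion from nm^2/ps to 1e-5 cm^2/s
_NM2_PS_TO_D = 1.0e3


@dataclass
class Trajectory:
    """Uniformly sampled, unwrapped particle positions (nm) vs time (ps)."""
    times: np.ndarray
    positions: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.times) < 2:
            raise ValueError("trajectory needs at least 2 frames")
        if self.positions.shape != (len(self.times), 3):
            raise ValueError("positions must be (n_frames, 3)")
        dts = np.diff(self.times)
        if np.any(dts <= 0) or np.ptp(dts) > 1e-9:
            raise ValueError("times must be uniform and strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def unwrap_trajectory(positions: np.ndarray, box_lengths) -> np.ndarray:
    """Undo periodic jumps in wrapped coordinates (orthorhombic box).

    Minimum-image jump repair: any frame-to-frame displacement component
    larger than half the box is shifted by a box length.
    """
    pos = np.asarray(positions, dtype=float)
    box = np.broadcast_to(np.asarray(box_lengths, dtype=float), (3,))
    deltas = np.diff(pos, axis=0)
    deltas -= box * np.round(deltas / box)
    return np.vstack([pos[:1], pos[:1] + np.cumsum(deltas, axis=0)])


@dataclass
class MSDCurve:
    """Mean-square displacement vs lag, with per-lag origin counts."""
    lags: np.ndarray       # ps
    msd: np.ndarray        # nm^2
    n_origins: np.ndarray
    dims: int

    def __post_init__(self):
        if self.msd[0] != 0.0:
            raise ValueError("msd at zero lag must be 0")


def compute_msd(traj: Trajectory, dims: int = 3,
                max_lag: Optional[float] = None,
                axes: Optional[Sequence[int]] = None) -> MSDCurve:
    """Multiple-time-origin MSD of a trajectory.

    For each lag tau, |r(t+tau) - r(t)|^2 is averaged over every valid
    origin t, using the first ``dims`` coordinate axes (or an explicit
    ``axes`` selection).
    """
    if axes is None:
        if dims not in (1, 2, 3):
            raise ValueError("dims must be 1, 2 or 3")
        axes = tuple(range(dims))
    else:
        axes = tuple(axes)
        dims = len(axes)
    n = len(traj.times)
    dt = traj.dt
    if max_lag is None:
        max_lag = (n - 1) * dt
    if max_lag >= n * dt:
        raise ValueError("max_lag must be below the trajectory duration")
    n_lags = int(math.floor(max_lag / dt)) + 1
    pos = traj.positions[:, axes]
    msd = np.empty(n_lags)
    counts = np.empty(n_lags, dtype=int)
    msd[0], counts[0] = 0.0, n
    for k in range(1, n_lags):
        disp = pos[k:] - pos[:-k]
        msd[k] = np.mean(np.einsum("ij,ij->i", disp, disp))
        counts[k] = n - k
    return MSDCurve(np.arange(n_lags) * dt, msd, counts, dims)


def average_msd(curves: Sequence[MSDCurve]) -> MSDCurve:
    """Average MSD curves from independent trajectories of one system.

    This mirrors the usual simulation protocol of averaging several
    independent single-particle traces before the window fit; all curves
    must share lags and dimensionality.
    """
    if not curves:
        raise ValueError("need at least one curve")
    first = curves[0]
    for c in curves[1:]:
        if c.dims != first.dims or len(c.lags) != len(first.lags) \
                or np.ptp(c.lags - first.lags) > 1e-9:
            raise ValueError("curves must share lags and dims")
    return MSDCurve(first.lags.copy(),
                    np.mean([c.msd for c in curves], axis=0),
                    np.sum([c.n_origins for c in curves], axis=0),
                    first.dims)


def fit_dapp(curve: MSDCurve, window: Tuple[float, float],
             temperature: float = 310.15, viscosity: float = 0.275):
    """Apparent diffusion coefficient from the linear MSD regime.

    Least-squares slope of MSD vs lag on ``window`` (ps); D = slope/(2 d),
    returned in 1e-5 cm^2 s^-1 with the slope's standard error propagated.
    ``temperature``/``viscosity`` annotate the estimate for downstream
    finite-size corrections.
    """
    from .hydro_scale import DiffusionEstimate

    lo, hi = window
    mask = (curve.lags >= lo) & (curve.lags <= hi)
    if mask.sum() < 3:
        raise ValueError(f"fit window [{lo}, {hi}] ps holds fewer than 3 "
                         f"MSD points")
    x, y = curve.lags[mask], curve.msd[mask]
    design = np.column_stack([np.ones_like(x), x])
    coef, residuals, *_ = np.linalg.lstsq(design, y, rcond=None)
    slope = coef[1]
    dof = len(x) - 2
    if dof > 0 and len(residuals):
        s2 = residuals[0] / dof
        cov = s2 * np.linalg.inv(design.T @ design)
        slope_se = math.sqrt(cov[1, 1])
    else:
        slope_se = 0.0
    denom = 2.0 * curve.dims
    return DiffusionEstimate(
        value=slope / denom * _NM2_PS_TO_D,
        uncertainty=slope_se / denom * _NM2_PS_TO_D,
        temperature=temperature, viscosity=viscosity, kind="D_app")


# ---------------------------------------------------------------------------
# finite-size model
# ---------------------------------------------------------------------------


def _correction_term(temperature: float, eta: float, box_length: float
                     ) -> float:
    """k_B T xi_EW / (6 pi eta L) in 1e-5 cm^2 s^-1."""
    return (K_B * temperature * XI_EW
            / (6.0 * math.pi * eta * ETA_UNIT * box_length * NM)) / D_UNIT


def finite_size_D(d0: float, box_length: float, temperature: float,
                  eta: float, alpha: float) -> float:
    """Apparent D in a cubic periodic cell of edge ``box_length`` (nm)."""
    if min(d0, box_length, temperature, eta) <= 0:
        raise ValueError("all inputs must be positive")
    d_app = d0 - alpha * _correction_term(temperature, eta, box_length)
    if d_app <= 0:
        raise ValueError(
            f"finite-size correction exceeds D_0 (D_app = {d_app:g}); "
            f"unphysical regime")
    return d_app


@dataclass
class FiniteSizeSeries:
    """(L, D_app) pairs at one state point, with the fit once performed."""
    box_lengths: np.ndarray          # nm
    d_app: np.ndarray                # 1e-5 cm^2/s
    uncertainties: Optional[np.ndarray]
    temperature: float
    viscosity: float
    fit: Optional[dict] = None       # keys: d0, alpha, d0_se, alpha_se

    def __post_init__(self):
        self.box_lengths = np.asarray(self.box_lengths, dtype=float)
        self.d_app = np.asarray(self.d_app, dtype=float)
        if self.uncertainties is not None:
            self.uncertainties = np.asarray(self.uncertainties, dtype=float)
        if np.any(self.box_lengths <= 0):
            raise ValueError("box lengths must be positive")
        if len(np.unique(self.box_lengths)) != len(self.box_lengths):
            raise ValueError("box lengths must be distinct")


def extrapolate_D0(series: FiniteSizeSeries) -> Tuple[float, float]:
    """Fit D_app vs 1/L; returns (D_0, alpha) and stores errors in ``fit``.

    Inverse-variance weighting is used when the series carries
    uncertainties, ordinary least squares otherwise.  The intercept is D_0;
    alpha follows from the slope via the periodic correction coefficient.
    """
    L = series.box_lengths
    if len(L) < 2:
        raise ValueError("need at least 2 box lengths to extrapolate")
    x = 1.0 / L
    y = series.d_app
    design = np.column_stack([np.ones_like(x), x])
    if series.uncertainties is not None:
        if np.any(series.uncertainties <= 0):
            raise ValueError("uncertainties must be positive")
        w = 1.0 / series.uncertainties ** 2
        xtwx = design.T @ (design * w[:, None])
        coef = np.linalg.solve(xtwx, design.T @ (w * y))
        cov = np.linalg.inv(xtwx)  # known variances: no residual scaling
    else:
        coef, residuals, *_ = np.linalg.lstsq(design, y, rcond=None)
        dof = len(x) - 2
        s2 = (residuals[0] / dof) if (dof > 0 and len(residuals)) else 0.0
        cov = s2 * np.linalg.inv(design.T @ design)
    d0, slope = float(coef[0]), float(coef[1])
    if d0 <= 0:
        raise ValueError(f"fitted D_0 = {d0:g} <= 0")
    # slope [1e-5 cm^2/s * nm] = -alpha k_B T xi / (6 pi eta)
    scale = -(K_B * series.temperature * XI_EW
              / (6.0 * math.pi * series.viscosity * ETA_UNIT)) / (D_UNIT * NM)
    alpha = slope / scale
    d0_se = float(np.sqrt(cov[0, 0]))
    alpha_se = float(np.sqrt(cov[1, 1]) / abs(scale))
    series.fit = {"d0": d0, "alpha": alpha, "d0_se": d0_se,
                  "alpha_se": alpha_se}
    return d0, alpha


def yeh_hummer_correct(d, box_length: float, alpha: float):
    """Single-box finite-size correction D_0 = D_app + alpha*kT*xi/(6 pi eta L).

    ``alpha`` must be supplied explicitly (for example the decapeptide
    average 0.86); it is solute-dependent and not guessed.
    """
    from dataclasses import replace
    if alpha <= 0 or box_length <= 0:
        raise ValueError("alpha and box length must be positive")
    corr = alpha * _correction_term(d.temperature, d.viscosity, box_length)
    return replace(d, value=d.value + corr, kind="D_0")


# ---------------------------------------------------------------------------
# Ewald cubic-lattice self term
# ---------------------------------------------------------------------------


def _xi_partial(kappa: float, n_real: int, n_recip: int) -> float:
    g = np.arange(-n_real, n_real + 1)
    nx, ny, nz = np.meshgrid(g, g, g, indexing="ij")
    n2 = (nx * nx + ny * ny + nz * nz).astype(float)
    n2[n_real, n_real, n_real] = np.inf
    r = np.sqrt(n2)
    from scipy.special import erfc
    real = float(np.sum(erfc(kappa * r) / r))

    g = np.arange(-n_recip, n_recip + 1)
    mx, my, mz = np.meshgrid(g, g, g, indexing="ij")
    m2 = (mx * mx + my * my + mz * mz).astype(float)
    m2[n_recip, n_recip, n_recip] = np.inf
    recip = float(np.sum(np.exp(-math.pi ** 2 * m2 / kappa ** 2) / m2)) / math.pi

    return 2.0 * kappa / math.sqrt(math.pi) + math.pi / kappa ** 2 - real - recip


def compute_xi_ew(rel_tol: float = 1e-9) -> float:
    """Simple-cubic lattice self term by Ewald summation.

    Real-space erfc sum + reciprocal Gaussian sum + self/background terms,
    with cutoffs grown until the value is stable to ``rel_tol`` and verified
    invariant to the splitting parameter.
    """
    if rel_tol < 1e-9:
        raise ValueError("rel_tol must be >= 1e-9")
    kappa = math.sqrt(math.pi)
    prev = None
    for cut in range(3, 12):
        val = _xi_partial(kappa, cut, cut)
        if prev is not None and abs(val - prev) <= rel_tol * abs(val):
            alt = _xi_partial(kappa * 1.3, cut + 2, cut + 2)
            if abs(alt - val) > 10.0 * rel_tol * abs(val):
                raise RuntimeError(
                    f"Ewald splitting-parameter invariance violated: "
                    f"{val!r} vs {alt!r}")
            return val
        prev = val
    raise RuntimeError(f"xi_EW did not converge to rel_tol={rel_tol}")
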