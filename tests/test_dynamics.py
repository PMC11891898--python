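"""MSD analysis, the finite-size model and the Ewald lattice constant."""

import math

import numpy as np
import pytest

from ride.dynamics import (FiniteSizeSeries, Trajectory, compute_msd,
                           compute_xi_ew, extrapolate_D0, finite_size_D,
                           fit_dapp, unwrap_trajectory, yeh_hummer_correct,
                           _xi_partial)
from ride.fixtures import gen_brownian_trajectory, gen_finite_size_series
from ride.hydro_scale import DiffusionEstimate


class TestComputeMSD:
    def test_stationary_particle_zero(self):
        traj = gen_brownian_trajectory(0.0, 100, 3.0, seed=1)
        curve = compute_msd(traj, max_lag=150.0)
        assert np.all(curve.msd == 0.0)

    def test_ballistic_closed_form(self):
        times = np.arange(200) * 2.0
        v = np.array([0.1, 0.0, 0.0])
        traj = Trajectory(times, np.outer(times, v))
        curve = compute_msd(traj, max_lag=100.0)
        np.testing.assert_allclose(curve.msd, 0.01 * curve.lags ** 2,
                                   rtol=1e-10, atol=1e-12)

    def test_brownian_matches_6dt_within_three_standard_errors(self):
        """Seeded Brownian fixture: MSD ~ 6 D tau at 10 lags, each within
        3 standard errors estimated from non-overlapping origins."""
        d = 1.0  # nm^2/ns
        dt = 3.0
        traj = gen_brownian_trajectory(d, 40000, dt, seed=42)
        curve = compute_msd(traj, max_lag=3000.0)
        pos = traj.positions
        for lag_idx in np.linspace(10, 1000, 10, dtype=int):
            tau = lag_idx * dt
            expected = 6.0 * d * tau / 1000.0
            strided = pos[::lag_idx]
            disp = strided[1:] - strided[:-1]
            sq = np.einsum("ij,ij->i", disp, disp)
            sem = sq.std(ddof=1) / math.sqrt(len(sq))
            assert abs(curve.msd[lag_idx] - expected) < 3.0 * sem

    def test_axis_decomposition(self):
        traj = gen_brownian_trajectory(0.8, 2000, 3.0, seed=3)
        full = compute_msd(traj, dims=3, max_lag=300.0)
        parts = [compute_msd(traj, axes=(k,), max_lag=300.0) for k in range(3)]
        np.testing.assert_allclose(full.msd, sum(p.msd for p in parts),
                                   rtol=1e-12, atol=1e-14)

    def test_invalid_dims_rejected(self):
        traj = gen_brownian_trajectory(1.0, 50, 3.0, seed=1)
        with pytest.raises(ValueError):
            compute_msd(traj, dims=4, max_lag=30.0)

    def test_max_lag_beyond_duration_rejected(self):
        traj = gen_brownian_trajectory(1.0, 50, 3.0, seed=1)
        with pytest.raises(ValueError):
            compute_msd(traj, max_lag=1e6)


class TestFitDapp:
    def test_exact_line(self):
        lags = np.arange(0, 101, dtype=float)
        curve = compute_msd(  # build a curve container via a real call
            gen_brownian_trajectory(0.1, 100, 1.0, seed=0), max_lag=100.0)
        curve.msd = 6.0 * 2.0e-3 * curve.lags  # D = 2.0 in 1e-5 cm^2/s
        d = fit_dapp(curve, (10.0, 90.0))
        assert d.value == pytest.approx(2.0, rel=1e-12)
        assert d.kind == "D_app"

    def test_dimension_normalization(self):
        traj = gen_brownian_trajectory(0.5, 500, 1.0, seed=5)
        curve = compute_msd(traj, dims=2, max_lag=200.0)
        curve.msd = 4.0 * 1.5e-3 * curve.lags
        assert fit_dapp(curve, (10.0, 150.0)).value == pytest.approx(
            1.5, rel=1e-12)

    def test_brownian_fixture_within_ten_percent(self):
        """Ten averaged 100 ns traces at 3 ps sampling, window 30-3000 ps:
        the fitted D_app is within 10% of the input 1.0 nm^2/ns."""
        from ride.dynamics import average_msd
        curves = [compute_msd(gen_brownian_trajectory(1.0, 33333, 3.0,
                                                      seed=100 + seed),
                              max_lag=3000.0) for seed in range(10)]
        d = fit_dapp(average_msd(curves), (30.0, 3000.0))
        assert d.value == pytest.approx(1.0, rel=0.10)

    def test_unbiased_over_seeds(self):
        """The window fit is unbiased: over 300 seeds of a 10 ns Brownian
        fixture the mean estimate sits within 3 s.e.m. of the truth (the
        single-trace estimator itself has ~20% spread)."""
        values = []
        for seed in range(300):
            traj = gen_brownian_trajectory(1.0, 3333, 3.0, seed=seed)
            curve = compute_msd(traj, max_lag=1000.0)
            values.append(fit_dapp(curve, (30.0, 1000.0)).value)
        values = np.array(values)
        sem = values.std(ddof=1) / math.sqrt(len(values))
        assert abs(values.mean() - 1.0) < 3.0 * sem

    def test_empty_window_rejected(self):
        traj = gen_brownian_trajectory(1.0, 100, 3.0, seed=1)
        curve = compute_msd(traj, max_lag=100.0)
        with pytest.raises(ValueError):
            fit_dapp(curve, (400.0, 500.0))


class TestFiniteSizeModel:
    def test_alpha_zero_identity(self):
        assert finite_size_D(1.2, 5.0, 310.15, 0.275, 0.0) == 1.2

    def test_large_box_limit(self):
        assert finite_size_D(1.2, 1e12, 310.15, 0.275, 0.86) == \
            pytest.approx(1.2, rel=1e-9)

    def test_noiseless_round_trip(self):
        series = gen_finite_size_series(1.20, 0.86, 310.15, 0.275,
                                        [5.0, 5.5, 6.0, 6.5, 7.0])
        d0, alpha = extrapolate_D0(series)
        assert d0 == pytest.approx(1.20, rel=1e-9)
        assert alpha == pytest.approx(0.86, rel=1e-9)

    def test_constant_series_gives_zero_alpha(self):
        series = FiniteSizeSeries(np.array([5.0, 6.0, 7.0]),
                                  np.array([1.1, 1.1, 1.1]), None,
                                  310.15, 0.275)
        d0, alpha = extrapolate_D0(series)
        assert d0 == pytest.approx(1.1, rel=1e-12)
        assert alpha == pytest.approx(0.0, abs=1e-12)

    def test_unphysical_regime_rejected(self):
        with pytest.raises(ValueError, match="unphysical"):
            finite_size_D(0.01, 3.0, 310.15, 0.275, 1.0)

    def test_single_point_unfittable(self):
        series = gen_finite_size_series(1.2, 0.86, 310.15, 0.275, [5.0])
        with pytest.raises(ValueError):
            extrapolate_D0(series)

    def test_coverage_of_two_se_intervals(self):
        """Seeded Gaussian noise (sd 0.02): 2-s.e. intervals cover the true
        (D_0, alpha) about 95% of the time over 200 seeds."""
        hits_d0 = hits_alpha = 0
        n_seeds = 200
        for seed in range(n_seeds):
            series = gen_finite_size_series(
                1.20, 0.86, 310.15, 0.275, [5.0, 5.5, 6.0, 6.5, 7.0],
                noise_sd=0.02, seed=seed)
            d0, alpha = extrapolate_D0(series)
            if abs(d0 - 1.20) <= 2.0 * series.fit["d0_se"]:
                hits_d0 += 1
            if abs(alpha - 0.86) <= 2.0 * series.fit["alpha_se"]:
                hits_alpha += 1
        assert hits_d0 / n_seeds == pytest.approx(0.95, abs=0.04)
        assert hits_alpha / n_seeds == pytest.approx(0.95, abs=0.04)


class TestYehHummer:
    def d_app(self, v):
        return DiffusionEstimate(v, 310.15, 0.275, kind="D_app")

    def test_inverse_of_finite_size_model(self):
        d_app = finite_size_D(1.2, 5.0, 310.15, 0.275, 0.86)
        corrected = yeh_hummer_correct(self.d_app(d_app), 5.0, 0.86)
        assert corrected.value == pytest.approx(1.2, rel=1e-12)
        assert corrected.kind == "D_0"

    def test_monotone_in_alpha(self):
        a = yeh_hummer_correct(self.d_app(1.0), 5.0, 1.0).value
        b = yeh_hummer_correct(self.d_app(1.0), 5.0, 0.86).value
        assert a > b

    def test_correction_halves_when_box_doubles(self):
        c1 = yeh_hummer_correct(self.d_app(1.0), 5.0, 0.86).value - 1.0
        c2 = yeh_hummer_correct(self.d_app(1.0), 10.0, 0.86).value - 1.0
        assert c1 == pytest.approx(2.0 * c2, rel=1e-12)


class TestXiEwald:
    def test_matches_literature_value(self):
        assert compute_xi_ew(1e-7) == pytest.approx(2.837298, abs=2e-6)

    def test_splitting_parameter_invariance(self):
        a = _xi_partial(math.sqrt(math.pi), 8, 8)
        b = _xi_partial(1.8 * math.sqrt(math.pi), 10, 10)
        assert a == pytest.approx(b, rel=1e-9)

    def test_brute_force_lattice_sum_oracle(self):
        """Direct 21^3 lattice sum against a neutralizing background, with
        a smooth spherical window for shell-convergence acceleration,
        agrees with the Ewald value to 1e-3."""
        from scipy.integrate import quad
        from scipy.special import erfc
        g = np.arange(-10, 11)
        nx, ny, nz = np.meshgrid(g, g, g, indexing="ij")
        r = np.sqrt((nx ** 2 + ny ** 2 + nz ** 2).astype(float))
        r[10, 10, 10] = np.inf
        r0, w = 7.0, 1.0
        window = 0.5 * erfc((r - r0) / w)
        lattice = float(np.sum(window / r))
        background = 4.0 * math.pi * quad(
            lambda x: 0.5 * erfc((x - r0) / w) * x, 0.0, r0 + 8.0 * w)[0]
        estimate = background - lattice
        assert estimate == pytest.approx(compute_xi_ew(1e-7), abs=1e-3)

    def test_too_tight_tolerance_rejected(self):
        with pytest.raises(ValueError):
            compute_xi_ew(1e-12)


class TestUnwrap:
    def test_repairs_periodic_jumps(self):
        traj = gen_brownian_trajectory(1.0, 3000, 3.0, seed=9)
        box = 4.0
        wrapped = traj.positions - box * np.floor(traj.positions / box)
        unwrapped = unwrap_trajectory(wrapped, box)
        # unwrapped differs from the original only by the initial image shift
        shift = traj.positions[0] - unwrapped[0]
        np.testing.assert_allclose(unwrapped + shift, traj.positions,
                                   atol=1e-9)
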