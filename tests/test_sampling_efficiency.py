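"""ACFs, autocorrelation times, free energies, KS comparison, generator."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.signal import lfilter

from fastwater.constants import KB
from fastwater.errors import (
    DegenerateSeriesError,
    InsufficientDataError,
    IntegrationError,
    InvalidArgumentError,
    InvalidRangeError,
)
from fastwater.sampling_efficiency import (
    CVSeries,
    PeriodicPotential,
    SeriesACF,
    autocorrelation,
    block_sem,
    dihedral_order_parameter,
    exponential_act,
    free_energy_profile,
    free_energy_surface,
    generate_dihedral_series,
    integrated_act,
    internal_friction_fit,
    ks_replica_comparison,
    vdsb_dihedral_acf,
)


def _ar1(rng: np.random.Generator, rho: float, n: int) -> np.ndarray:
    return lfilter([1.0], [1.0, -rho], rng.normal(size=n))


class TestLinearACF:
    def test_lag_zero_is_one(self, rng):
        acf = autocorrelation(CVSeries(rng.normal(size=500), 1.0))
        assert acf.values[0] == 1.0

    def test_white_noise_uncorrelated(self, rng):
        n = 20000
        acf = autocorrelation(CVSeries(rng.normal(size=n), 1.0), max_lag=50.0)
        assert np.all(np.abs(acf.values[1:]) < 3.0 / math.sqrt(n))

    def test_ar1_matches_geometric_decay(self, rng):
        rho = 0.8
        acf = autocorrelation(CVSeries(_ar1(rng, rho, 200000), 1.0),
                              max_lag=10.0)
        expected = rho ** np.arange(11)
        assert np.allclose(acf.values, expected, atol=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            autocorrelation(CVSeries(np.ones(100), 1.0))

    def test_circular_series_rejected(self):
        with pytest.raises(InvalidArgumentError):
            autocorrelation(CVSeries(np.zeros(10) + 1.0, 1.0, circular=True))


class TestDihedralACF:
    def test_constant_angle_stays_at_one(self):
        series = CVSeries(np.full(200, 42.0), 1.0, circular=True)
        acf = vdsb_dihedral_acf(series, max_lag=20.0)
        assert np.allclose(acf.values, 1.0, atol=1e-12)

    def test_iid_uniform_angles_decorrelate(self, rng):
        series = CVSeries(rng.uniform(-180, 180, 40000), 1.0, circular=True)
        acf = vdsb_dihedral_acf(series, max_lag=10.0)
        assert np.all(np.abs(acf.values[1:]) < 0.02)

    def test_linear_series_rejected(self):
        with pytest.raises(InvalidArgumentError):
            vdsb_dihedral_acf(CVSeries(np.arange(10.0), 1.0))

    def test_decay_time_scales_with_friction(self):
        # single-well potential: relaxation is friction-proportional
        pot = PeriodicPotential(terms=((2.0, 1, 180.0),))
        taus = []
        for gamma, seed in ((1.0, 31), (4.0, 32)):
            reps = generate_dihedral_series(
                pot, friction=gamma, dt=0.002, n_steps=120_000, seed=seed,
                n_replicas=8)
            acfs = [vdsb_dihedral_acf(r, max_lag=20.0,
                                      normalize="fluctuation") for r in reps]
            taus.append(integrated_act(acfs).tau_int)
        assert taus[1] / taus[0] == pytest.approx(4.0, rel=0.2)


class TestOrderParameter:
    def test_delta_distribution_is_one(self):
        assert dihedral_order_parameter(np.full(50, -77.0)) == pytest.approx(1.0)

    def test_uniform_angles_vanish(self, rng):
        s = dihedral_order_parameter(rng.uniform(-180, 180, 200000))
        assert s < 0.001

    def test_antipodal_mixture_cancels(self):
        angles = np.concatenate([np.zeros(1000), np.full(1000, 180.0)])
        assert dihedral_order_parameter(angles) == pytest.approx(0.0, abs=1e-12)

    def test_empty_series_rejected(self):
        with pytest.raises(InvalidArgumentError):
            dihedral_order_parameter(np.array([]))


class TestIntegratedACT:
    def test_white_noise_is_half_frame(self, rng):
        acf = autocorrelation(CVSeries(rng.normal(size=500_000), 1.0),
                              max_lag=100.0)
        assert integrated_act(acf).tau_int == pytest.approx(0.5, abs=0.05)

    def test_ar1_closed_form(self, rng):
        rho, dt = 0.9, 2.0
        acf = autocorrelation(CVSeries(_ar1(rng, rho, 1_000_000), dt),
                              max_lag=400.0)
        expected = dt * (0.5 + rho / (1 - rho))
        assert integrated_act(acf).tau_int == pytest.approx(expected, rel=0.05)

    def test_replica_se_shrinks_as_sqrt_n(self, rng):
        rho = 0.8
        acfs = [autocorrelation(CVSeries(_ar1(rng, rho, 20000), 1.0),
                                max_lag=100.0) for _ in range(10)]
        est = integrated_act(acfs)
        per_replica = [integrated_act(a).tau_int for a in acfs]
        spread = np.std(per_replica, ddof=1)
        assert est.se_int == pytest.approx(spread / math.sqrt(10), rel=1e-9)
        assert est.n_replicas == 10

    def test_first_negative_window_rule(self, rng):
        acf = autocorrelation(CVSeries(_ar1(rng, 0.5, 100000), 1.0),
                              max_lag=200.0)
        est = integrated_act(acf, window_rule="first_negative")
        assert est.tau_int == pytest.approx(0.5 + 0.5 / 0.5, rel=0.15)


class TestExponentialACT:
    def _acf_from(self, values: np.ndarray, dt: float = 1.0) -> SeriesACF:
        lags = np.arange(values.size) * dt
        return SeriesACF(lags=lags, values=values, frame_dt=dt, n_samples=1000)

    def test_pure_exponential_exact(self):
        tau = 12.5
        lags = np.arange(100.0)
        est = exponential_act(self._acf_from(np.exp(-lags / tau)))
        assert est.tau_exp == pytest.approx(tau, rel=1e-9)

    def test_biexponential_tail_recovers_slow_scale(self):
        lags = np.arange(200.0)
        vals = 0.7 * np.exp(-lags / 2.0) + 0.3 * np.exp(-lags / 20.0)
        est = exponential_act(self._acf_from(vals), fit_range=(40.0, 80.0))
        assert est.tau_exp == pytest.approx(20.0, rel=0.05)

    def test_negative_values_in_range_rejected(self):
        vals = np.exp(-np.arange(50.0) / 5.0)
        vals[30:] = -0.01
        with pytest.raises(InvalidRangeError):
            exponential_act(self._acf_from(vals), fit_range=(20.0, 45.0))


class TestBlockSEM:
    def test_constant_series_is_zero(self):
        assert block_sem(np.full(1024, 3.3)) == 0.0

    def test_iid_matches_naive_sem(self, rng):
        x = rng.normal(size=65536)
        naive = x.std(ddof=1) / math.sqrt(x.size)
        assert block_sem(x) == pytest.approx(naive, rel=0.2)

    def test_correlated_series_matches_act_formula(self, rng):
        rho = 0.95
        x = _ar1(rng, rho, 262144)[2000:]
        tau_int = 0.5 + rho / (1 - rho)
        expected = x.std(ddof=1) * math.sqrt(2 * tau_int / x.size)
        assert block_sem(x) == pytest.approx(expected, rel=0.3)

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            block_sem(np.arange(8.0))


class TestFreeEnergy:
    def test_equal_bins_have_equal_energy(self):
        samples = np.concatenate([np.full(500, 0.5), np.full(500, 1.5)])
        prof = free_energy_profile(samples, np.array([0.0, 1.0, 2.0]), 310.0)
        assert prof.free_energies[0] == prof.free_energies[1] == 0.0

    def test_probability_ratio_e_gives_kt(self):
        n1, n2 = 27183, 10000  # ratio e to 4 decimals
        samples = np.concatenate([np.full(n1, 0.5), np.full(n2, 1.5)])
        prof = free_energy_profile(samples, np.array([0.0, 1.0, 2.0]), 310.0)
        assert prof.free_energies[1] == pytest.approx(KB * 310.0, rel=1e-3)
        assert prof.free_energies[1] == pytest.approx(2.578, abs=2e-3)

    def test_empty_bins_masked_and_probabilities_normalised(self, rng):
        samples = rng.uniform(0, 1, 1000)
        prof = free_energy_profile(samples, np.linspace(-1, 2, 31), 300.0)
        assert np.isnan(prof.free_energies[prof.counts == 0]).all()
        assert prof.probabilities.sum() == pytest.approx(1.0)

    def test_all_samples_outside_bins_rejected(self):
        from fastwater.errors import EmptyHistogramError
        with pytest.raises(EmptyHistogramError):
            free_energy_profile(np.full(10, 5.0), np.array([0.0, 1.0]), 300.0)

    def test_2d_difference_map_vanishes_for_same_distribution(self, rng):
        edges = np.linspace(-180, 180, 37)
        x1, y1 = rng.uniform(-180, 180, (2, 30000))
        surf_a = free_energy_surface(x1, y1, edges, edges, 310.0)
        surf_b = free_energy_surface(x1, y1, edges, edges, 310.0)
        diff = surf_a.difference(surf_b)
        assert np.nanmax(np.abs(diff)) == pytest.approx(0.0, abs=1e-12)

    def test_2d_marginal_consistent_with_1d(self, rng):
        edges = np.linspace(-180, 180, 19)
        x = rng.uniform(-180, 180, 20000)
        y = rng.uniform(-180, 180, 20000)
        surf = free_energy_surface(x, y, edges, edges, 310.0)
        prof = free_energy_profile(x, edges, 310.0)
        marg = surf.probabilities.sum(axis=1)
        assert np.allclose(marg, prof.probabilities, atol=1e-12)


class TestKSComparison:
    def test_replica_against_itself_is_zero(self, rng):
        x = rng.normal(size=500)
        res = ks_replica_comparison([x, x], [x, x.copy()])
        assert res.between.min() == 0.0

    def test_null_groups_overlap(self, rng):
        group_a = [rng.normal(size=3000) for _ in range(5)]
        group_b = [rng.normal(size=3000) for _ in range(5)]
        res = ks_replica_comparison(group_a, group_b)
        assert res.overlap_summary >= 0.8

    def test_shifted_group_separates(self, rng):
        group_a = [rng.normal(size=3000) for _ in range(5)]
        group_b = [rng.normal(size=3000) + 3.0 for _ in range(5)]
        res = ks_replica_comparison(group_a, group_b)
        assert res.overlap_summary <= 0.2

    def test_single_replica_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            ks_replica_comparison([rng.normal(size=10)],
                                  [rng.normal(size=10)] * 2)


class TestInternalFriction:
    def test_noiseless_exact_recovery(self):
        a_true, b_true = 0.041, 0.013
        points = [(m, a_true + b_true * math.sqrt(m), 0.001)
                  for m in (0.5, 1.116, 4.464, 18.0154)]
        fit = internal_friction_fit(points)
        assert fit.a == pytest.approx(a_true, rel=1e-9)
        assert fit.b == pytest.approx(b_true, rel=1e-9)

    def test_flat_tau_gives_zero_slope(self):
        points = [(m, 0.2, 0.01) for m in (1.0, 4.0, 9.0)]
        fit = internal_friction_fit(points)
        assert fit.a == pytest.approx(0.2, rel=1e-9)
        assert fit.b == pytest.approx(0.0, abs=1e-12)

    def test_weighted_coverage_near_nominal(self, rng):
        a_true, b_true = 0.04, 0.015
        masses = np.array([0.5, 1.0, 2.0, 4.5, 9.0, 18.0])
        ses = 0.002 + 0.001 * np.sqrt(masses)
        hits_a = hits_b = 0
        n_mc = 400
        for _ in range(n_mc):
            taus = a_true + b_true * np.sqrt(masses) + rng.normal(0, ses)
            fit = internal_friction_fit(list(zip(masses, taus, ses)))
            hits_a += abs(fit.a - a_true) < 2 * fit.se_a
            hits_b += abs(fit.b - b_true) < 2 * fit.se_b
        assert hits_a / n_mc == pytest.approx(0.954, abs=0.05)
        assert hits_b / n_mc == pytest.approx(0.954, abs=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            internal_friction_fit([(1.0, 0.05, 0.01)])


class TestDihedralGenerator:
    def test_stationary_density_matches_boltzmann(self):
        pot = PeriodicPotential(terms=((3.0, 1, 180.0),))  # single well at 0
        reps = generate_dihedral_series(pot, friction=1.0, dt=0.002,
                                        n_steps=150_000, seed=33,
                                        n_replicas=4)
        tau = integrated_act(
            [vdsb_dihedral_acf(r, max_lag=10.0, normalize="fluctuation")
             for r in reps]).tau_int
        stride = max(1, int(round(5 * tau / 0.002)))
        pooled = np.concatenate([r.values[::stride] for r in reps])
        deg, cdf = pot.stationary_cdf(310.0)
        u = np.interp(pooled, deg, cdf)
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_fixed_seed_bit_identical(self):
        a = generate_dihedral_series(dt=0.005, n_steps=2000, seed=34)
        b = generate_dihedral_series(dt=0.005, n_steps=2000, seed=34)
        assert np.array_equal(a[0].values, b[0].values)

    def test_unstable_time_step_rejected(self):
        with pytest.raises(IntegrationError):
            generate_dihedral_series(friction=0.1, dt=0.05, n_steps=100,
                                     seed=1)

    def test_floor_friction_creates_relaxation_floor(self):
        """With a thermostat-like friction floor, tau_int versus sqrt(mass)
        extrapolates to a positive intercept (internal friction)."""
        pot = PeriodicPotential()
        points = []
        for i, scale in enumerate((0.0625, 0.25, 1.0)):
            reps = generate_dihedral_series(
                pot, friction=2.0, mass_scale=scale, floor_friction=1.0,
                dt=0.002, n_steps=100_000, seed=40 + i, n_replicas=8)
            est = integrated_act(
                [vdsb_dihedral_acf(r, max_lag=25.0) for r in reps])
            points.append((scale, est.tau_int, est.se_int))
        fit = internal_friction_fit(points)
        assert fit.a > 3 * fit.se_a        # positive floor resolved
        assert fit.b > 0
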