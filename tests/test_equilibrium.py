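"""Closed-form equilibria, adaptation covariances, and the coupled solver."""

import numpy as np
import pytest

from plastisle import (
    DispersalParams,
    EnvironmentParams,
    GeneticSelectionParams,
    ParameterBundle,
    SlopeIndeterminateError,
    cov_intercept_dev_temporal,
    grand_mean_intercept,
    island_intercept_deviation,
    mean_slope_limit,
    run_simulation,
    solve_full_equilibrium,
    spatial_adaptation,
    temporal_adaptation,
)
from plastisle.criteria import swap_space_time
from plastisle.equilibrium import island_grid
from plastisle.params import ParameterError

from conftest import random_valid_bundle

# the worked small-Gbb chain: symmetric tracking g = 0.25 on both axes,
# gamma_z = 1/3, gamma_b = 1/9, giving b = 0.975 / (1/3 + 1.5)
CHAIN_ENV = EnvironmentParams(
    sigma2_DI=1, sigma2_DT=1, sigma2_SI=1, sigma2_ST=1,
    kappa_I=0.5, kappa_T=0.8, alpha_T=0.5,
)
CHAIN_GEN = GeneticSelectionParams(Gaa=1, Gbb=0, Eaa=1, Ebb=0, omega_b=3.0)
CHAIN_DISP = DispersalParams(m=0.5)
CHAIN_SLOPE = 0.975 / (1 / 3 + 1.5)


class TestGrandMeanIntercept:
    def test_equals_optimum_intercept(self):
        assert grand_mean_intercept(GeneticSelectionParams(A=0.0)) == 0.0
        assert grand_mean_intercept(GeneticSelectionParams(A=3.7)) == 3.7

    def test_independent_of_everything_else(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            b = random_valid_bundle(rng)
            assert grand_mean_intercept(b.gen) == b.gen.A


class TestIslandInterceptDeviation:
    def test_no_tracking_means_no_deviation(self):
        assert island_intercept_deviation(0.0, B=1, S_i=5, slope_i=2, D_i=3) == 0.0

    def test_direct_substitution(self):
        assert island_intercept_deviation(1.0, B=1, S_i=2, slope_i=0.5, D_i=2) == pytest.approx(1.0)

    def test_full_tracking_puts_phenotype_on_the_optimum(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            A, B, S, slope, D = rng.normal(size=5)
            a_dev = island_intercept_deviation(1.0, B, S, slope, D)
            assert A + a_dev + slope * D == pytest.approx(A + B * S)


class TestMeanSlopeLimit:
    def test_no_cost_equal_kappas_gives_DO_regression(self):
        env = EnvironmentParams(
            sigma2_DI=1, sigma2_DT=1, sigma2_DIT=0.5, sigma2_SI=1, sigma2_ST=1,
            sigma2_SIT=0.5, kappa_I=0.8, kappa_T=0.8, kappa_IT=0.8, alpha_T=0.5,
        )
        gen = GeneticSelectionParams(B=1.0, omega_b=None)
        slope = mean_slope_limit(env, gen, DispersalParams(m=0.3), gamma_z=0.2)
        assert slope == 0.8  # B * kappa exactly

    def test_cost_keeps_slope_strictly_below_DO_regression(self):
        env = EnvironmentParams(
            sigma2_DI=1, sigma2_DT=1, sigma2_SI=1, sigma2_ST=1,
            kappa_I=0.8, kappa_T=0.8, alpha_T=0.5,
        )
        gen = GeneticSelectionParams(B=1.0, omega_b=3.0)
        slope = mean_slope_limit(env, gen, DispersalParams(m=0.3), gamma_z=0.2)
        assert 0 < slope < 0.8

    def test_worked_arithmetic_chain(self):
        slope = mean_slope_limit(CHAIN_ENV, CHAIN_GEN, CHAIN_DISP, gamma_z=1 / 3)
        assert slope == pytest.approx(CHAIN_SLOPE)
        assert slope == pytest.approx(0.5318, abs=1e-4)

    def test_zero_cue_reliability_means_no_plasticity(self):
        env = EnvironmentParams(kappa_I=0.0, kappa_T=0.0, alpha_T=0.5)
        assert mean_slope_limit(env, GeneticSelectionParams(), DispersalParams(m=0.5),
                                gamma_z=0.2) == 0.0

    def test_indeterminate_when_costfree_and_fully_tracked(self):
        # no temporal or interaction variance, no migration: gI = 1 and the
        # slope equation loses both numerator and denominator
        env = EnvironmentParams(sigma2_DT=0, sigma2_ST=0, kappa_I=0.8)
        gen = GeneticSelectionParams(omega_b=None)
        with pytest.raises(SlopeIndeterminateError):
            mean_slope_limit(env, gen, DispersalParams(m=0.0), gamma_z=0.2)

    def test_space_time_swap_invariance(self):
        rng = np.random.default_rng(23)
        for _ in range(300):
            b = random_valid_bundle(rng)
            gz = 0.2
            try:
                direct = mean_slope_limit(b.env, b.gen, b.disp, gamma_z=gz)
            except SlopeIndeterminateError:
                continue
            env_s, disp_s = swap_space_time(b.env, b.disp)
            swapped = mean_slope_limit(env_s, b.gen, disp_s, gamma_z=gz)
            assert swapped == pytest.approx(direct, rel=1e-12, abs=1e-14)

    def test_monotone_in_cost(self):
        slopes = [
            mean_slope_limit(CHAIN_ENV, GeneticSelectionParams(
                Gbb=0, Ebb=0, omega_b=wb), CHAIN_DISP, gamma_z=1 / 3)
            for wb in (None, 10.0, 3.0, 1.0)
        ]
        assert all(s1 > s2 for s1, s2 in zip(slopes, slopes[1:]))

    def test_monotone_in_tracking_for_positive_kappas(self):
        # easier genetic tracking (higher philopatry) flattens the slope
        env = EnvironmentParams(kappa_I=0.8, kappa_T=0.8, alpha_T=0.5)
        slopes = [
            mean_slope_limit(env, GeneticSelectionParams(), DispersalParams(m=m),
                             gamma_z=0.3)
            for m in (0.0, 0.3, 0.6, 1.0)
        ]
        assert all(s1 <= s2 for s1, s2 in zip(slopes, slopes[1:]))


class TestAdaptationCovariances:
    def test_cov_intercept_cue_examples(self):
        assert cov_intercept_dev_temporal(0.0, 1.0, 1.0, 0.8, 0.5) == 0.0
        assert cov_intercept_dev_temporal(0.3, 1.0, 1.0, 0.8, 0.8) == 0.0
        assert cov_intercept_dev_temporal(0.25, 1.0, 1.0, 0.8, CHAIN_SLOPE) == pytest.approx(
            0.067045, abs=1e-5
        )

    def test_temporal_adaptation_examples(self):
        assert temporal_adaptation(0.0, 1.0, 1.0, 0.5, 0.8, 1.0) == 0.0
        # plasticity fully absorbing the temporal fluctuations: b = B s2ST/(kT s2DT)
        assert temporal_adaptation(0.3, 1.0, 1.0, 1.0 / 0.8, 0.8, 1.0) == pytest.approx(0.0)
        assert temporal_adaptation(0.25, 1.0, 1.0, CHAIN_SLOPE, 0.8, 1.0) == pytest.approx(
            0.143636, abs=1e-5
        )

    def test_spatial_mirrors_temporal(self):
        rng = np.random.default_rng(24)
        for _ in range(50):
            g, B, s2s, b, k, s2d = rng.uniform(0.1, 2.0, size=6)
            assert spatial_adaptation(g, B, s2s, b, k, s2d) == temporal_adaptation(
                g, B, s2s, b, k, s2d
            )

    def test_local_adaptation_rises_as_spatial_cue_degrades(self):
        # with the plastic slope held fixed, kappa_I -> 0 raises Cov(a, S)
        vals = [spatial_adaptation(0.5, 1.0, 1.0, 0.6, k, 1.0) for k in (0.8, 0.4, 0.0)]
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] == pytest.approx(0.5)  # gI * B * sigma2_SI


class TestIslandGrid:
    def test_weights_and_moments(self):
        env = EnvironmentParams(sigma2_DI=1.3, sigma2_SI=2.0, kappa_I=0.7)
        d, s, w = island_grid(env, n_nodes=31)
        assert w.sum() == pytest.approx(1.0)
        assert np.sum(w * d**2) == pytest.approx(1.3, rel=1e-8)
        assert np.sum(w * s**2) == pytest.approx(2.0, rel=1e-8)
        assert np.sum(w * d * s) == pytest.approx(0.7 * 1.3, rel=1e-8)

    def test_monte_carlo_grid_matches_quadrature(self):
        env = EnvironmentParams(sigma2_DI=1.0, sigma2_SI=1.0, kappa_I=0.8)
        d, s, w = island_grid(env, mc_sample=200_000, seed=25)
        assert np.sum(w * d * s) == pytest.approx(0.8, abs=0.02)


class TestFullSolver:
    def _fig1_bundle(self, sigma2_T, m):
        env = EnvironmentParams(
            sigma2_DI=1, sigma2_SI=1, sigma2_DT=sigma2_T, sigma2_ST=sigma2_T,
            kappa_I=0.8, kappa_T=0.8, alpha_T=0.5,
        )
        return ParameterBundle(env, GeneticSelectionParams(), DispersalParams(m=m))

    def test_residuals_below_tolerance(self):
        b = self._fig1_bundle(1.0, 0.3)
        sol = solve_full_equilibrium(b.env, b.gen, b.disp, gamma_z_estimator="plugin")
        assert sol.residual < 1e-10
        assert sol.a_bar == b.gen.A

    def test_island_deviations_are_centred(self):
        b = self._fig1_bundle(1.0, 0.3)
        sol = solve_full_equilibrium(b.env, b.gen, b.disp, gamma_z_estimator="plugin")
        w = sol.islands["weight"].to_numpy()
        assert np.sum(w * sol.islands["b_dev"]) == pytest.approx(0.0, abs=1e-12)

    def test_small_Gbb_recovers_closed_form(self):
        b = self._fig1_bundle(1.0, 0.3).replace(Gbb=1e-8)
        gz = 0.2
        sol = solve_full_equilibrium(b.env, b.gen, b.disp, gamma_z=gz)
        limit = mean_slope_limit(b.env, b.gen, b.disp, gamma_z=gz)
        assert sol.b_bar == pytest.approx(limit, abs=1e-4)

    def test_requires_genetic_slope_variance(self):
        b = self._fig1_bundle(1.0, 0.3).replace(Gbb=0.0)
        with pytest.raises(ParameterError, match="Gbb"):
            solve_full_equilibrium(b.env, b.gen, b.disp, gamma_z=0.2)

    def test_temporal_variance_substitutes_for_local_adaptation(self):
        # adding temporal fluctuation reduces spatial genetic differentiation
        # of the intercept at every philopatry level
        for aI in (0.2, 0.5, 0.8, 1.0):
            sols = [
                solve_full_equilibrium(
                    self._fig1_bundle(s2t, 1 - aI).env,
                    GeneticSelectionParams(),
                    DispersalParams(m=1 - aI),
                    gamma_z_estimator="plugin",
                )
                for s2t in (0.0, 1.0)
            ]
            assert sols[1].intercept_spatial_variance < sols[0].intercept_spatial_variance

    def test_slope_cline_shallowest_in_average_environment(self):
        # pure spatial model: island slopes sit closest to zero near S_i = 0
        # and steepen toward the extremes
        b = self._fig1_bundle(0.0, 0.3)
        sol = solve_full_equilibrium(b.env, b.gen, b.disp, gamma_z_estimator="plugin")
        isl = sol.islands
        centre = isl.loc[isl["S_i"].abs().idxmin(), "b_total"]
        extreme = isl.loc[isl["S_i"].abs().idxmax(), "b_total"]
        assert abs(centre) < abs(extreme)

    def test_matches_simulation_at_weak_selection(self):
        # time-averaged simulated slope against the solver at omega_z = 20
        b = self._fig1_bundle(1.0, 0.5).replace(omega_z=20.0, kappa_T=-0.8)
        sol = solve_full_equilibrium(b.env, b.gen, b.disp, gamma_z_estimator="taylor")
        sims = [
            run_simulation(b, n_islands=200, n_generations=3000, burn_in=1000, seed=s).mean_slope
            for s in (31, 32, 33)
        ]
        se = np.std(sims, ddof=1) / np.sqrt(3)
        assert np.mean(sims) == pytest.approx(sol.b_bar, abs=max(4 * se, 5e-3))
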