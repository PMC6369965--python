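"""Stochastic recursion: selection and migration updates, equilibration, determinism."""

import numpy as np
import pytest

from plastisle import (
    DispersalParams,
    EnvironmentParams,
    GeneticSelectionParams,
    MetapopState,
    ParameterBundle,
    SpaceTimeEnvironment,
    migration_step,
    run_simulation,
    selection_step,
    slope_mc_se,
    summarize,
)


def _state(a, b, D, S):
    """Metapopulation state with a hand-set environment (all spatial)."""
    n = len(a)
    env = EnvironmentParams(sigma2_DI=1, sigma2_SI=1)
    st = SpaceTimeEnvironment(
        env=env,
        D_i=np.asarray(D, float),
        S_i=np.asarray(S, float),
        D_t=0.0,
        S_t=0.0,
        D_it=np.zeros(n),
        S_it=np.zeros(n),
    )
    return MetapopState(a_bar=np.asarray(a, float), b_bar=np.asarray(b, float), environment=st)


class TestSelectionStep:
    def test_no_change_at_the_optimum(self, unit_gen):
        bundle = ParameterBundle(EnvironmentParams(), unit_gen, DispersalParams())
        # theta = A + B S = 2 on an island with z_bar = 2 and b_bar = 0
        state = _state(a=[2.0], b=[0.0], D=[0.0], S=[2.0])
        selection_step(state, bundle)
        assert state.a_bar[0] == pytest.approx(2.0)
        assert state.b_bar[0] == pytest.approx(0.0)

    def test_intercept_moves_by_Gaa_gamma_mismatch(self, unit_gen):
        # D=0 -> P = Gaa+Eaa = 2, gamma = 1/(1+2) = 1/3; theta = A = 1 and
        # z_bar = 0, so a' = Gaa * gamma * (theta - z_bar) = 1/3 and the slope
        # gradient vanishes (no cue, no plasticity)
        gen = GeneticSelectionParams(A=1.0, B=1.0, omega_z=1.0)
        bundle = ParameterBundle(EnvironmentParams(), gen, DispersalParams())
        state = _state(a=[0.0], b=[0.0], D=[0.0], S=[0.0])
        selection_step(state, bundle)
        assert state.a_bar[0] == pytest.approx(1 / 3)
        assert state.b_bar[0] == pytest.approx(0.0)

    def test_costly_plasticity_decays_geometrically_without_cue(self, unit_gen):
        bundle = ParameterBundle(EnvironmentParams(), unit_gen, DispersalParams())
        b0 = 0.7
        state = _state(a=[0.0], b=[b0], D=[0.0], S=[0.0])
        selection_step(state, bundle)
        # gamma_b = 1/(9+2); slope shrinks by factor (1 - Gbb gamma_b)
        assert state.b_bar[0] == pytest.approx(b0 * (1 - 1 / 11))

    def test_nonfinite_state_aborts_with_diagnostics(self, unit_gen):
        bundle = ParameterBundle(EnvironmentParams(), unit_gen, DispersalParams())
        state = _state(a=[0.0, np.nan], b=[0.0, 0.0], D=[0.0, 0.0], S=[0.0, 0.0])
        with pytest.raises(FloatingPointError, match="island 1"):
            selection_step(state, bundle)


class TestMigrationStep:
    @pytest.mark.parametrize("m", [0.0, 0.3, 1.0])
    def test_global_means_conserved(self, unit_gen, m):
        bundle = ParameterBundle(EnvironmentParams(), unit_gen, DispersalParams(m=m))
        rng = np.random.default_rng(13)
        a, b = rng.normal(size=50), rng.normal(size=50)
        state = _state(a=a.copy(), b=b.copy(), D=np.zeros(50), S=np.zeros(50))
        migration_step(state, bundle)
        assert state.a_bar.mean() == pytest.approx(a.mean(), abs=1e-12)
        assert state.b_bar.mean() == pytest.approx(b.mean(), abs=1e-12)
        if m == 0.0:
            np.testing.assert_array_equal(state.a_bar, a)
        if m == 1.0:
            np.testing.assert_allclose(state.a_bar, a.mean())
            np.testing.assert_allclose(state.b_bar, b.mean())


class TestRunSimulation:
    def test_constant_environment_converges_to_optimum(self):
        env = EnvironmentParams(sigma2_DI=0, sigma2_DT=0, sigma2_SI=0, sigma2_ST=0)
        gen = GeneticSelectionParams(A=2.0, omega_z=1.0)
        bundle = ParameterBundle(env, gen, DispersalParams(m=0.1))
        out = run_simulation(bundle, n_islands=10, n_generations=201, burn_in=200, seed=0)
        assert np.all(np.abs(out.island_means["time_avg_a"] - 2.0) < 1e-6)
        assert np.all(np.abs(out.island_means["time_avg_b"]) < 1e-6)

    def test_pure_spatial_model_adapts_locally(self):
        # no temporal variation, no migration, tiny slope variance: the
        # phenotype cline converges onto the optimum cline
        env = EnvironmentParams(
            sigma2_DI=1, sigma2_SI=1, sigma2_DT=0, sigma2_ST=0, kappa_I=0.8
        )
        gen = GeneticSelectionParams(Gbb=1e-3, Ebb=0.0, omega_z=1.0)
        bundle = ParameterBundle(env, gen, DispersalParams(m=0.0))
        out = run_simulation(bundle, n_islands=30, n_generations=2000, burn_in=1500, seed=1)
        im = out.island_means
        phenotype = im["time_avg_a"] + im["time_avg_b"] * im["D_i"]
        optimum = gen.A + gen.B * im["S_i"]
        np.testing.assert_allclose(phenotype, optimum, atol=5e-3)

    def test_slope_frozen_without_genetic_variance(self, fig3_bundle):
        bundle = fig3_bundle.replace(Gbb=0.0)
        out = run_simulation(bundle, n_islands=20, n_generations=100, burn_in=50, seed=2)
        assert not out.island_means["time_avg_b"].any()

    def test_bit_identical_given_seed(self, fig3_bundle):
        outs = [
            run_simulation(fig3_bundle, n_islands=20, n_generations=120, burn_in=50, seed=3)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(outs[0].global_b, outs[1].global_b)
        assert outs[0].island_means.equals(outs[1].island_means)

    def test_burn_in_must_precede_end(self, fig3_bundle):
        with pytest.raises(ValueError, match="burn_in"):
            run_simulation(fig3_bundle, n_islands=5, n_generations=10, burn_in=10)

    def test_stochastic_equilibrium_of_global_intercept(self, fig3_bundle):
        # after burn-in the generation-to-generation change of the global mean
        # intercept has expectation zero
        out = run_simulation(fig3_bundle, n_islands=200, n_generations=3000, burn_in=1000, seed=4)
        delta = np.diff(out.global_a)
        se = delta.std(ddof=1) / np.sqrt(delta.size)
        assert abs(delta.mean()) < 4 * se

    def test_trajectories_match_streaming_summaries(self, fig3_bundle):
        out = run_simulation(
            fig3_bundle, n_islands=10, n_generations=60, burn_in=20, seed=5,
            record_trajectories=True,
        )
        per_island = out.trajectories.groupby("island")[["a_bar", "b_bar"]].mean()
        np.testing.assert_allclose(
            per_island["a_bar"].to_numpy(), out.island_means["time_avg_a"].to_numpy()
        )
        np.testing.assert_allclose(
            per_island["b_bar"].to_numpy(), out.island_means["time_avg_b"].to_numpy()
        )


class TestSummaries:
    def test_constant_environment_has_zero_covariances(self):
        env = EnvironmentParams(sigma2_DI=0, sigma2_DT=0, sigma2_SI=0, sigma2_ST=0)
        bundle = ParameterBundle(env, GeneticSelectionParams(), DispersalParams(m=0.1))
        out = run_simulation(bundle, n_islands=10, n_generations=300, burn_in=250, seed=6)
        s = summarize(out)
        assert s["spatial_cov_a_S"] == pytest.approx(0.0, abs=1e-12)
        assert s["temporal_cov_a_S"] == pytest.approx(0.0, abs=1e-12)

    def test_mc_se_positive_and_needs_enough_generations(self, fig3_bundle):
        out = run_simulation(fig3_bundle, n_islands=20, n_generations=300, burn_in=100, seed=7)
        assert slope_mc_se(out) > 0
        with pytest.raises(ValueError):
            slope_mc_se(out, n_batches=150)
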