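"""Stochastic evolutionary recursion on island mean reaction norms.

Each generation: the environment advances (AR(1) temporal step, fresh
interaction deviations), phenotypes develop as ``z = a + b * D_it``, Gaussian
stabilizing selection moves the island mean intercept and slope along the
gradients of mean log fitness (the multivariate breeder's-equation update),
and gamete migration mixes each island mean with the global mean.

The selection strength on the trait, ``gamma_zit = 1 / (omega_z^2 + P_zz)``
with ``P_zz = Gaa + Eaa + (Gbb + Ebb) * D_it^2``, is computed exactly per
island and generation — the analytical theory treats it as a constant, and
the simulator exists precisely to test that approximation.  Within-island
variances are fixed; islands are of infinite size, so there is no drift and
fertilization/gametogenesis leave the means unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .environment import SpaceTimeEnvironment
from .params import ParameterBundle, gamma_b

__all__ = [
    "MetapopState",
    "SimulationOutput",
    "selection_step",
    "migration_step",
    "run_simulation",
    "summarize",
    "slope_mc_se",
]

logger = logging.getLogger(__name__)


@dataclass
class MetapopState:
    """Per-island mean reaction-norm components plus the current environment."""

    a_bar: np.ndarray
    b_bar: np.ndarray
    environment: SpaceTimeEnvironment

    @property
    def mean_phenotype(self) -> np.ndarray:
        """Island mean phenotype ``z_bar = a_bar + b_bar * D_it``."""
        return self.a_bar + self.b_bar * self.environment.D


def selection_step(state: MetapopState, bundle: ParameterBundle) -> None:
    """Apply one generation of Gaussian selection to the island means, in place.

    With optimum ``theta = A + B * S_it`` and exact island/generation-specific
    selection strength ``gamma_zit``:

    * ``a_bar += Gaa * gamma_zit * (theta - z_bar)``
    * ``b_bar += Gbb * (gamma_zit * D_it * (theta - z_bar) - gamma_b * b_bar)``
    """
    gen = bundle.gen
    d = state.environment.D
    s = state.environment.S
    z_bar = state.a_bar + state.b_bar * d
    if not (np.all(np.isfinite(z_bar))):
        bad = int(np.flatnonzero(~np.isfinite(z_bar))[0])
        raise FloatingPointError(
            f"non-finite island state at generation {state.environment.generation}, "
            f"island {bad}: a_bar={state.a_bar[bad]!r}, b_bar={state.b_bar[bad]!r}"
        )
    p_zz = gen.Gaa + gen.Eaa + (gen.Gbb + gen.Ebb) * d**2
    gamma_zit = 1.0 / (gen.omega_z**2 + p_zz)
    mismatch = (gen.A + gen.B * s) - z_bar
    state.a_bar = state.a_bar + gen.Gaa * gamma_zit * mismatch
    state.b_bar = state.b_bar + gen.Gbb * (
        gamma_zit * d * mismatch - gamma_b(gen) * state.b_bar
    )


def migration_step(state: MetapopState, bundle: ParameterBundle) -> None:
    """Mix each island mean with the unweighted global mean, weight ``m``, in place.

    Leaves the global averages of both components unchanged to machine
    precision (migration redistributes, it does not create)."""
    m = bundle.disp.m
    if m == 0.0:
        return
    state.a_bar = (1.0 - m) * state.a_bar + m * state.a_bar.mean()
    state.b_bar = (1.0 - m) * state.b_bar + m * state.b_bar.mean()


@dataclass
class SimulationOutput:
    """Recorded trajectories (optional) and streaming summaries of a run.

    Per-island accumulators are time sums over the recorded (post burn-in)
    generations; ``global_a`` / ``global_b`` hold the across-island mean of
    each component for every recorded generation.
    """

    params: ParameterBundle
    n_islands: int
    n_generations: int
    burn_in: int
    seed: int
    D_i: np.ndarray
    S_i: np.ndarray
    global_a: np.ndarray
    global_b: np.ndarray
    island_means: pd.DataFrame
    trajectories: pd.DataFrame | None = None

    @property
    def n_recorded(self) -> int:
        return self.n_generations - self.burn_in

    @property
    def mean_slope(self) -> float:
        """Time-and-island average of the mean slope after burn-in."""
        return float(self.global_b.mean())

    @property
    def mean_intercept(self) -> float:
        return float(self.global_a.mean())


def run_simulation(
    bundle: ParameterBundle,
    n_islands: int = 1000,
    n_generations: int = 15000,
    burn_in: int = 5000,
    seed: int = 0,
    record_trajectories: bool = False,
    progress: bool = False,
) -> SimulationOutput:
    """Run the full stochastic recursion and return recorded output.

    Initial state: ``a_bar = A`` and ``b_bar = 0`` on every island.  Events per
    generation: environment advance, selection, migration; state is recorded
    after migration (end of generation) for generations past ``burn_in``.
    Deterministic given ``seed``.
    """
    bundle.validate()
    if not burn_in < n_generations:
        raise ValueError(f"burn_in ({burn_in}) must be < n_generations ({n_generations})")
    rng = np.random.default_rng(seed)
    env_state = SpaceTimeEnvironment.initialize(n_islands, bundle.env, rng)
    state = MetapopState(
        a_bar=np.full(n_islands, float(bundle.gen.A)),
        b_bar=np.zeros(n_islands),
        environment=env_state,
    )
    logger.info(
        "simulate: %d islands, %d generations (burn-in %d), seed %d, params %s",
        n_islands, n_generations, burn_in, seed, bundle.to_dict(),
    )

    n_rec = n_generations - burn_in
    global_a = np.empty(n_rec)
    global_b = np.empty(n_rec)
    # per-island accumulators for the summary table
    keys = ("a", "b", "D", "S", "aS", "aD", "bD", "S2", "D2")
    acc = {k: np.zeros(n_islands) for k in keys}
    traj_rows = [] if record_trajectories else None

    gen_iter = range(n_generations)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm

            gen_iter = tqdm(gen_iter, desc="simulate")
        except ImportError:
            pass

    for t in gen_iter:
        env_state.advance(rng)
        selection_step(state, bundle)
        migration_step(state, bundle)
        if t >= burn_in:
            i = t - burn_in
            global_a[i] = state.a_bar.mean()
            global_b[i] = state.b_bar.mean()
            d, s = env_state.D, env_state.S
            acc["a"] += state.a_bar
            acc["b"] += state.b_bar
            acc["D"] += d
            acc["S"] += s
            acc["aS"] += state.a_bar * s
            acc["aD"] += state.a_bar * d
            acc["bD"] += state.b_bar * d
            acc["S2"] += s**2
            acc["D2"] += d**2
            if traj_rows is not None:
                traj_rows.append(
                    pd.DataFrame(
                        {
                            "generation": t,
                            "island": np.arange(n_islands),
                            "a_bar": state.a_bar,
                            "b_bar": state.b_bar,
                            "D": d,
                            "S": s,
                        }
                    )
                )

    island_means = pd.DataFrame(
        {
            "island": np.arange(n_islands),
            "D_i": env_state.D_i,
            "S_i": env_state.S_i,
            "time_avg_a": acc["a"] / n_rec,
            "time_avg_b": acc["b"] / n_rec,
            "time_avg_D": acc["D"] / n_rec,
            "time_avg_S": acc["S"] / n_rec,
            # per-island temporal covariances of the mean intercept with the fields
            "cov_a_S": acc["aS"] / n_rec - (acc["a"] / n_rec) * (acc["S"] / n_rec),
            "cov_a_D": acc["aD"] / n_rec - (acc["a"] / n_rec) * (acc["D"] / n_rec),
            "time_avg_bD": acc["bD"] / n_rec,
        }
    )
    return SimulationOutput(
        params=bundle,
        n_islands=n_islands,
        n_generations=n_generations,
        burn_in=burn_in,
        seed=seed,
        D_i=env_state.D_i,
        S_i=env_state.S_i,
        global_a=global_a,
        global_b=global_b,
        island_means=island_means,
        trajectories=pd.concat(traj_rows, ignore_index=True) if traj_rows else None,
    )


def summarize(output: SimulationOutput) -> dict:
    """Summary statistics of a run: global means, adaptation covariances, clines.

    Returns a dict with

    * ``global_mean_slope`` / ``global_mean_intercept`` — time-and-island
      averages after burn-in;
    * ``spatial_cov_a_S`` — across-island covariance of the time-averaged
      intercept with the spatial selection component (local adaptation);
    * ``temporal_cov_a_S`` / ``temporal_cov_a_D`` — island averages of the
      within-island temporal covariances of the mean intercept with S and D;
    * ``intercept_cline`` — regression of the time-averaged intercept on the
      island's spatial selection component ``S_i``;
    * ``plastic_cline`` — regression of the time-averaged plasticity-induced
      phenotype ``b_bar * D`` on the same axis.

    Cline regressions use the true spatial components as the regressor rather
    than finite-time averages of the assembled field: a finite time average
    still carries temporal noise, which would attenuate the regression
    (errors-in-variables) without changing what it estimates.
    """
    im = output.island_means
    if len(im) == 0:
        raise ValueError("empty simulation output")
    res = {
        "global_mean_slope": output.mean_slope,
        "global_mean_intercept": output.mean_intercept,
        "temporal_cov_a_S": float(im["cov_a_S"].mean()),
        "temporal_cov_a_D": float(im["cov_a_D"].mean()),
    }
    if len(im) > 1:
        res["spatial_cov_a_S"] = float(
            np.cov(im["time_avg_a"], im["S_i"], ddof=1)[0, 1]
        )
        s_axis = im["S_i"].to_numpy()
        if np.std(s_axis) > 0:
            res["intercept_cline"] = float(
                stats.linregress(s_axis, im["time_avg_a"]).slope
            )
            res["plastic_cline"] = float(
                stats.linregress(s_axis, im["time_avg_bD"]).slope
            )
        else:
            res["intercept_cline"] = 0.0
            res["plastic_cline"] = 0.0
    else:
        res["spatial_cov_a_S"] = 0.0
        res["intercept_cline"] = 0.0
        res["plastic_cline"] = 0.0
    return res


def slope_mc_se(output: SimulationOutput, n_batches: int = 10) -> float:
    """Monte-Carlo standard error of the time-averaged global mean slope.

    Batch-means estimate: the recorded series of across-island mean slopes is
    split into ``n_batches`` contiguous batches (long relative to the
    autocorrelation time of the slope process) and the SE of the overall mean
    is computed from the spread of batch means.
    """
    series = output.global_b
    n = series.size
    if n < 2 * n_batches:
        raise ValueError("too few recorded generations for batch-means SE")
    usable = n - n % n_batches
    batches = series[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))
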