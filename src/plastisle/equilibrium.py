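"""Analytical stochastic-equilibrium solutions for the island reaction-norm model.

At stochastic equilibrium the expected per-generation change of the island
mean intercept and slope is zero.  Treating the selection strength on the
trait as a constant ``gamma_z``, the time-averaged island means satisfy a
closed system:

* the grand mean intercept equals the optimum intercept ``A`` exactly;
* the island intercept deviation is the local optimum mismatch weighted by
  the spatial genetic-tracking factor ``g_I``
  (``a_i = g_I [B S_i - (b + b_i) D_i]``);
* the island slope balances the covariance between the cue and the local
  optimum mismatch against the cost of plasticity and the temporal tracking
  of the intercept (whose equilibrium covariance with the cue is
  ``g_T sigma2_DT [B kappa_T - b - b_i]``).

In the limit of vanishing genetic slope variance (``Gbb -> 0``) the slope
still reaches its equilibrium, spatial slope differentiation disappears, and
the global mean slope has the closed form implemented in
:func:`mean_slope_limit`: a variance-weighted average of the component
DO-regressions, discounted by genetic tracking and by the cost/benefit ratio
``gamma_b / gamma_z``.  For finite ``Gbb`` the coupled system is solved
numerically on a deterministic Gauss-Hermite quadrature grid over the joint
island environment ``(D_i, S_i)`` (:func:`solve_full_equilibrium`); the
closed-form global mean the model's second-order expansion would give is not
reproduced symbolically, the grid expectation replaces it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (
    EnvironmentParams,
    GeneticSelectionParams,
    DispersalParams,
    ParameterBundle,
    ParameterError,
    g_factor,
    gamma_b,
    gamma_z_estimate,
)

__all__ = [
    "EquilibriumSolution",
    "SlopeIndeterminateError",
    "ConvergenceError",
    "grand_mean_intercept",
    "island_intercept_deviation",
    "mean_slope_limit",
    "cov_intercept_dev_temporal",
    "temporal_adaptation",
    "spatial_adaptation",
    "island_grid",
    "solve_full_equilibrium",
]


class SlopeIndeterminateError(ZeroDivisionError):
    """The equilibrium slope is indeterminate (zero denominator).

    Happens only when plasticity is cost-free and every environmental
    variance component is fully tracked genetically — the slope is then
    neutral and has no defined equilibrium value.
    """


class ConvergenceError(RuntimeError):
    """The equilibrium solve failed to reach the requested residual."""


def grand_mean_intercept(gen: GeneticSelectionParams) -> float:
    """Equilibrium grand mean intercept: exactly the optimum intercept ``A``."""
    return gen.A


def island_intercept_deviation(gI, B, S_i, slope_i, D_i):
    """Equilibrium island intercept deviation ``a_i = gI [B S_i - slope_i D_i]``.

    ``slope_i`` is the island's total mean slope (global mean plus island
    deviation).  The bracket is the gap between the local optimum and the
    plasticity-induced phenotype; ``gI`` is the fraction of that gap closed by
    spatial genetic differentiation.  At ``gI = 1`` the mean phenotype
    ``A + a_i + slope_i * D_i`` equals the local optimum ``A + B S_i``.
    """
    return gI * (B * S_i - slope_i * D_i)


def mean_slope_limit(
    env: EnvironmentParams,
    gen: GeneticSelectionParams,
    disp: DispersalParams,
    gamma_z: float | None = None,
    gamma_z_estimator: str = "taylor",
) -> float:
    """Equilibrium global mean slope in the ``Gbb -> 0`` limit.

    ``b = B [kI (1-gI) s2DI + kT (1-gT) s2DT + kIT s2DIT]
       / [gamma_b/gamma_z + (1-gI) s2DI + (1-gT) s2DT + s2DIT]``

    with ``gI = g(alpha_I, Gaa, gamma_z)`` and ``gT = g(alpha_T, Gaa,
    gamma_z)``.  Slopes are steeper when the cost of plasticity is small, the
    capacity to genetically track fluctuations is low and cue reliability
    (the kappas) is high; spatial and temporal parameters enter symmetrically.

    ``gamma_z`` may be given directly; otherwise it is computed from
    ``gamma_z_estimator`` (see :func:`plastisle.params.gamma_z_estimate`).
    """
    if gamma_z is None:
        gamma_z = gamma_z_estimate(gen, env, gamma_z_estimator)
    if gamma_z <= 0:
        raise ParameterError(f"gamma_z must be positive, got {gamma_z}")
    gb = gamma_b(gen)
    gI = g_factor(disp.alpha_I, gen.Gaa, gamma_z)
    # alpha_T may be negative; a negative PO-regression gives no capacity to
    # track (the factor is only defined on [0, 1]), so clamp at zero.
    gT = g_factor(max(env.alpha_T, 0.0), gen.Gaa, gamma_z)
    num = gen.B * (
        env.kappa_I * (1.0 - gI) * env.sigma2_DI
        + env.kappa_T * (1.0 - gT) * env.sigma2_DT
        + env.kappa_IT * env.sigma2_DIT
    )
    den = gb / gamma_z + (1.0 - gI) * env.sigma2_DI + (1.0 - gT) * env.sigma2_DT + env.sigma2_DIT
    if den == 0.0:
        raise SlopeIndeterminateError(
            "slope indeterminate: cost-free plasticity with fully tracked environments"
        )
    return num / den


def cov_intercept_dev_temporal(gT, sigma2_DT, B, kappa_T, slope_i):
    """Equilibrium within-island temporal covariance of mean intercept with the cue.

    ``Cov_t|i(a_it, D_it) = gT sigma2_DT [B kappa_T - slope_i]`` — genetic
    tracking of temporal fluctuations fills whatever gap is left between the
    plastic response and the temporal DO-regression.
    """
    return gT * sigma2_DT * (B * kappa_T - slope_i)


def temporal_adaptation(gT, B, sigma2_ST, b_bar, kappa_T, sigma2_DT):
    """Temporal adaptation: ``Cov_t|i(a_it, S_it) = gT [B sigma2_ST - b kappa_T sigma2_DT]``."""
    return gT * (B * sigma2_ST - b_bar * kappa_T * sigma2_DT)


def spatial_adaptation(gI, B, sigma2_SI, b_bar, kappa_I, sigma2_DI):
    """Local adaptation: ``Cov_i|t(a_it, S_it) = gI [B sigma2_SI - b kappa_I sigma2_DI]``."""
    return gI * (B * sigma2_SI - b_bar * kappa_I * sigma2_DI)


def island_grid(
    env: EnvironmentParams,
    n_nodes: int = 31,
    mc_sample: int | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Representative set of island environments (D_i, S_i) with weights.

    Default: tensor Gauss-Hermite quadrature over the joint normal
    ``D_i ~ N(0, s2DI)``, ``S_i = kappa_I D_i + e``, ``e ~ N(0, s2SI -
    kappa_I^2 s2DI)`` (deterministic; degenerate dimensions collapse to a
    single node).  With ``mc_sample`` set, a seeded Monte-Carlo sample of that
    size with uniform weights is returned instead, for cross-checks.
    """
    resid = env.residual_variance("spatial")
    if mc_sample is not None:
        rng = np.random.default_rng(seed)
        d = rng.normal(0.0, np.sqrt(env.sigma2_DI), size=mc_sample)
        s = env.kappa_I * d + rng.normal(0.0, np.sqrt(max(resid, 0.0)), size=mc_sample)
        w = np.full(mc_sample, 1.0 / mc_sample)
        return d + env.D_mean, s + env.S_mean, w

    def nodes_1d(var):
        if var <= 0:
            return np.array([0.0]), np.array([1.0])
        x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
        return x * np.sqrt(var), w / w.sum()

    xd, wd = nodes_1d(env.sigma2_DI)
    xe, we = nodes_1d(max(resid, 0.0))
    d = np.repeat(xd, xe.size)
    e = np.tile(xe, xd.size)
    w = np.repeat(wd, we.size) * np.tile(we, wd.size)
    s = env.kappa_I * d + e
    return d + env.D_mean, s + env.S_mean, w


@dataclass
class EquilibriumSolution:
    """Solution of the coupled equilibrium system on an island grid.

    ``a_bar``/``b_bar`` are the global means; per-island columns of ``islands``
    give the environments, weights, intercept/slope deviations, the total
    values, the phenotype and the within-island temporal covariance of the
    intercept with the cue.
    """

    a_bar: float
    b_bar: float
    gI: float
    gT: float
    gamma_z: float
    islands: pd.DataFrame
    residual: float
    n_iterations: int
    params: ParameterBundle

    @property
    def intercept_spatial_variance(self) -> float:
        """Across-island variance of the equilibrium intercept deviations."""
        w = self.islands["weight"].to_numpy()
        a = self.islands["a_dev"].to_numpy()
        mean = float(np.sum(w * a))
        return float(np.sum(w * (a - mean) ** 2))

    def plastic_cline(self) -> float:
        """Weighted regression of the plastic phenotype ``b_i D_i`` on ``S_i`` across islands."""
        w = self.islands["weight"].to_numpy()
        s = self.islands["S_i"].to_numpy()
        bd = (self.islands["b_total"] * self.islands["D_i"]).to_numpy()
        s_mean = np.sum(w * s)
        var_s = np.sum(w * (s - s_mean) ** 2)
        if var_s == 0:
            raise ParameterError("zero spatial selection variance: cline undefined")
        cov = np.sum(w * (s - s_mean) * (bd - np.sum(w * bd)))
        return float(cov / var_s)

    def intercept_cline(self) -> float:
        """Weighted regression of the intercept deviation on ``S_i`` across islands."""
        w = self.islands["weight"].to_numpy()
        s = self.islands["S_i"].to_numpy()
        a = self.islands["a_dev"].to_numpy()
        s_mean = np.sum(w * s)
        var_s = np.sum(w * (s - s_mean) ** 2)
        if var_s == 0:
            raise ParameterError("zero spatial selection variance: cline undefined")
        cov = np.sum(w * (s - s_mean) * (a - np.sum(w * a)))
        return float(cov / var_s)

    def scalars(self) -> dict:
        return {
            "a_bar": self.a_bar,
            "b_bar": self.b_bar,
            "gI": self.gI,
            "gT": self.gT,
            "gamma_z": self.gamma_z,
            "residual": self.residual,
            "n_iterations": self.n_iterations,
        }


def solve_full_equilibrium(
    env: EnvironmentParams,
    gen: GeneticSelectionParams,
    disp: DispersalParams,
    gamma_z: float | None = None,
    gamma_z_estimator: str = "taylor",
    n_nodes: int = 31,
    mc_sample: int | None = None,
    seed: int | None = None,
    tol: float = 1e-10,
) -> EquilibriumSolution:
    """Solve the coupled equilibrium system for finite ``Gbb`` numerically.

    The defining equations (island intercept deviation, island slope,
    intercept-cue covariance, global slope as grid expectation) are jointly
    linear in the unknowns once ``gamma_z`` and the tracking factors are
    fixed, so the system is solved directly: the intercept and covariance
    equations are substituted into the slope equation, each island slope
    becomes an affine function of the global mean slope, and the grid
    expectation closes the system in one step.  The direct solve stays well
    conditioned in the ``Gbb -> 0`` limit, where the equations become nearly
    degenerate and iterative schemes stall.

    Returns an :class:`EquilibriumSolution` whose maximum relative residual of
    the original defining equations on the grid is below ``tol``.
    """
    ParameterBundle(env, gen, disp).validate()
    if gen.Gbb <= 0:
        raise ParameterError("solve_full_equilibrium requires Gbb > 0; use mean_slope_limit")
    if gamma_z is None:
        gamma_z = gamma_z_estimate(gen, env, gamma_z_estimator)
    gb = gamma_b(gen)
    aI = disp.alpha_I
    gI = g_factor(aI, gen.Gaa, gamma_z)
    gT = g_factor(max(env.alpha_T, 0.0), gen.Gaa, gamma_z)

    d_i, s_i, w = island_grid(env, n_nodes=n_nodes, mc_sample=mc_sample, seed=seed)

    a_bar = gen.A

    # The three defining equations are linear in (a_tot, cov, b_tot, b_bar).
    # Substituting the intercept and covariance equations into the slope
    # equation gives, per island node,
    #     b_tot_i = (c_i + (1 - alpha_I) b_bar) / e_i
    # with the coefficients below; the grid expectation then yields b_bar in
    # closed form.  This is exact (up to quadrature), and in particular stays
    # well conditioned as Gbb -> 0 where a naive fixed-point iteration stalls.
    e_i = aI * gen.Gbb * (
        gamma_z * (
            (1.0 - gT) * env.sigma2_DT + (1.0 - gI) * d_i**2 + env.sigma2_DIT
        )
        + gb
    ) + (1.0 - aI)
    c_i = aI * gen.Gbb * gamma_z * gen.B * (
        (1.0 - gI) * s_i * d_i
        + env.kappa_T * (1.0 - gT) * env.sigma2_DT
        + env.kappa_IT * env.sigma2_DIT
    )
    if np.any(e_i <= 0):
        raise SlopeIndeterminateError(
            "slope indeterminate: the slope equation has a non-positive denominator"
        )
    mean_inv = float(np.sum(w * (1.0 / e_i)))
    mean_c = float(np.sum(w * (c_i / e_i)))
    pivot = 1.0 - (1.0 - aI) * mean_inv
    if pivot <= 0:
        raise SlopeIndeterminateError(
            "slope indeterminate: cost-free plasticity with fully tracked environments"
        )
    b_bar = mean_c / pivot
    b_tot = (c_i + (1.0 - aI) * b_bar) / e_i

    a_tot = a_bar + island_intercept_deviation(gI, gen.B, s_i, b_tot, d_i)
    cov = cov_intercept_dev_temporal(gT, env.sigma2_DT, gen.B, env.kappa_T, b_tot)

    # verify the original (un-substituted) defining equations
    slope_num = aI * gen.Gbb * (
        gamma_z * d_i * (gen.A + gen.B * s_i - a_tot)
        + gamma_z * gen.B * (env.kappa_T * env.sigma2_DT + env.kappa_IT * env.sigma2_DIT)
        - gamma_z * cov
    ) + (1.0 - aI) * b_bar
    slope_den = aI * gen.Gbb * (
        gamma_z * (env.sigma2_DT + d_i**2 + env.sigma2_DIT) + gb
    ) + (1.0 - aI)
    r_a = a_tot - (a_bar + island_intercept_deviation(gI, gen.B, s_i, b_tot, d_i))
    r_c = cov - cov_intercept_dev_temporal(gT, env.sigma2_DT, gen.B, env.kappa_T, b_tot)
    r_b = b_tot - slope_num / slope_den
    r_m = b_bar - float(np.sum(w * b_tot))
    scale = 1.0 + max(abs(b_bar), float(np.max(np.abs(b_tot))), abs(a_bar))
    resid = max(
        np.max(np.abs(r_a)), np.max(np.abs(r_c)), np.max(np.abs(r_b)), abs(r_m)
    ) / scale
    if not resid < tol:
        raise ConvergenceError(
            f"equilibrium residual {resid:g} exceeds tolerance {tol:g}"
        )
    it = 1
    islands = pd.DataFrame(
        {
            "D_i": d_i,
            "S_i": s_i,
            "weight": w,
            "a_dev": a_tot - a_bar,
            "b_dev": b_tot - b_bar,
            "a_total": a_tot,
            "b_total": b_tot,
            "phenotype": a_tot + b_tot * d_i,
            "optimum": gen.A + gen.B * s_i,
            "cov_a_D": cov,
        }
    )
    return EquilibriumSolution(
        a_bar=a_bar,
        b_bar=b_bar,
        gI=gI,
        gT=gT,
        gamma_z=gamma_z,
        islands=islands,
        residual=float(resid),
        n_iterations=it,
        params=ParameterBundle(env, gen, disp),
    )
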