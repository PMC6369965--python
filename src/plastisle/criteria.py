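"""Analytical conditions for spatial hyperplasticity and negative plasticity.

Along the spatial gradient the plasticity-induced phenotype is ``b * D_i``,
and its regression on the environment of selection ``S_i`` is the plastic
cline.  Plasticity is *hyperplastic* in space when that cline is steeper than
the environmental sensitivity of the optimum ``B`` (for ``B > 0``), and
*negative* when the cline has the opposite sign to ``B``.  Both phenomena can
be adaptive outcomes of joint spatio-temporal fluctuation: plasticity that
evolves to cope with temporal fluctuations can overshoot or oppose the
spatial optimum gradient, with spatial genetic differentiation compensating
(counter-gradient variation).

The closed-form conditions below are derived in the ``Gbb -> 0``
approximation with zero interaction variance, and are algebraically
equivalent to comparing the closed-form plastic cline with ``B`` or with 0 —
an equivalence enforced by the test suite over random parameter draws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import json

import numpy as np

from .params import (
    DispersalParams,
    EnvironmentParams,
    GeneticSelectionParams,
    ParameterError,
    g_factor,
    gamma_b,
    gamma_z_estimate,
)
from .equilibrium import mean_slope_limit

__all__ = [
    "ClineDiagnostics",
    "spatial_cue_correlation",
    "plastic_cline_slope",
    "hyperplasticity_condition",
    "negative_plasticity_condition",
    "swap_space_time",
    "diagnose",
]


def spatial_cue_correlation(env: EnvironmentParams) -> float:
    """Spatial correlation between the environments of development and selection.

    ``r_I = kappa_I * sigma_DI / sigma_SI``; must lie in [-1, 1] for any
    valid parameter set.
    """
    if env.sigma2_SI <= 0:
        raise ParameterError("zero spatial selection variance: r_I undefined")
    return env.kappa_I * np.sqrt(env.sigma2_DI / env.sigma2_SI)


def _check_preconditions(env: EnvironmentParams, gen: GeneticSelectionParams) -> None:
    if not gen.B > 0:
        raise ParameterError(f"conditions derived for B > 0, got B={gen.B}")
    if env.kappa_I == 0:
        raise ParameterError("kappa_I = 0: the plastic cline is flat, conditions undefined")
    if env.sigma2_DIT != 0 or env.sigma2_SIT != 0:
        raise ParameterError(
            "conditions derived for zero interaction variance "
            f"(sigma2_DIT={env.sigma2_DIT}, sigma2_SIT={env.sigma2_SIT})"
        )


def plastic_cline_slope(
    env: EnvironmentParams,
    gen: GeneticSelectionParams,
    disp: DispersalParams,
    gamma_z: float | None = None,
    gamma_z_estimator: str = "taylor",
) -> float:
    """Closed-form regression of the plastic phenotype ``b D_i`` on ``S_i``.

    ``b * kappa_I * sigma2_DI / sigma2_SI`` with the global mean slope ``b``
    from the ``Gbb -> 0`` closed form.
    """
    if env.sigma2_SI <= 0:
        raise ParameterError("zero spatial selection variance: cline undefined")
    b_bar = mean_slope_limit(
        env, gen, disp, gamma_z=gamma_z, gamma_z_estimator=gamma_z_estimator
    )
    return b_bar * env.kappa_I * env.sigma2_DI / env.sigma2_SI


def _tracking_factors(env, gen, disp, gamma_z, gamma_z_estimator):
    if gamma_z is None:
        gamma_z = gamma_z_estimate(gen, env, gamma_z_estimator)
    gI = g_factor(disp.alpha_I, gen.Gaa, gamma_z)
    gT = g_factor(max(env.alpha_T, 0.0), gen.Gaa, gamma_z)
    return gamma_z, gI, gT


def hyperplasticity_condition(
    env: EnvironmentParams,
    gen: GeneticSelectionParams,
    disp: DispersalParams,
    gamma_z: float | None = None,
    gamma_z_estimator: str = "taylor",
) -> bool:
    """True iff the spatial plastic cline is steeper than the optimum's (``> B``).

    Closed form (``B > 0``, no interaction variance):

    ``-(1-gI) s2DI (1 - rI^2)  >  gamma_b/gamma_z + (1-gT) s2DT (1 - (kT/kI) rI^2)``

    Hyperplasticity needs genetic tracking to be harder in time than in space
    and the cue-optimum regression steeper in time than in space, with some
    spatial cue-optimum association (``rI^2 > 0``).
    """
    _check_preconditions(env, gen)
    gamma_z, gI, gT = _tracking_factors(env, gen, disp, gamma_z, gamma_z_estimator)
    rI2 = spatial_cue_correlation(env) ** 2
    lhs = -(1.0 - gI) * env.sigma2_DI * (1.0 - rI2)
    rhs = gamma_b(gen) / gamma_z + (1.0 - gT) * env.sigma2_DT * (
        1.0 - (env.kappa_T / env.kappa_I) * rI2
    )
    return bool(lhs > rhs)


def negative_plasticity_condition(
    env: EnvironmentParams,
    gen: GeneticSelectionParams,
    disp: DispersalParams,
    gamma_z: float | None = None,
    gamma_z_estimator: str = "taylor",
) -> bool:
    """True iff the spatial plastic cline is opposite in sign to ``B`` (``< 0``).

    Closed form: ``(1-gI)/(1-gT) < -(kT/kI) (s2DT/s2DI)`` — requires the two
    cue-optimum regressions to differ in sign, with the temporal association
    strong relative to the capacity to adapt in time.
    """
    _check_preconditions(env, gen)
    if env.sigma2_DI <= 0:
        raise ParameterError("zero spatial cue variance: condition undefined")
    gamma_z, gI, gT = _tracking_factors(env, gen, disp, gamma_z, gamma_z_estimator)
    if gT >= 1.0:
        raise ParameterError("gT = 1: condition undefined (perfect temporal tracking)")
    lhs = (1.0 - gI) / (1.0 - gT)
    rhs = -(env.kappa_T / env.kappa_I) * (env.sigma2_DT / env.sigma2_DI)
    return bool(lhs < rhs)


def swap_space_time(
    env: EnvironmentParams, disp: DispersalParams
) -> tuple[EnvironmentParams, DispersalParams]:
    """Exchange the spatial and temporal parameter blocks.

    ``(alpha_I, kappa_I, s2DI, s2SI) <-> (alpha_T, kappa_T, s2DT, s2ST)``.
    Applying the spatial hyperplasticity / negative-plasticity conditions to
    the swapped bundle evaluates the corresponding *temporal* conditions.  The
    swapped philopatry must be a probability, so ``alpha_T`` must lie in
    [0, 1].
    """
    if not 0.0 <= env.alpha_T <= 1.0:
        raise ParameterError(
            f"cannot swap: alpha_T={env.alpha_T} is not a valid philopatry probability"
        )
    new_env = replace(
        env,
        kappa_I=env.kappa_T,
        kappa_T=env.kappa_I,
        sigma2_DI=env.sigma2_DT,
        sigma2_DT=env.sigma2_DI,
        sigma2_SI=env.sigma2_ST,
        sigma2_ST=env.sigma2_SI,
        alpha_T=disp.alpha_I,
    )
    new_disp = DispersalParams(m=1.0 - env.alpha_T)
    return new_env.validate(), new_disp.validate()


@dataclass(frozen=True)
class ClineDiagnostics:
    """Spatial cline diagnostics for one parameter set."""

    r_I: float
    plastic_cline: float
    mean_slope: float
    hyperplastic: bool
    negative_plastic: bool
    gamma_z: float
    gamma_z_estimator: str

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def diagnose(
    env: EnvironmentParams,
    gen: GeneticSelectionParams,
    disp: DispersalParams,
    gamma_z_estimator: str = "taylor",
) -> ClineDiagnostics:
    """Evaluate the cline and both conditions for one parameter set."""
    gamma_z = gamma_z_estimate(gen, env, gamma_z_estimator)
    return ClineDiagnostics(
        r_I=float(spatial_cue_correlation(env)),
        plastic_cline=float(plastic_cline_slope(env, gen, disp, gamma_z=gamma_z)),
        mean_slope=float(mean_slope_limit(env, gen, disp, gamma_z=gamma_z)),
        hyperplastic=hyperplasticity_condition(env, gen, disp, gamma_z=gamma_z),
        negative_plastic=negative_plasticity_condition(env, gen, disp, gamma_z=gamma_z),
        gamma_z=float(gamma_z),
        gamma_z_estimator=gamma_z_estimator,
    )
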