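import numpy as np
import pytest

from plastisle import (
    DispersalParams,
    EnvironmentParams,
    GeneticSelectionParams,
    ParameterBundle,
    ParameterError,
    validate_params,
)


@pytest.fixture
def unit_gen():
    """Unit genetic/environmental variances, optimum through the origin: the shared scenario set."""
    return GeneticSelectionParams(
        Gaa=1, Gbb=1, Eaa=1, Ebb=1, A=0.0, B=1.0, omega_z=1.0, omega_b=3.0
    )


@pytest.fixture
def fig3_bundle():
    """Opposed spatial/temporal cue-optimum regressions, unit variances."""
    env = EnvironmentParams(
        sigma2_DI=1, sigma2_SI=1, sigma2_DT=1, sigma2_ST=1,
        kappa_I=0.8, kappa_T=-0.8, alpha_T=0.5,
    )
    return ParameterBundle(env, GeneticSelectionParams(), DispersalParams(m=0.5)).validate()


def random_valid_bundle(rng, require_positive_B=True, allow_interaction=False):
    """One random parameter bundle satisfying every invariant.

    S variances are drawn at or above the kappa^2 * D-variance floor so the
    residual-variance invariant holds by construction.
    """
    while True:
        s2_DI = rng.uniform(0.01, 3.0)
        s2_DT = rng.uniform(0.01, 3.0)
        s2_DIT = rng.uniform(0.0, 1.0) if allow_interaction else 0.0
        kI = rng.uniform(-2.0, 2.0)
        kT = rng.uniform(-2.0, 2.0)
        kIT = rng.uniform(-1.0, 1.0) if allow_interaction else 0.0
        env = EnvironmentParams(
            sigma2_DI=s2_DI,
            sigma2_DT=s2_DT,
            sigma2_DIT=s2_DIT,
            sigma2_SI=kI**2 * s2_DI * rng.uniform(1.0, 3.0) + rng.uniform(0.01, 1.0),
            sigma2_ST=kT**2 * s2_DT * rng.uniform(1.0, 3.0) + rng.uniform(0.01, 1.0),
            sigma2_SIT=kIT**2 * s2_DIT * rng.uniform(1.0, 3.0) + (0.1 if allow_interaction else 0.0),
            kappa_I=kI,
            kappa_T=kT,
            kappa_IT=kIT,
            alpha_T=rng.uniform(0.0, 0.99),
        )
        gen = GeneticSelectionParams(
            Gaa=rng.uniform(0.1, 2.0),
            Gbb=rng.uniform(0.0, 2.0),
            Eaa=rng.uniform(0.1, 2.0),
            Ebb=rng.uniform(0.0, 2.0),
            A=rng.normal(0.0, 1.0),
            B=rng.uniform(0.1, 2.0) if require_positive_B else rng.normal(0.0, 1.0),
            omega_z=rng.uniform(0.5, 20.0),
            omega_b=None if rng.random() < 0.2 else rng.uniform(1.0, 10.0),
        )
        disp = DispersalParams(m=rng.uniform(0.0, 1.0))
        try:
            return validate_params(env, gen, disp)
        except ParameterError:  # pragma: no cover - construction avoids this
            continue
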