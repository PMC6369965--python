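"""Model parameters and the scalar selection/tracking quantities derived from them.

The model describes a metapopulation of islands in which a quantitative trait
develops as a linear reaction norm, ``z = a + b * D``, to an environment of
development ``D``, while stabilizing selection pulls the phenotype toward an
optimum ``theta = A + B * S`` set by an environment of selection ``S``.  Both
environments decompose into purely spatial, purely temporal and
island-by-generation (interaction) components; the two environments are
linearly associated within each component through regression coefficients
``kappa`` (cue reliability), and the temporal components follow a stationary
AR(1) process with autocorrelation ``alpha_T``.

Three groups of parameters are kept in frozen dataclasses:

* :class:`EnvironmentParams` — component variances, cross-regressions and
  temporal autocorrelation of the two environmental fields.
* :class:`GeneticSelectionParams` — within-island genetic/environmental
  variances of reaction-norm intercept and slope, the optimum, and the widths
  of the Gaussian fitness functions on the trait and on the slope.
* :class:`DispersalParams` — the gamete migration rate ``m`` and its
  complement, the philopatry probability ``alpha_I = 1 - m``.

The functions at module level compute the quantities reused everywhere:
the strength of stabilizing selection on the slope (:func:`gamma_b`), three
estimators of the strength of stabilizing selection on the trait
(:func:`gamma_z_constant`, :func:`gamma_z_taylor`, :func:`gamma_z_plugin`) and
the genetic tracking factor (:func:`g_factor`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

__all__ = [
    "EnvironmentParams",
    "GeneticSelectionParams",
    "DispersalParams",
    "ParameterBundle",
    "ParameterError",
    "TaylorExpansionError",
    "validate_params",
    "gamma_b",
    "gamma_z_constant",
    "gamma_z_taylor",
    "gamma_z_plugin",
    "gamma_z_estimate",
    "expected_D2",
    "g_factor",
]

#: Names of the three variance components of each environmental field.
COMPONENTS = ("spatial", "temporal", "interaction")


class ParameterError(ValueError):
    """A model parameter violates one of its invariants."""


class TaylorExpansionError(ArithmeticError):
    """The Taylor estimate of the selection strength is non-positive.

    Raised instead of returning an invalid (non-positive) selection strength
    when the expansion breaks down under strong selection on the trait or
    wide environmental fluctuations.
    """


@dataclass(frozen=True)
class EnvironmentParams:
    """Variance/regression structure of the environments of development and selection.

    Parameters
    ----------
    sigma2_DI, sigma2_DT, sigma2_DIT
        Variances of the spatial, temporal and interaction components of the
        environment of development (environment units squared).
    sigma2_SI, sigma2_ST, sigma2_SIT
        Same for the environment of selection.
    kappa_I, kappa_T, kappa_IT
        Regression of each component of S on the matching component of D
        (dimensionless).  ``B * kappa`` is the DO-regression — the regression
        of the optimum on the developmental cue — in that dimension.
    alpha_T
        Lag-one autocorrelation of the temporal components, shared by D and S
        (the temporal parent-offspring regression).  Must satisfy
        ``|alpha_T| < 1`` for stationarity.
    D_mean, S_mean
        Grand means of the two fields (default 0).
    """

    sigma2_DI: float = 1.0
    sigma2_DT: float = 1.0
    sigma2_DIT: float = 0.0
    sigma2_SI: float = 1.0
    sigma2_ST: float = 1.0
    sigma2_SIT: float = 0.0
    kappa_I: float = 0.0
    kappa_T: float = 0.0
    kappa_IT: float = 0.0
    alpha_T: float = 0.0
    D_mean: float = 0.0
    S_mean: float = 0.0

    def validate(self) -> "EnvironmentParams":
        for name in (
            "sigma2_DI", "sigma2_DT", "sigma2_DIT",
            "sigma2_SI", "sigma2_ST", "sigma2_SIT",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"negative variance: {name}={getattr(self, name)}")
        if not abs(self.alpha_T) < 1:
            raise ParameterError(
                f"non-stationary temporal process: |alpha_T|={abs(self.alpha_T)} >= 1"
            )
        for comp, kappa, s2d, s2s in (
            ("I", self.kappa_I, self.sigma2_DI, self.sigma2_SI),
            ("T", self.kappa_T, self.sigma2_DT, self.sigma2_ST),
            ("IT", self.kappa_IT, self.sigma2_DIT, self.sigma2_SIT),
        ):
            if kappa**2 * s2d > s2s:
                raise ParameterError(
                    f"negative residual variance of S given D in component {comp}: "
                    f"kappa_{comp}^2 * sigma2_D{comp} = {kappa**2 * s2d:g} "
                    f"> sigma2_S{comp} = {s2s:g}"
                )
        return self

    def residual_variance(self, component: str) -> float:
        """Residual variance of the S component after regression on D (``sigma2_S - kappa^2 sigma2_D``)."""
        kappa, s2d, s2s = {
            "spatial": (self.kappa_I, self.sigma2_DI, self.sigma2_SI),
            "temporal": (self.kappa_T, self.sigma2_DT, self.sigma2_ST),
            "interaction": (self.kappa_IT, self.sigma2_DIT, self.sigma2_SIT),
        }[component]
        return s2s - kappa**2 * s2d


@dataclass(frozen=True)
class GeneticSelectionParams:
    """Reaction-norm variance components, the optimum, and fitness-function widths.

    ``omega_b = None`` is the explicit no-cost sentinel: plasticity carries no
    intrinsic cost and the strength of selection on the slope is exactly zero,
    rather than a large-omega approximation.
    """

    Gaa: float = 1.0
    Gbb: float = 1.0
    Eaa: float = 1.0
    Ebb: float = 1.0
    A: float = 0.0
    B: float = 1.0
    omega_z: float = 1.0
    omega_b: float | None = 3.0

    def validate(self) -> "GeneticSelectionParams":
        for name in ("Gaa", "Gbb", "Eaa", "Ebb"):
            if getattr(self, name) < 0:
                raise ParameterError(f"negative variance: {name}={getattr(self, name)}")
        if not self.omega_z > 0:
            raise ParameterError(f"non-positive fitness width: omega_z={self.omega_z}")
        if self.omega_b is not None and not self.omega_b > 0:
            raise ParameterError(
                f"non-positive fitness width: omega_b={self.omega_b} "
                "(use omega_b=None for a cost-free slope)"
            )
        return self

    @property
    def Pbb(self) -> float:
        """Within-island phenotypic variance of the slope (constant)."""
        return self.Gbb + self.Ebb


@dataclass(frozen=True)
class DispersalParams:
    """Gamete migration rate and the spatial parent-offspring regression.

    ``alpha_I = 1 - m`` is the philopatry probability: the correlation between
    the spatial environment components of parent and offspring, mirroring the
    temporal autocorrelation ``alpha_T``.
    """

    m: float = 0.5

    def validate(self) -> "DispersalParams":
        if not 0.0 <= self.m <= 1.0:
            raise ParameterError(f"migration rate outside [0, 1]: m={self.m}")
        return self

    @property
    def alpha_I(self) -> float:
        return 1.0 - self.m


@dataclass(frozen=True)
class ParameterBundle:
    """A validated triple of environment, genetic/selection and dispersal parameters."""

    env: EnvironmentParams = field(default_factory=EnvironmentParams)
    gen: GeneticSelectionParams = field(default_factory=GeneticSelectionParams)
    disp: DispersalParams = field(default_factory=DispersalParams)

    def validate(self) -> "ParameterBundle":
        self.env.validate()
        self.gen.validate()
        self.disp.validate()
        return self

    def replace(self, **kwargs) -> "ParameterBundle":
        """Return a bundle with individual *field-level* parameters replaced.

        Keys are routed to whichever of the three dataclasses owns them, e.g.
        ``bundle.replace(m=0.1, kappa_T=-0.8, omega_z=20)``.
        """
        env_kw, gen_kw, disp_kw = {}, {}, {}
        env_names = {f.name for f in fields(EnvironmentParams)}
        gen_names = {f.name for f in fields(GeneticSelectionParams)}
        disp_names = {f.name for f in fields(DispersalParams)}
        for key, value in kwargs.items():
            if key in env_names:
                env_kw[key] = value
            elif key in gen_names:
                gen_kw[key] = value
            elif key in disp_names:
                disp_kw[key] = value
            else:
                raise ParameterError(f"unknown parameter: {key}")
        return ParameterBundle(
            env=replace(self.env, **env_kw) if env_kw else self.env,
            gen=replace(self.gen, **gen_kw) if gen_kw else self.gen,
            disp=replace(self.disp, **disp_kw) if disp_kw else self.disp,
        )

    def to_dict(self) -> dict:
        d = {}
        for part in (self.env, self.gen, self.disp):
            for f in fields(part):
                d[f.name] = getattr(part, f.name)
        return d


def validate_params(
    env: EnvironmentParams,
    gen: GeneticSelectionParams,
    disp: DispersalParams,
) -> ParameterBundle:
    """Validate all parameter invariants and return them as a bundle.

    Raises :class:`ParameterError` naming the first violated invariant.
    """
    return ParameterBundle(env=env, gen=gen, disp=disp).validate()


def gamma_b(gen: GeneticSelectionParams) -> float:
    """Strength of stabilizing selection on the slope, ``1 / (omega_b^2 + Pbb)``.

    The slope fitness function is Gaussian with optimum 0, so any plasticity
    is costly in proportion to ``gamma_b``.  Returns exactly 0 for the
    no-cost sentinel ``omega_b=None``.
    """
    if gen.omega_b is None:
        return 0.0
    return 1.0 / (gen.omega_b**2 + gen.Pbb)


def gamma_z_constant(gen: GeneticSelectionParams) -> float:
    """Selection strength on the trait assuming no variance in slopes.

    ``1 / (omega_z^2 + Gaa + Eaa)`` — the phenotypic variance with the
    slope-variance contribution ``(Gbb+Ebb) D^2`` dropped entirely.
    """
    return 1.0 / (gen.omega_z**2 + gen.Gaa + gen.Eaa)


def gamma_z_taylor(gen: GeneticSelectionParams, ED2: float) -> float:
    """Expected selection strength on the trait via a third-order Taylor expansion.

    The island- and time-specific strength is ``1 / (c + v D^2)`` with
    ``c = omega_z^2 + Gaa + Eaa`` and ``v = Gbb + Ebb``.  Expanding around
    ``D = 0`` to third order (odd terms vanish for a mean-zero cue) and taking
    expectations gives ``E[gamma] ~= 1/c - (v / c^2) * ED2``.

    Parameters
    ----------
    ED2
        Expectation of the squared (mean-centred) environment of development,
        ``E[D^2]``.

    Raises
    ------
    TaylorExpansionError
        If the estimate is non-positive, i.e. the expansion is invalid under
        strong stabilizing selection or wide environmental fluctuations.
    """
    if ED2 < 0:
        raise ParameterError(f"negative second moment: ED2={ED2}")
    c = gen.omega_z**2 + gen.Gaa + gen.Eaa
    v = gen.Gbb + gen.Ebb
    estimate = 1.0 / c - (v / c**2) * ED2
    if estimate <= 0:
        raise TaylorExpansionError(
            f"Taylor estimate non-positive ({estimate:g}); the expansion of the "
            "selection strength is invalid for these parameters"
        )
    return estimate


def gamma_z_plugin(gen: GeneticSelectionParams, ED2: float) -> float:
    """Selection strength on the trait with the phenotypic variance taken at ``E[D^2]``.

    ``1 / (omega_z^2 + Gaa + Eaa + (Gbb+Ebb) * ED2)`` — the slope-variance
    contribution is retained but evaluated at the expected squared cue.
    Unlike the Taylor form this is positive for all parameter values, which
    makes it the practical choice under strong selection (small ``omega_z``)
    where the expansion breaks down.
    """
    if ED2 < 0:
        raise ParameterError(f"negative second moment: ED2={ED2}")
    return 1.0 / (gen.omega_z**2 + gen.Gaa + gen.Eaa + (gen.Gbb + gen.Ebb) * ED2)


#: Named gamma_z estimators selectable throughout the analytic modules.
GAMMA_Z_ESTIMATORS = ("constant", "taylor", "plugin")


def expected_D2(env: EnvironmentParams) -> float:
    """Stationary expectation of the squared mean-centred environment of development.

    The three components are independent, so
    ``E[(D - D_mean)^2] = sigma2_DI + sigma2_DT + sigma2_DIT``.
    """
    return env.sigma2_DI + env.sigma2_DT + env.sigma2_DIT


def gamma_z_estimate(
    gen: GeneticSelectionParams,
    env: EnvironmentParams,
    estimator: str = "taylor",
) -> float:
    """Evaluate a named gamma_z estimator at the stationary ``E[D^2]`` of *env*."""
    if estimator == "constant":
        return gamma_z_constant(gen)
    if estimator == "taylor":
        return gamma_z_taylor(gen, expected_D2(env))
    if estimator == "plugin":
        return gamma_z_plugin(gen, expected_D2(env))
    raise ParameterError(
        f"unknown gamma_z estimator {estimator!r}; choose from {GAMMA_Z_ESTIMATORS}"
    )


def g_factor(alpha: float, Gaa: float, gamma_z: float) -> float:
    """Capacity to genetically track environmental fluctuations, in [0, 1].

    ``g = alpha Gaa gamma_z / (alpha Gaa gamma_z + 1 - alpha)`` where ``alpha``
    is the parent-offspring regression of the environment (philopatry in
    space, AR(1) autocorrelation in time).  ``g = 0`` means island mean
    breeding values cannot follow fluctuations in the optimum at all;
    ``g = 1`` means they track it completely.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError(f"PO-regression outside [0, 1]: alpha={alpha}")
    if Gaa < 0 or gamma_z < 0:
        raise ParameterError("Gaa and gamma_z must be non-negative")
    num = alpha * Gaa * gamma_z
    den = num + (1.0 - alpha)
    if den == 0.0:
        # alpha == 1 with Gaa * gamma_z == 0: no migration but also no response;
        # the tracking factor is conventionally 0 (nothing can be tracked).
        return 0.0
    return num / den
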