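# plastisle

Evolution of phenotypic plasticity on an island metapopulation whose
environment fluctuates jointly in **space and time**.

`plastisle` is a research tool for quantitative geneticists and evolutionary
ecologists studying when organisms should respond to environmental cues
plastically, when they should adapt genetically, and when the interplay of
the two produces the counter-intuitive outcomes seen in reciprocal-transplant
studies: *hyperplasticity* (a plastic response steeper than the optimum's
cline) and *negative plasticity* (a response opposed to it), compensated by
*counter-gradient* genetic variation.

## The model

A trait develops as a linear reaction norm to an environment of development
*D*:

    z = a + b·D

with genetic and environmental variance in both intercept (*G_aa*, *E_aa*)
and slope (*G_bb*, *E_bb*).  Gaussian stabilizing selection (width ω_z) pulls
the phenotype toward an optimum set by an environment of selection *S*,

    θ = A + B·S,

while a second Gaussian function (width ω_b, optimum 0) makes plasticity
intrinsically costly.  Both environments decompose into island (spatial),
generation (temporal, stationary AR(1) with autocorrelation α_T) and
island-by-generation components, with per-component regressions κ_I, κ_T,
κ_I·T of *S* on *D* (cue reliability).  Gametes migrate between islands with
probability *m*; philopatry α_I = 1 − m plays exactly the role in space that
α_T plays in time — both are parent–offspring regressions of the environment,
and both set the **genetic tracking capacity**

    g = α·G_aa·γ_z / (α·G_aa·γ_z + 1 − α),  γ_z = 1/(ω_z² + P_zz).

In the small-*G_bb* limit the equilibrium mean slope has the closed,
space–time-symmetric form

    b̄ = B·[κ_I(1−g_I)σ²_DI + κ_T(1−g_T)σ²_DT + κ_I·T σ²_DI·T]
        ─────────────────────────────────────────────────────
        γ_b/γ_z + (1−g_I)σ²_DI + (1−g_T)σ²_DT + σ²_DI·T

Plasticity is steep when cues are reliable, costs are low and genetic
tracking is hard.  When tracking capacity and cue reliability differ between
space and time, the slope that evolves for one dimension can be maladaptive
in the other, producing hyperplastic or negative spatial clines.

The package provides:

* `environment` — seeded generator for the separable space-time fields;
* `simulate` — the stochastic recursion on island means (development,
  Gaussian selection via the multivariate breeder's equation, migration);
* `equilibrium` — the closed forms above plus an exact grid solver for the
  coupled finite-*G_bb* equilibrium system;
* `criteria` — closed-form hyperplasticity / negative-plasticity conditions,
  provably equivalent to comparing the plastic cline with *B* and 0;
* `presets` / CLI — the reference figure scenarios as reproducible tables.

## Worked example

Opposed cue reliabilities in space (κ_I = 0.8) and time (κ_T = −0.8) with
near-complete philopatry (m = 0.01):

```sh
plastisle criteria --kappa-I 0.8 --kappa-T -0.8 --alpha-T 0.5 --m 0.01 --gamma-z plugin
```

```json
{
  "gamma_z": 0.14285714285714285,
  "gamma_z_estimator": "plugin",
  "hyperplastic": false,
  "mean_slope": -0.4102759276879162,
  "negative_plastic": true,
  "plastic_cline": -0.328220742150333,
  "r_I": 0.8
}
```

The equilibrium mean slope is negative (−0.41): plasticity evolves to track
the temporal fluctuations, whose cue-optimum regression is negative, and is
therefore *maladaptive in space* — the plastic cline (−0.33) runs against the
optimum cline (B = 1), which the `negative_plastic` flag confirms.  Spatial
genetic differentiation compensates (counter-gradient variation); a full
simulation (`plastisle figure figure4a`) shows the intercept cline at ≈ +1.25
against the plastic cline of ≈ −0.24.

The analytics can be checked against the stochastic simulator directly:

```python
import plastisle as pl

env = pl.EnvironmentParams(kappa_I=0.8, kappa_T=0.8, alpha_T=0.5)
gen = pl.GeneticSelectionParams(omega_z=20.0)          # weak selection
disp = pl.DispersalParams(m=0.3)
print(pl.mean_slope_limit(env, gen, disp, gamma_z_estimator="taylor"))
out = pl.run_simulation(pl.ParameterBundle(env, gen, disp),
                        n_islands=200, n_generations=3000, burn_in=1000, seed=1)
print(out.mean_slope, pl.slope_mc_se(out))
```

prints an analytic slope of `0.041` and a simulated time-and-island average
of `0.0379 ± 0.001` — the closed form is accurate when stabilizing selection
is weak.

## Command line

```
plastisle simulate     # stochastic run -> island/global summaries (CSV + JSON)
plastisle equilibrium  # coupled equilibrium solve on an island grid
plastisle criteria     # cline diagnostics as JSON
plastisle check-env    # empirical vs target environment moments
plastisle figure NAME  # figure1_left ... figure4b preset tables
```

All parameters can come from a flat YAML/JSON config (`--config`) with CLI
flags overriding; every stochastic entry point takes `--seed` and is
bit-reproducible.

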