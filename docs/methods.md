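# Methods

## Model and assumptions

The population is an island metapopulation: many islands, each of infinite
size, exchanging gametes at rate *m* per generation.  Individuals carry a
linear reaction norm `z = a + b·D` whose intercept and slope each have
genetic and environmental components; within-island variances (G_aa, E_aa,
G_bb, E_bb) are constants of the model, intercepts and slopes are
uncorrelated, and only island *means* evolve.  Because islands are infinite
there is no drift, and fertilization and gametogenesis leave means unchanged;
the explicit per-generation events are environment advance, development,
selection and migration, with state recorded after migration.

Fitness is the product of two independent Gaussian functions: one on the
phenotype with optimum `θ = A + B·S` and width ω_z, one on the slope with
optimum 0 and width ω_b (a maintenance cost of plasticity).  Selection moves
island means along the gradient of mean log fitness (the multivariate
breeder's-equation update):

    Δā = G_aa·γ_z·(θ − z̄)
    Δb̄ = G_bb·[γ_z·D·(θ − z̄) − γ_b·b̄]

with `γ_z = 1/(ω_z² + P_zz)`, `P_zz = G_aa + E_aa + (G_bb + E_bb)·D²` and
`γ_b = 1/(ω_b² + G_bb + E_bb)`.  The simulator evaluates γ_z exactly per
island and generation; the analytical theory holds it constant, and the
simulator exists to quantify that approximation.  Selection on the
phenotypic *variance* (bet-hedging) is outside the model's scope.

Both environments decompose as `X_it = X̄ + X_i + X_t + X_i·t`.  Spatial
components are iid normal across islands and frozen for a run; temporal
components follow a stationary bivariate AR(1) with common autocorrelation
α_T; interaction components are redrawn independently each generation (their
parent-offspring correlation is zero, so they can never be tracked
genetically).  Within each component, S regresses on D with coefficient κ
and a residual variance fixed by the stated marginal variance of S — the
unique bivariate normal with the stated moments.  Normality itself is an
assumption: the model only pins down second moments, and the linear
regression structure makes the Gaussian the natural completion.  Temporal
components are initialized from their stationary distribution, so the
environment needs no burn-in.

## Equilibrium theory

At stochastic equilibrium the expected change of each island mean is zero.
With γ_z constant, the time-averaged means satisfy a closed system: the grand
mean intercept equals A exactly; the island intercept deviation is
`g_I·[B·S_i − (b̄+b̄_i)·D_i]`; the intercept-cue temporal covariance is
`g_T·σ²_DT·[B·κ_T − b̄ − b̄_i]`; and the island slope balances cue-optimum
covariance against cost and tracking.  The tracking factors
`g = α·G_aa·γ_z/(α·G_aa·γ_z + 1 − α)` are the model's central objects: the
PO-regression α (philopatry in space, autocorrelation in time) enters space
and time identically.  A negative α_T is treated as zero tracking capacity
(the factor is defined on [0, 1]).

In the limit G_bb → 0 the global mean slope has the closed form shown in the
README, slope differentiation between islands vanishes, and the temporal and
spatial adaptation covariances become `g·[B·σ²_S − b̄·κ·σ²_D]` per dimension.

For finite G_bb the coupled system is solved numerically over a
deterministic tensor Gauss–Hermite grid (default 31 nodes per dimension) on
the joint island environment (D_i, S_i); a seeded Monte-Carlo island sample
is available as a cross-check.  Because the defining equations are jointly
linear in the unknowns once γ_z and the tracking factors are fixed, the
solver substitutes the intercept and covariance equations into the slope
equation and closes the system with the grid expectation in a single exact
linear solve, then verifies the residuals of the original equations
(reported; well below 1e-10).  A damped fixed-point iteration was tried
first and abandoned: as G_bb → 0 the equations become nearly degenerate and
an iterate can satisfy any residual tolerance while the global slope is far
from the solution, whereas the direct solve is exact and stays conditioned
in the limit (it reproduces the closed form at G_bb = 1e-8 to ~1e-9).

The exact closed-form expression for the global mean slope at finite G_bb
(a second-order expansion over islands) is not reproduced here; the grid
expectation replaces it and is validated against both the G_bb → 0 closed
form and the stochastic simulator.

## γ_z conventions

Three estimators of the constant selection strength are provided, matching
the conventions used across the figure scenarios:

* `constant` — `1/(ω_z² + G_aa + E_aa)`: slope variance ignored;
* `taylor` — `1/c − (v/c²)·E[D²]` with `c = ω_z² + G_aa + E_aa`,
  `v = G_bb + E_bb`: third-order expansion of `1/(c + v·D²)` around D = 0
  (odd terms vanish for mean-zero cues).  Invalid (an error is raised) when
  the estimate is non-positive, which happens under strong selection with
  wide environments — e.g. ω_z = 1 with E[D²] = 2;
* `plugin` — `1/(c + v·E[D²])`: the phenotypic variance evaluated at the
  expected squared cue.  Always positive; used for the strong-selection
  (ω_z = 1) scenarios where the Taylor form breaks down.

E[D²] is the stationary second moment of the mean-centred cue,
σ²_DI + σ²_DT + σ²_DI·T; a nonzero grand mean is removed before squaring.
The cost-free case is an explicit sentinel (`omega_b=None`, γ_b = 0), not a
large-ω_b approximation, so cost-free limits are exact.

## Hyperplasticity and negative plasticity

Along the spatial gradient the plastic phenotype is b̄·D_i and its regression
on S_i (the plastic cline) is `b̄·κ_I·σ²_DI/σ²_SI`.  For B > 0 and zero
interaction variance the closed-form conditions

    hyperplastic:     −(1−g_I)·σ²_DI·(1−r_I²) > γ_b/γ_z + (1−g_T)·σ²_DT·(1−(κ_T/κ_I)·r_I²)
    negative plastic: (1−g_I)/(1−g_T) < −(κ_T/κ_I)·(σ²_DT/σ²_DI)

with `r_I = κ_I·σ_DI/σ_SI` are algebraically equivalent to `cline > B` and
`cline < 0` respectively; the test suite enforces this equivalence exactly
over 10⁴ random valid parameter draws, and the bracketed multiplicative
reading of the first condition is the unique one with that property.  The
conditions are derived in the G_bb → 0 approximation; the simulator provides
the finite-G_bb empirical check.

## Simulation design and problem sizes

The reference run shape is 1000 islands × 15000 generations with the first
5000 discarded, matching the study design the presets reproduce; a reduced
shape of 200 islands × 3000 generations (1000 discarded) is used for the
test suite and the acceptance script so the whole suite completes in well
under a minute of simulation time.  At the reduced shape the Monte-Carlo
spread of a run's time-averaged slope is ≈ 0.002 (at ω_z = 20), dominated by
the frozen spatial draw and the temporal environment realisation rather than
by within-run noise — which is why standard errors for simulation-vs-theory
comparisons are estimated from replicate runs with independent seeds, not
from batch means of a single trajectory (`slope_mc_se` provides the
batch-means estimate for within-run uncertainty only).

Empirical clines are regressions across islands of time-averaged quantities
on the island's *true spatial component* S_i rather than on the island's
time-averaged S: a finite time average retains temporal noise, which would
attenuate the regression (errors-in-variables) without changing the
estimand.  At the reduced shape this attenuation is material (≈ 15% for the
hyperplasticity scenario).

What the generator does *not* emulate: finite island sizes (drift and
sampling noise in selection responses), evolving G-matrices, within-island
environmental heterogeneity, temporally autocorrelated interaction
components, and non-Markovian or non-Gaussian environmental change.  Passing
tests therefore demonstrate the internal consistency of the mean-recursion
model and its analytic approximations, not robustness of the biology to
those relaxations.

## Parameter feasibility and scenario notes

The variance/regression structure requires `κ²·σ²_D ≤ σ²_S` within every
component (the residual variance of S given D cannot be negative); parameter
validation enforces this.  The hyperplasticity showcase scenario
(`figure4b`: κ_T = 2 with σ²_DT = σ²_ST = 2) violates it in the temporal
component — no joint Gaussian process has that regression with those two
stationary variances.  The closed-form slope, the cline and both conditions
never involve σ²_ST, so all analytic results use the scenario values
verbatim; only the stochastic engine needs a realisable process, and it
raises σ²_ST to the minimal feasible value κ_T²·σ²_DT = 8 (zero residual),
which leaves the slope dynamics and the spatial clines unchanged.

The Figure-2 surface presets suppress slope variance (G_bb = E_bb = 0) so the
closed form is exact; their a/b panels sweep the spatial block and its exact
space-time mirror so the two output tables are identical, exhibiting the
symmetry of the slope equation.  Where a check needs strictness (temporal
variance strictly reducing spatial intercept differentiation), the philopatry
grid spans 0.1–1.0: at α_I = 0 the tracking factor is zero and both variants
give identically zero intercept deviation.

## Known limitations

* The analytic branch treats γ_z as one number; under strong selection with
  wide environmental fluctuation no constant-γ_z convention is accurate, and
  the simulation-minus-theory deviation grows accordingly (by an order of
  magnitude between ω_z = 20 and ω_z = 1 on the migration grid).
* The grid solver's accuracy is set by the 31-node quadrature; highly skewed
  or heavy-tailed island distributions are outside its assumptions.
* Condition checkers require B > 0, κ_I ≠ 0 and zero interaction variance,
  as derived; the temporal analogues are obtained by the space-time swap,
  which requires α_T ∈ [0, 1].
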