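# Methods

## Model and scope

`modmedpower` simulates and fits recursive Gaussian path models with fixed
covariates, per group *g*:

    y_i = α_g + B_g y_i + K_g x_i + ζ_i ,   ζ_i ~ N(0, Ψ_g)

The covariates x are experimental dummy codes (0/1) and their products;
they are part of the design, not the model, and are held fixed across
Monte Carlo replications.  B must be permutable to strictly lower
triangular (recursive models only), Ψ is diagonal (no correlated
residuals), and endogenous variables are continuous and conditionally
normal.  Moderation of an indirect effect can be expressed two ways:

* **single-group** — the moderator W and the product XW are covariate
  columns; the index of moderated mediation is the XW → M slope times b;
* **multigroup** — W is a grouping variable; each group has its own
  matrices, equality constraints are shared labels (e.g. one `b` bound in
  every group), and the index is the between-group slope difference times
  b.  Only the multigroup form can encode heteroskedastic residual
  variances across moderator levels.

Out of scope: latent variables / measurement models, non-recursive
structures, correlated residuals, non-normal residuals, missing data,
nonparametric bootstrap tests.

## Standardization solver

Users state slopes on a standardized scale; the solver turns them into
residual variances.  Walking the endogenous variables in topological order
it maintains the joint covariance S of (covariates, already-solved
endogenous variables); for variable j with stacked predictor weights w,
explained variance = wᵀSw and ψ_j = target_j − explained_j (target 1 by
default).  This makes the model-implied total variances equal the targets
exactly (round-trip checked to 1e−10), and fails loudly — naming the
variable — if explained variance reaches the target.

Covariate moments use the **unbiased (n−1) divisor** by default.  That
convention is deliberate: it is the one under which the solver reproduces
the published pooled residual variances 0.8718434 / 0.8061616 for the
2×2, 25-per-cell moderated-mediation population model, and it matches what
a user computing a covariance matrix with standard statistical software
would feed in.  A `population` (divisor n) option exists for cross-checks.
A consequence worth knowing: the standardization depends (weakly) on n, so
power curves re-solve it at every grid point.

## Data generation

Residuals are drawn via Cholesky of Ψ (eigendecomposition fallback for
semidefinite Ψ, e.g. zero-noise checks) and endogenous values are filled
in topological order.  Covariate columns are copied verbatim from the
design each replication.  Multigroup samples are generated per group and
concatenated with a `group` column appended last, coded 1..G.

Seeding: replication r uses `SeedSequence([seed, r])` for data and
`SeedSequence([seed, r, 1])` for MCCI draws.  Results are therefore
identical for any worker count, any subset of replications can be rerun in
isolation, and interval noise is decoupled from data noise.  Equality with
any other software's streams is not a goal.

What the generator does **not** emulate: real mediators and outcomes are
often skewed, ordinal, or heteroskedastic in ways not indexed by the
design; covariate imbalance from attrition; measurement error in M and Y
(which attenuates b and inflates required N).  Passing power targets here
says the engine is calibrated under the stated Gaussian conditions, not
that a real study with the same N will enjoy the same power.

## Estimation

Because the model is recursive with diagonal Ψ, the conditional (fixed-x)
likelihood factorizes into one Gaussian regression per endogenous variable
per group.  Free parameters are the distinct labels:

* **no shared labels** → the ML solution is closed-form per-equation OLS
  with ψ̂ = SS/n (ML divisor), taken directly;
* **shared labels** (cross-group or cross-equation constraints) → BFGS on
  the labels with an analytic gradient, residual variances on the log
  scale, started from the OLS solution with shared labels averaged;
  convergence at gradient norm < 1e−8.

Standard errors come from the observed information, assembled analytically
across equations on the natural scale (−∂²ℓ blocks: ZᵀZ/ψ, Zᵀr/ψ²,
−n/(2ψ²)+SS/ψ³) and inverted via Cholesky; a non-PD information marks the
vcov unavailable and the replication nonconverged.  ψ̂ below 1e−7 is a
boundary estimate and is flagged the same way.  When no mean structure is
declared, every equation still receives a free nuisance intercept
(saturated means) — labelled `_alpha.*`, population value 0 — so slopes are
never forced through the origin.

Delta-method SEs of defined parameters use central finite differences with
step 1e−6·max(1, |θ|) per coordinate; for `ab` this reproduces the Sobel
closed form to 1e−6 (the cross-equation covariance is exactly zero).

## Inference

* Wald: z = θ̂/SE, symmetric CI, reject iff |z| > z_{1−α/2}.
* MCCI: `draws` vectors from N(θ̂_sub, V̂_sub) restricted to the labels the
  expressions use; percentile interval; reject iff 0 outside.  Default
  20,000 draws — at that size the 2.5% percentile of a unit-SE quantity is
  stable to ≈ ±0.02 SE, small against the sampling noise it feeds.
  Percentile (not bias-corrected) intervals; a floor of 100 draws is
  enforced.

## Power engine

Per replication: generate → fit → test every free and defined parameter.
Nonconverged replications are dropped from every numerator and denominator
and reported via `n_converged`; a convergence rate below 95% triggers a
warning, zero convergence is a hard error.  The summary reports, per
parameter: average estimate, average bias (flagged at |bias| ≥ 0.10),
coverage of the delta CI at the population value, and power per method.
Population values of defined parameters are derived automatically by
evaluating their expressions at the population parameters.

Monte Carlo error of a power estimate is binomial, √(p(1−p)/nrep):
roughly ±0.016 at nrep = 1000 — the default, chosen from the commonly
recommended 1000–5000 range.  The acceptance script uses nrep = 2000 and
the test suite nrep = 1000; both finish in minutes on one CPU because the
unconstrained studies take the closed-form OLS path (≈ 1 ms per
replication including a 20,000-draw MCCI).

## Design decisions that were genuinely open

* **Divisor convention** — n−1 throughout (see above); validated against
  the published residual variances rather than chosen by taste.
* **Moderator simple effects** in the moderated-mediation population model
  default to +0.1 (W → M) and −0.1 (W → Y): the values consistent with the
  published standardizing residual variances.
* **c path across moderator groups** — free per group by default
  (`constrain_c=True` to share it).  The index of moderated mediation is
  insensitive to this choice; freeing it is the safer default when
  heteroskedasticity is already being modelled.
* **Expression grammar** limited to `+ − * ( )` over labels: exactly spans
  indirect/total/conditional effects and keeps delta gradients
  well-behaved; no ratios or nonlinear indices.
* **Nonconvergence denominator** — dropped-and-counted rather than
  imputed; transparent and conservative.

## Known limitations

* Two-level factors only in the design builders (the DesignMatrix type
  itself is code-agnostic, but no contrast-coding or >2-level builder is
  provided).
* Gaussian conditional likelihood only; no robust/sandwich SEs, no fit
  indices, no model-comparison tests.
* MCCI assumes the point estimates are jointly normal — accurate at the
  sample sizes used here, optimistic at very small n.
* Power for *differences* of indirect effects is intrinsically low at
  N ≈ 100 under these effect sizes (≈ 5–13%); the engine measures this
  honestly rather than working around it.
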