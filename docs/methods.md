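# Methods

## Model and estimator

Every model is held internally in all-η (LISREL-style) form, one set of
coefficient matrices per group *g*: loadings Λ (p×m), latent paths B
(m×m, acyclic), latent/disturbance covariances Ψ (m×m), measurement
error covariances Θ (p×p), and — when a mean structure is requested —
intercepts τ and latent means α.  Implied moments are

    Σ = Λ (I−B)⁻¹ Ψ (I−B)⁻ᵀ Λᵀ + Θ,      μ = τ + Λ (I−B)⁻¹ α.

Estimation minimizes the classical multi-group ML discrepancy

    F = Σ_g (N_g/N) [ ln|Σ_g| + tr(S_g Σ_g⁻¹) − ln|S_g| − p
                      + (x̄_g − μ_g)ᵀ Σ_g⁻¹ (x̄_g − μ_g) ],

with sample covariances using divisor N_g − 1 (the conventional SEM
input).  The test statistic defaults to T = (N − G)·F̂ (the LISREL-era
multi-group convention); `chi2_multiplier="group"` reports
Σ_g (N_g − 1) F̂_g instead.  The exact χ² upper-tail p at the
structurally computed df is always reported, alongside the severity
heuristic z = (T − df)/√(2df) — the normal approximation to the χ²
locates a statistic in standard-deviation units, but decisions use the
exact tail probability, never the approximation.

**Identification.** Marker scaling by default: the first listed
indicator of each common factor carries a fixed 1.0 loading
(unit-factor-variance scaling is available for exogenous factors via
`scaling: factor_variance`).  Single-indicator latents carry a fixed
1.0 loading and an error variance fixed to a stated proportion of the
indicator's *sample* variance in each group (default 2 %).  The sample
variance is the only group-specific base available at specification
time, and fixing per group keeps the assumption — "2 % of what this
indicator varies in this population is noise" — interpretable.  With a
mean structure, intercepts are free per group and latent means fixed
at 0; when intercepts are constrained equal across groups (the scalar
step), latent means are freed in the non-reference groups, the
standard reparameterization.

**Default covariance structure.** Latents on the same side freely
covary: all pairs of exogenous latents (factor covariances,
auxiliary-cause correlations) and all pairs of endogenous
disturbances.  The disturbances of the work-style factors therefore
remain mutually correlated after auxiliary causes are added — the
factors are related beyond what the auxiliary causes explain — which
is what makes the augmented two-group df come out at 138 (+18 per
group over 24 new covariances) and the reduced-indicator variant at 54.

**Optimization.** Quasi-Newton (L-BFGS-B) on the free parameters with
analytic gradients of F (back-propagated through the implied-moment
algebra), followed by Fisher-scoring polish using the expected
information until the gradient max-norm is below 1e-9; iteration cap
1000.  Starting values: loadings 1.0, error variances 0.5·diag(S),
latent variances 0.5 × the scaling indicator's variance (auxiliary
latents: (1 − proportion) × indicator variance), paths and covariances
0, intercepts at the sample means.  A non-positive-definite implied
covariance during the search returns a large barrier value, which the
line search backtracks from.  Convergence is reported honestly;
Heywood cases (negative variance estimates) are warnings, never
silent.  Standard errors come from the inverse expected (Fisher)
information, acov = (2/n) H⁻¹ with n the χ² multiplier.

## Diagnostics

Modification indices are full score tests: for a fixed cell *a*, with
g the gradient of F and H the expected information over free
parameters plus the candidate,

    MI = (n/2) g_a² / (H_aa − H_af H_ff⁻¹ H_fa),
    EPC = −g_a / (H_aa − H_af H_ff⁻¹ H_fa),

i.e. the expected χ² drop were that one cell freed, with the free
parameters' information partialled out.  The raw gradient-squared
shortcut was rejected because it does not support the "expected χ²
drop" reading; the refit fidelity test (drop within 25 % of MI for
MI > 10, typically within ~10 %) depends on the partialling.
Candidate classes: cross-loadings, direct auxiliary-cause loadings
(exposed by the all-η conversion), and error covariances.

"Standardized" covariance residuals are implemented as *normalized*
residuals, (s_ij − σ̂_ij)/√((σ̂_ii σ̂_jj + σ̂_ij²)/N_g).  Evaluated at the
true parameter values these are approximately N(0,1) — verified by
simulation — while residuals at *fitted* values are smaller because
free parameters absorb misfit; the >2.0 screen is therefore
conservative on fitted models, matching its qualitative use.  The full
standardized residual (requiring the asymptotic covariance of the
residual moments) was considered and deferred: the decision rule it
feeds is identical.

Thresholds 4.0 (MI, ≈ the 5 % χ²₁ critical value) and 2.0 (residuals,
≈ two standard errors) are overridable configuration defaults.

## The auxiliary-cause probe

`add_auxiliary_causes` turns named observed variables into correlated
single-indicator exogenous latents with paths to every common factor.
The probe fits the base configural model and the augmented model and
flags `evidence_of_misspecification` iff either exact χ² p falls below
α (default 0.05); non-convergence yields `indeterminate`, never a pass.
Diagnostics are restricted to the informative blocks: the new
auxiliary-by-indicator covariances (residual screen) and the candidate
direct cause→indicator loadings (MI screen).  The all-η conversion
that exposes those candidates is bookkeeping here — the coefficient
matrices are already in all-η form — so the converted model's fit is
identical by construction, and a test asserts it.

The ladder (`run_ladder`) refits with accumulated between-group
equality classes — metric (all non-marker loadings), scalar
(intercepts, with latent means freed in non-reference groups), strict
(error variances) — and tests each Δχ² at Δdf.  Nesting is asserted
structurally (free-cell containment and constraint-partition
refinement), not assumed.  The configural test result is always
reported first and never suppressed; fit indices are computed only on
explicit request and labeled descriptive.  The ladder constrains all
non-marker loadings in the metric step (markers are already fixed at
1.0 in every group) and documents this choice.

## Synthetic designs

The canned two-group design mimics a twelve-item work-orientations
scale administered in Great Britain (n = 648) and the USA (n = 823):
three factors with four indicators each, plus Sex and Age.  Marginal
means and standard deviations are set to the published per-country
values; the truth is built on the standardized scale and rescaled, so
population moments reproduce those marginals exactly.  Values the
source table does not provide are fixture choices, stated once:
standardized loadings 0.7 (a typical communality of ~0.5 for attitude
items), inter-factor correlations 0.3, standardized Sex/Age effects on
each factor 0.15, Sex–Age correlation 0.05, auxiliary measurement
error 2 %.  With no injection the augmented truth is exactly the
augmented model, and — because the indicators load only on the factors
— the marginal 12-indicator covariance is exactly three-factor
structured, so the configural model is also true.  Draws are
multivariate normal: the real items are 5-point ordinal, but the
analysis operates on covariance matrices of items treated as
continuous, so the generator matches the analyzed scale; ordinal
discretization, sampling weights and nonnormal errors are out of
scope, and passing tests accordingly certify the estimator and
decision logic, not robustness to ordinality.

Injections deform the population before moments are computed:
`direct_aux_effect` / `omitted_cross_loading` add a loading scaled so
the *standardized* effect equals the requested magnitude (using the
pre-injection implied variances), `error_covariance` adds a scaled
error covariance, `extra_common_factor` appends an independent
unit-variance latent with loadings on chosen indicators.  Positive
definiteness is verified after injection.  Seeding: one master seed
spawns per-group child streams (`numpy.random.SeedSequence`), so each
group's draw is reproducible and independent of the others.

## Problem sizes in tests and the acceptance script

Calibration uses 500 replications of the group-invariant two-group
design at N = 500/group, fitting configural and metric models per
replication (rejection rate vs the exact binomial 99 % interval around
0.05; metric Δχ² vs χ²₉ by Kolmogorov–Smirnov).  Probe power uses 200
replications at the survey sizes (648/823) with one injected direct
Sex→y1 effect of standardized 0.3.  Oracle equivalence checks five
random small models (1–2 factors, ≤6 indicators, 1–2 groups) against
an independent RAM-formulation fitter kept inside the test suite.
These sizes were chosen to estimate each rate with adequate precision
while keeping the whole pipeline comfortably re-runnable.

## Known limitations

- Normal-theory ML only: no FIML for missing data (listwise deletion
  only), no robust/ordinal estimators, no bootstrap intervals.
- No formal identification (rank) checking; df ≥ 0 plus convergence
  behavior are the guards.
- Expected (not observed or sandwich) information standard errors.
- The probe's verdict logic is deliberately χ²-primary; users wanting
  index-based judgments must opt in and are told the indices are
  descriptive.
- A reduced paired-indicator variant of the survey model (two
  indicators per factor plus the two auxiliary causes) is structurally
  expressible here, and its df accounting follows the same rules as
  the models above; published df figures for such a model differ
  across sources and are not used as checks.
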