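# Methods

## Study design being modeled

A gender-blocked, randomized 3×2×2 factorial mailed-survey experiment:
480 men and 480 women, each block split into 12 equal cells of 40, one
per combination of cover-letter content (combat, unwanted sexual
attention, generic lifetime framing), stated name source (OEF/OIF/OND
roster vs disability-claims list) and promised incentive ($20 vs $40).
Eight binary administrative correlates are known for the entire sampling
frame (age < 30, non-white race, combat exposure, military sexual trauma,
serious mental illness, Charlson index > 0, any VA disability benefits,
PTSD disability benefits); two binary self-reports (combat exposure,
military sexual assault) are observed only for responders.
Administrative military sexual trauma is deliberately distinct from
self-reported military sexual assault — the administrative flag also
covers severe, pervasive physical sexual harassment — and the synthetic
generator links them only through model coefficients, never by equating
them.

## Randomization

Within each gender block, a seeded uniform shuffle (`numpy`
`default_rng`) followed by deterministic chunking into 12 consecutive
groups mapped to cells in canonical order (content × source × incentive,
row-major). This yields exactly equal cells and reproducible plans; any
procedure that assigns cells to equal random groups induces the same
distribution, so the choice is one of implementation convenience.

## Response rates and homogeneity

RR1 = 100·returned/assigned, the strictest standard definition.
Homogeneity across factor levels and across the 12 cells uses the
Pearson χ² test without continuity correction (a `correction` flag
exposes the Yates version); with the published return counts the
uncorrected test reproduces the published significance pattern for the
source and incentive margins.

## Bias and its factorial decomposition

Bias is respondent-percent minus frame-percent in signed percentage
points, per correlate, per block. Per-arm bias compares each single
factor level's respondents against the full block frame prevalence;
with 100% response the overall bias is exactly zero while arm strata
retain their (small, random) randomization imbalance.

The η² decomposition works on respondent-level frame-centered
indicators (the 0/1 correlate minus the block frame prevalence), so
each design cell's mean equals its bias and an ANOVA partition of the
centered indicator is a partition of bias variance. Sums of squares are
sequential (Type I, term order content, source, incentive, then
interactions): under respondent imbalance only sequential SS partition
the total exactly, which the tests verify to 1e-8 relative. Interactions
are tested highest-order first and every interaction with p ≥ 0.05 is
pooled into the error term (its degrees of freedom join the error df)
before η² = 100·SS_factor/SS_total is read off the final model. A
constant correlate yields SS_total = 0 and η² defined as 0. Because the
published grid also flags *net* bias, a one-sample t-test of the mean
centered indicator (`overall_bias_test`) complements the factor-level
F-tests; both are reported.

## Missingness estimators

Let x be the frame-complete covariates (by default the 8 correlates plus
treatment-coded arm indicators; columns constant or collinear among
responders are dropped by a rank-revealing QR), y the binary self-report,
r the return indicator.

* **MCAR**: complete-case mean of y among responders.
* **MAR (multiple imputation)**: logistic fit of y on x among
  responders; each of m = 25 imputations draws coefficients from the
  fit's asymptotic normal (proper-imputation approximation; a
  ridge-penalized fallback handles separation) and then Bernoulli
  outcomes for every nonresponder. Per-imputation prevalence is the
  full-frame mean; Rubin's rules pool: total variance = within +
  (1 + 1/m)·between, verified to 1e-10.
* **MNAR (nonignorable selection model)**: joint likelihood
  P(y|x;β)·P(r|x,y;α,γ) with logistic links, y entering the response
  model linearly with coefficient γ (γ = 0 nests the ignorable case).
  Fitted by EM: the E-step gives each nonresponder posterior weight
  w₁ ∝ P(y=1|x)·P(r=0|x,y=1); the M-step runs two weighted logistic
  fits on the expanded table (responders at weight 1, each nonresponder
  as two pseudo-rows). The reported MNAR prevalence averages observed
  outcomes with the posterior weights (a purely model-marginal variant,
  averaging expit(x'β) over the frame, is available via
  `method="marginal"`).

### Weighted logistic numerics

The M-steps and the MI base fit need fractional weights and benefit
enormously from warm starts, so the solver is a small Newton/IRLS
routine with step-halving (guaranteed non-decreasing likelihood),
a rank check, and a quasi-separation flag at |coefficient| > 15 on the
logit scale. It is cross-checked in the tests against a brute-force
two-stage likelihood grid (agreement to 1e-4) and against an independent
GLM fit with frequency weights.

### EM acceleration and convergence

The plain EM map converges linearly and, when the selection model is
weakly identified, painfully slowly (thousands of iterations at the
default tolerance). Each recorded iteration therefore takes a SQUAREM
extrapolation step built from two EM map applications plus a
stabilizing third, with an explicit fallback to the plain double EM step
whenever the extrapolated point would lower the observed-data
log-likelihood — so the recorded log-likelihood trajectory is
non-decreasing by construction, which the tests assert to 1e-10 on
every iteration of every fit. Convergence is declared when the EM-map
fixed-point residual drops below `tol` (default 1e-6 on the parameter
scale); a plateau guard stops iteration once likelihood increments fall
below float resolution (1e-12), since further steps only churn
roundoff. Initialization is the ignorable fit (β from responders, α
from r on x, γ = 0); `n_starts` adds randomly perturbed restarts and
keeps the best likelihood.

### Cross-mechanism summary

`summarize_mechanisms` reports the sample variance (denominator 2) of
the three estimates **on the proportion scale** and the range
(max − min) **in percentage points** — the mixed-unit convention under
which the published tables' printed magnitudes (e.g. variance 0.0144
against range 22.5) reproduce exactly. Close estimates and a small
variance support random missingness; divergence flags a nonignorable
mechanism.

## Synthetic cohort generator

Defaults emulate the study conditions: two blocks of 480; correlate
prevalences set to the published frame values (e.g. men's combat 67.1%,
women's military sexual trauma 45.6%); independent Bernoulli covariates
by default with optional pairwise dependence through a Gaussian-copula
threshold construction (positive semi-definiteness of the latent
correlation is checked at generation time). Latent self-reports exist
for *all* frame members so MNAR estimators can be scored against the
truth; the response model is exactly the selection model above, making
the mechanism taxonomy constructive: intercept-only α with γ = 0 is
MCAR, covariate-dependent α with γ = 0 is MAR, γ ≠ 0 is MNAR.

The bundled `study_like` scenario sets the response intercept and arm
effects to give an overall return rate near 43% with higher returns
under $40 and the claims-list framing, γ = +0.6 on self-reported combat
and γ = −0.9 on self-reported assault (survivors respond less). These
coefficients are scenario parameters chosen for plausibility — the study
never published its response process — and are not estimates of it.

What the generator does **not** emulate: item-level (within
questionnaire) nonresponse, reminder-wave dynamics, covariate
measurement error in the administrative flags, and any non-logistic
response behavior. Passing tests therefore certify the estimators under
a correctly specified parametric selection model, not robustness to its
misspecification.

## Simulation designs used by the tests and the acceptance script

* **Parameter recovery**: cohorts drawn from the selection model at
  n = 5,000 with one standard-normal and one Bernoulli(0.4) covariate
  and all true coefficients at least 0.8 in magnitude
  (β = (1.0, 2.5, −2.0), α = (1.0, 0.8, −0.8), γ = −2.0; return rate
  ≈ 42%). Rationale: relative bias is ill-defined near zero, and the
  selection model is identified only through its parametric form — a
  low-dimensional, well-separated design tests the algorithm rather
  than the identifiability of an arbitrary design. The test suite runs
  200 replicates; the acceptance script reports a 60-replicate version.
* **Ignorable-case equivalence**: γ = 0 cohorts at n = 20,000 with three
  covariates that predict both outcome and response (so the
  complete-case mean is biased upward by construction). Because γ's
  maximum-likelihood estimate has substantial sampling variance even at
  this size — EM reaches the exact global optimum, verified against
  direct maximization — single-fit MNAR−MAR gaps fluctuate, and the
  equivalence check uses the median gap across replicates.
* **MCAR coherence**: a single n = 50,000 cohort with 60% completely
  random response; all three estimators agree within 1 pp and the
  cross-mechanism variance sits below 1e-4.

Problem sizes (replicate counts, n per cohort) were chosen so the whole
suite runs in a couple of minutes on one CPU while leaving the
Monte-Carlo error well inside each tolerance.

## Known limitations

* MNAR estimates carry no nonparametric identification: there is no
  instrument, and everything rests on the logistic forms. Reports carry
  a standing caveat, and applied conclusions should treat the MNAR
  column as an assumption-contingent scenario, mirroring how the
  original analysis used it.
* At the study's actual scale (480 per block, ~40% response, 12
  covariates) the selection model's γ is extremely noisy; stratum-level
  MNAR estimates in the published-style tables swing accordingly. That is
  a property of the method at that scale, reproduced faithfully.
* The ANOVA uses respondent-level indicators; the mixed/logistic
  variants of the bias analysis are intentionally out of scope.
* No post-survey weighting, raking or propensity adjustment is
  implemented; the package measures bias rather than correcting it.
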