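# Methods

## The scientific problem

Behavioural problems (undercontrolled, disruptive conduct) and emotional
problems (negative mood, inhibition) co-occur in young children but are not
the same thing. Beyond a child's *total* burden of problems, the *relative*
balance of the two domains — how far they have *differentiated* from one
another — may carry its own information about which mental health
conditions emerge later. This package implements that idea as a complete,
testable analysis pipeline: score construction, a developmental model of
differentiation, validation against later symptoms and registry-style
diagnoses, an exposure screen, and a sibling-comparison analysis of
familial confounding. Because the motivating cohort data (a Norwegian
population birth cohort linked to national health registries) are
access-restricted, the pipeline runs on a synthetic cohort whose generator
is itself a first-class, tested component.

## Score construction

Parent-rated behavioural (8 items, 0–16) and emotional (5 items, 0–10)
subscale scores at nominal ages 1.5, 3 and 5 years are z-standardised
within wave over all children observed at that wave. The differentiation
score is `diff_w = z_beh_w − z_emo_w` (positive = relatively more
behavioural problems) and the total score is `tot_w = z_beh_w + z_emo_w`.
Since `cov(zB − zE, zB + zE) = var(zB) − var(zE) = 0` on the
standardisation population, the two are orthogonal by construction; the
package verifies |r| below 1e−10 on complete cases and ≈0.02 at most on the
all-waves-complete subset under attrition.

Standardisation uses the n−1 denominator and the per-wave observed
population (not complete cases across waves), consistent with the
full-information estimation philosophy. Both choices are conventional and
exposed as options.

A child is a diagnostic *case* for a category (depression, anxiety, ADHD,
disruptive behaviour disorders) if the contact table records the relevant
diagnosis at least twice in primary care, at least twice in secondary care,
or once in each, between the child's 8th birthday and the follow-up end
(2021-07-01). Two same-day contacts count as two (the rule counts
diagnoses and carries no de-duplication clause); a switch collapses them.

## The growth model

For each child i the observed vector (three wave scores, optionally
followed by age-8 symptom scales) follows

    y_i   = nu + Lambda eta_i + kappa d_i + eps_i,   eps_i ~ N(0, Theta)
    eta_i = alpha + Gamma x_i + zeta_i,              zeta_i ~ N(0, Psi)

with fixed wave loadings Lambda_w = (1, t_w) and time scores
t = (−3.5, −2, 0) years: the intercept is the age-5 *endpoint* of the
process ("extent" of differentiation) and the slope is its per-year "rate".
d_i is the deviation of the child's actual age at questionnaire return from
the nominal wave age, entering the measurement equation with a single
shared coefficient kappa (per-wave coefficients would add two parameters
for a covariate that explains almost nothing at jitter SD 0.1 y).
Covariates are sex and parity; exposures enter the same Gamma block.
Wave residual variances are free by default (an equality toggle exists);
symptom rows have free intercepts, loadings and residuals. The bivariate
variant stacks both subscales with four factors, per-wave 2×2 residual
blocks, and is used for the separate-subscale sensitivity analysis and the
reparameterisation checks.

**Estimation.** Casewise full-information maximum likelihood: children are
grouped by missingness pattern and each contributes the Gaussian
log-density of its observed subvector (valid under MAR). Observation
weights multiply casewise contributions. Optimisation is quasi-Newton
(L-BFGS-B) on an unconstrained scale — log variances, log-Cholesky factor
covariances — with fully analytic gradients, moment-based starting values
and up to four jittered restarts; the convergence flag reports the final
projected-gradient norm honestly (threshold 1e−5 on the per-child-scaled
objective). Analytic gradients are verified against central finite
differences in the test suite.

**Inference.** Standard errors come from the cluster-robust sandwich
A⁻¹BA⁻¹ on the natural parameter scale, with clusters defined by mother:
A is the observed information (central finite differences of the analytic
score) and B the outer product of per-cluster summed score vectors times
G/(G−1). With singleton clusters this reduces to the per-child robust
sandwich. Derived quantities (slope–intercept correlation, standardised
betas) get delta-method SEs with numeric Jacobians. Standardised effects
are per SD of predictor on the SD scale of the *marginal* factor variance
(Psi plus the variance explained through Gamma and the sample predictor
covariance).

**Fit indices.** The saturated model is the unrestricted mean/covariance of
the three wave scores (closed form when complete; EM otherwise) and the
baseline model frees means and variances with zero covariances. chi² =
2(llₛ − llₘ) with df = 9 − 8 = 1 for the bare growth model; RMSEA =
sqrt(max(chi²−df,0)/(df·n)) with n = children (cluster-count alternative
noted); CFI/TLI from the baseline chi²; SRMR is the root mean square of the
9 standardised moment residuals (3 means, 6 covariances, standardised by
the saturated SDs). Indices are defined for measurement-only fits — a fit
with predictors is not nested under this covariate-free saturated model, so
the package reports AIC/BIC/LRT for those instead, and `measurement_fit()`
is the supported route to indices.

**Model comparison and factor scores.** Nested fits are compared by
likelihood-ratio test (with a BIC report alongside for non-nested
decisions); a negative LR statistic beyond tolerance returns a refit
advisory rather than silently clamping. Factor scores use the regression
method — the conditional expectation of (intercept, slope) given the
child's observed waves and covariates — which shrinks toward the
covariate-conditional mean as information decreases; Bartlett scores are
available for children with ≥2 observed waves. The "scaled" robust test
statistic used with some SEM estimators is not implemented: the synthetic
data are Gaussian, where its correction factor is ≈1; plain LRTs plus
robust SEs are used throughout, and this is the one deliberate departure
from the source analysis stack.

## The synthetic cohort generator

The generator draws families (1–2 children each; default 18% two-child
families, i.e. ~30% of children are siblings) and, per child, a bivariate
linear growth process for the behavioural and emotional subscales in a
latent z-metric, mapped affinely to the instrument scales (means 6 and 5,
SD 2.5; optional rounding/truncation). Scores are generated as continuous
Gaussians because every estimator treats them as continuous.

Key calibration choices, fixed once:

- **Latent covariance.** The 4×4 factor covariance is parameterised so the
  implied differentiation factors have variances (1, 0.1) and correlation
  0.64 — the published point estimate — while the total factors correlate
  ≈0.42. Wave residual variances are chosen to make each subscale's total
  wave variance equal (1.5) at every wave, so the downstream per-wave
  standardisation is one common rescaling and the linear growth structure
  survives it exactly; correlations and standardised effects are invariant
  to that rescaling.
- **Effects on differentiation.** Exposure and covariate effects are
  specified on the differentiation metric (per SD of predictor, in factor-SD
  units) and expanded to opposite-signed half-loadings on the two
  subscales, so they move differentiation and leave the total process
  untouched. Covariates enter centred, making the calibrated marginal
  factor law exact. Defaults: sex → intercept 0.09, sex → slope 0.01,
  parity 0.05/0.06; six active exposures at ±0.03–0.05 mirroring the
  published pattern (at-risk drinking, relationship problems, prenatal and
  concurrent distress, education, prenatal smoking); the rest null.
- **Exposures.** Unit-variance with a family-level variance share of 0.5
  (family component plus child component) and a loading of 0.3 on an
  unobserved family confounder that also shifts the differentiation factors
  (0.15/0.10 SD) — the confounding testbed for the sibling design. A fully
  null regime (`null_exposure_params`) zeroes both the exposure paths and
  the confounder for FDR experiments.
- **Outcomes.** Six age-8 symptom scales are linear in the standardised
  differentiation factors (loadings mirroring the published figure,
  hyperactivity strongest at 0.25) with unit total variance. Diagnosis
  contacts are drawn so that the case rule reproduces a logistic model on
  the standardised factors exactly: case children receive 2+Poisson(0.3)
  in-window contacts, non-cases at most one, plus pre-window noise contacts
  that the window rule must discard. Default per-SD intercept ORs: ADHD
  1.76, DBD 1.50, DEP 0.90, ANX 0.85; base rates ≈3–6%.
- **Attrition.** Waves 2 and 3 are missing at random given parity, an
  exposure, and the wave-1 behaviour score (wave 1 is the anchor and always
  observed); defaults give ≈35%/45% missingness, leaving ≈36% of children
  complete on all waves — the response pattern of the source cohort. The
  mechanism is configuration, not an asserted truth, because the source
  study reports only "low selective attrition". Note one deliberate
  realism: dropout depends on the wave-1 *behavioural* score and on an
  exposure outside the differentiation model, so the differentiation fit is
  very mildly MNAR; the bias is far below test tolerances and is the kind
  of deviation a real analysis would face.
- **Sibling selection.** Whole families are selected into the two-child
  subsample by a logit on observed first-child variables (default: positive
  on the education-like exposure, negative on parity), with the intercept
  calibrated by root-finding so the expected selected share equals the
  sibling fraction. Second children share the family confounder and family
  exposure components, get parity+1, and draw fresh child-level components.

What the generator does **not** emulate: item-level measurement,
ordinal/count score distributions (unless truncation is enabled), genetic
(ACE) family structure, more than two siblings, non-linear growth, and
calendar-time effects. Passing tests therefore show that the estimators do
what they claim under the stated model, not that the substantive published
estimates would replicate in real data.

## Exposure screening and FDR

The 16 exposures enter the growth model jointly (mutually adjusted, as a
single questionnaire battery); a marginal one-at-a-time mode exists for
sensitivity. Three structural variants — both factors, intercept-only,
slope-only — are compared by LRT against the full model: keep "both" when
dropping either set of paths significantly hurts; otherwise take the
tenable reduction, breaking ties by BIC. Benjamini–Hochberg q-values
(step-up with cumulative-minimum monotonicity) are computed within one
outcome model's family of exposure × free-factor tests (32 under "both"),
matching a per-outcome-figure correction; the family width is
configurable.

## Sibling comparison

Selection into the sibling subsample is modelled by a logistic regression
of sibling status on all other study variables (exposures, covariates, wave
scores with missingness indicators); sibling children receive stabilised
weights P(S=1)/P̂(S=1|x), truncated at the 99th percentile and renormalised
to mean 1 (truncation is standard variance control, not in the source
description, and can be switched off). Each exposure is split into family
mean and child deviation (within/between, i.e. Mundlak, decomposition) over
families with two participating children; the deviation coefficient is free
of family-shared confounding. The adjusted model was implemented as this
observed decomposition feeding the FIML growth model — rather than a
latent two-level SEM — because for two-child families it targets the same
within-family estimand while staying simple enough to verify against
oracles; the equivalence is not asserted for unbalanced designs. Both
unadjusted and adjusted effects are reported per SD of the *raw* exposure,
so attenuation is read off a common scale; exposures with a within-family
variance share below 1% are flagged "education-like" and their adjusted
estimates marked unreliable rather than suppressed. Known fragility,
verified by a directional test: random measurement error in the exposure
attenuates the within-family estimate more than the naive one.

## Numerical choices and degenerate inputs

- Variances live on log scales and covariance blocks on log-Cholesky
  scales during optimisation; the sandwich is evaluated on the natural
  scale at the interior optimum.
- A singular implied covariance for any observation pattern raises an
  error naming the pattern; non-convergence after restarts returns an
  explicit `converged=False`, never a silent result.
- Perfect separation or instability in a diagnosis logit triggers an
  L2-penalised fallback with a `penalised` flag; zero-case categories are
  skipped with a diagnostic row.
- Fewer clusters than parameters attaches a warning to the sandwich.
- The EM for the saturated model stops at a relative log-likelihood change
  of 1e−9 (cap 2000 iterations).

## Problem sizes

The experiment drivers use: 10,000 families for the orthogonality check;
500 replicate cohorts of ~2,000 children for the FDR study; n = 5,000
(100 replicates) for fit-quality; n = 20,000 children for the correlation
recovery; n = 50,000 for the sex-effect and odds-ratio recoveries (the
recovery experiments switch attrition off to isolate estimator behaviour);
20,000 families for the sibling-design scenarios. The test suite replicates
the same studies at reduced replicate counts where the full versions are
already exercised by the acceptance path.

## Known limitations

- No scaled/robust chi-square correction (see above); fit indices are
  defined for measurement-only models.
- Factor-score logits inherit shrinkage attenuation: with a generating
  ADHD OR of 1.76 per SD of the true factor, extracted-score estimates are
  biased toward 1 (the source analysis has the same property and does not
  correct it; the acceptance recovery therefore regresses on the true
  factor, as specified).
- The slope factor is identified by three waves only; its factor-score
  correlation with truth (~0.64 at default settings) is intrinsically lower
  than the intercept's (~0.74).
- The within/between adjustment controls family-shared confounding only —
  child-specific confounders and 50% of segregating genetic effects remain,
  exactly as in the real design.
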