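# diffgrowth

Latent growth modelling of the **differentiation of behavioural and
emotional problems** in early childhood.

Behavioural and emotional problems co-occur in young children, but the
*relative* balance between the domains — how far they have differentiated
from one another — may predict later mental health over and above the total
burden of problems. This package implements that research design end to
end, for epidemiologists and psychometricians who want a fully testable
version of the analysis:

- **Scores.** Per wave (ages 1.5, 3, 5 y), subscale scores are z-standardised
  and combined into a differentiation score `z_beh − z_emo` and a total
  score `z_beh + z_emo`; the two are orthogonal by construction.
- **Growth model.** A linear latent growth model with the intercept set at
  age 5: `y_iw = α₀ + α₁ t_w + Γx_i + ζ + κ d_iw + ε`, time scores
  t = (−3.5, −2, 0) years, estimated by casewise full-information maximum
  likelihood (FIML, valid under MAR attrition) with analytic gradients,
  mother-clustered sandwich standard errors, CFI/TLI/RMSEA/SRMR fit
  indices, likelihood-ratio model selection, and regression-method factor
  scores. The latent intercept is the *extent* and the slope the *rate* of
  differentiation.
- **Validation.** Growth factors predicting age-8 symptom scales inside the
  model, and extracted factor scores predicting registry-style diagnosis
  case status (two-contact rule after the 8th birthday) in cluster-robust
  logistic regressions, reported as per-SD odds ratios.
- **Exposures.** Sixteen early-life exposures entered jointly, with
  LRT-based selection among both/intercept-only/slope-only variants and
  Benjamini–Hochberg FDR control.
- **Sibling comparison.** Stabilised inverse-probability weights for
  selection into the sibling subsample, within/between (Mundlak)
  decomposition of each exposure, and unadjusted vs family-confounding-
  adjusted estimates with attenuation reporting.
- **Synthetic cohort.** Because the motivating cohort and registry data are
  access-restricted, a seeded generator reproduces the statistical
  structure the analysis assumes — family clusters, bivariate latent
  growth, confounded exposures, MAR attrition, symptom and diagnosis
  outcomes, covariate-dependent sibling selection — and is calibrated to
  published point estimates (slope–intercept r = 0.64, sex → intercept
  β = 0.09, ADHD OR 1.76 per SD) so parameter-recovery checks are
  meaningful.

See `docs/methods.md` for the model, calibration and design decisions.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_score_cohort.py
python analysis/03_growth_models.py
python analysis/04_validate_outcomes.py
python analysis/05_exposure_effects.py
python analysis/06_sibling_comparison.py
```

The first three print, for the default 8,000-family cohort:

```
cohort: 9376 children in 8000 families
  sibling children: 2752 (29.4%)
  complete on all three waves: 32.7%
complete-case corr(diff, tot) per wave:
1   -0.0
2   -0.0
3   -0.0
[diff] measurement model: CFI=1.000 TLI=1.002 RMSEA=0.000 SRMR=0.001 (chi2=0.08, df=1, n=9376)
[diff] slope-intercept r = 0.669 [0.624, 0.715]
[diff] sex -> I: beta = 0.096 [0.060, 0.132]
```

Reading this: the differentiation and total scores are exactly orthogonal
on complete cases; the linear growth model fits its own data in the
conventional good-fit region; the extent and rate of differentiation are
positively correlated (generating value 0.64, recovered within its CI);
and boys sit ~0.1 SD higher than girls on the age-5 differentiation
endpoint (generating value 0.09). Script 04 then shows hyperactivity,
inattention, conduct and oppositional symptoms loading positively — and
anxiety negatively — on the differentiation factors while the orthogonal
total-score factors carry none of that signal, plus ADHD/DBD odds ratios
above 1 for the extracted intercept score; script 05 flags the exposures
with real generating effects after FDR; script 06 contrasts unadjusted and
within-family-adjusted exposure effects in the weighted sibling subsample,
where estimates driven by the family confounder collapse toward zero.

Library use mirrors the scripts:

```python
import diffgrowth as dg

params = dg.default_params(n_families=8000, seed=2025)
cohort, truth, contacts = dg.simulate_cohort(params)
scored, _ = dg.score_cohort(cohort)
fit = dg.fit_growth(scored, dg.GrowthSpec(outcome="diff"))
r, se = dg.factor_correlation(fit)
```

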