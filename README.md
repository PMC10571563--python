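# depmed — Bayesian causal mediation of area-level deprivation on ovarian cancer survival

Neighborhood deprivation indices (DIs) — composite census-tract scores such
as the Yost index, the Singh area deprivation index (ADI), the Kolak
social-determinants dimensions (URB, MOB, SES, MICA), concentrated
disadvantage (CDI), or simple percent-poverty (POV) — are widely used to
adjust cancer-outcome analyses for socio-economic context. This package
implements, as a tested pipeline, a Bayesian structural-equation approach to
asking a sharper question: does a DI act on ovarian cancer survival
*directly*, or *indirectly* through clinical mediators (stage at diagnosis,
surgical debulking status), and how much of each?

It is written for biostatisticians and epidemiologists who want to run or
audit this kind of joint mediation model. Because cohorts of this type are
IRB-restricted, the package ships a calibrated synthetic-cohort generator
that emulates the data structure of a study of n = 558 Black women with
epithelial ovarian cancer (≈60% deaths, 66% distant stage, ~30% suboptimal
debulking, ~34% missing debulking status), so every stage of the pipeline is
verifiable end-to-end against known ground truth.

## The model

For survival time T (days from diagnosis to death or last contact), exposure
X (one standardized DI per model), mediator M (3-level stage or binary
debulking), modifiers **C** (age, BMI, income, smoking, physical activity)
and a census-tract latent effect U_g, the joint model is

- **Outcome** — Weibull proportional hazards:
  h(t) = κ t^{κ−1} exp(η),  η = β₀ + β_X X + β_M′ 1[M] + β_C′ C + λ_T U_g
- **Mediator** — multinomial (or Bernoulli) logit:
  P(M = k) ∝ exp(α₀k + α_Xk X + α_Ck′ C + λ_M U_g),  reference level 0
- **Latent effect** — U_g ~ Normal(0, σ_u²), shared between the two models
  and scaled by λ_T (sign-constrained positive) and λ_M.

Estimation is Metropolis-within-Gibbs with adaptive random-walk proposals.
Gibbs variable selection samples one inclusion indicator γ_j per candidate
modifier in the hazard model (pseudo-priors from a pilot run); modifiers
with inclusion frequency strictly above 0.5 are kept for a refit, mirroring
the two-panel layout (selection frequencies, then effects) of the published
tables. Effects are reported per SD of the index on the hazard-ratio scale:

- direct = exp(β_X Δx),
- indirect via level k = exp(β_Mk · Δp̄_k), where Δp̄_k is the average shift
  in P(M = k) induced by the exposure contrast,
- total(k) = direct × indirect(k), draw-wise.

Missing debulking status is multiply imputed (White–Royston: logistic
regression on site, histology, stage, adjuvant/neoadjuvant therapy, age,
plus the Nelson–Aalen cumulative hazard and the event indicator; 25
datasets; per-participant mode consensus).

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_impute_debulking.py
python analysis/03_fit_joint_models.py --exposures URB ADI --mediators stage3 debulk2
```

The first two steps print the cohort calibration and the missing-at-random
diagnostic:

```
deceased: 61.3% (study: 60.4%)
distant stage: 64.0% (study: 66.3%)
suboptimal debulking: 29.4% (study: 29.9%)
missing debulking: 33.0% (study: ~34%)
true direct HR per SD of URB: 0.731
  KM median,    optimal:    2612 days
  KM median,    missing:    2055 days
  KM median, suboptimal:    1574 days
```

— the missing-debulking subgroup's survival falling between the optimal and
suboptimal groups is the classical check that missingness tracks observables
only. The fits then report, per (index, mediator) pair:

```
URB__stage3:  direct HR 0.775 (0.687, 0.861) *
URB__debulk2: direct HR 0.748 (0.668, 0.830) *
ADI__stage3:  direct HR 1.089 (0.971, 1.207)
ADI__debulk2: direct HR 1.115 (0.973, 1.249)
(* = 95% credible interval excludes 1)
```

Read: a 1-SD higher urbanicity/SES score (URB) reduces the hazard of death
by ~22–25% and the interval excludes 1 ("well estimated"); the positively
oriented deprivation index ADI raises the hazard but its interval crosses 1.
The generating truth for URB in this cohort is HR 0.731, inside both URB
intervals. Full per-level indirect/total tables are written to
`results/fits/effects_<index>__<mediator>.csv`.

`analysis/05_validation_studies.py` verifies the machinery: the mediation
decomposition matches a brute-force counterfactual Monte-Carlo oracle to
within Monte-Carlo error, 95% credible intervals for β_X cover the truth in
19/20 replicate cohorts, and consensus imputation is more accurate than the
majority-class baseline (70.0% vs 66.1%).

## Layout

```
src/depmed/        cohort.py (I/O, validation, descriptives, encoding)
                   simulate.py (generator + counterfactual MC oracle)
                   impute.py (Nelson–Aalen, White–Royston MI, consensus)
                   jointmodel.py (joint SEM, MWG sampler, GVS, diagnostics)
                   mediation.py (effect decomposition and summaries)
                   pipeline.py (orchestration, manifests, comparison)
                   validate.py (recovery / oracle / imputation studies)
analysis/          numbered drivers reproducing the full analysis
tests/             unit, property and end-to-end acceptance tests
docs/methods.md    modeling choices, assumptions and limitations
```
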