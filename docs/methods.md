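# Methods

This note records the modeling choices behind `depmed`, in the order the
pipeline uses them, with the reasoning for each decision that was genuinely
open.

## Joint structural model

One deprivation index at a time is the exposure X, z-standardized over its
non-missing values, so every reported hazard ratio is per one SD of the
index. (The alternative — raw-scale coefficients — would make indices with
scales from 0.13 to 900+ incomparable; per-SD effects of magnitude ~0.7–1.3
are the only scale on which cross-index comparison is meaningful.)
Standardization never flips signs: each index keeps its native direction,
recorded in `ExposureSpec.direction` (URB/MOB/SES/YOST: high = advantage;
MICA/ADI/POV/CDI: high = deprivation) and carried into reports.

The outcome is a Weibull model in the proportional-hazards
parameterization, h(t) = κ t^{κ−1} e^η, chosen over the accelerated-failure
form because all effects are reported as hazard ratios (HR = e^coef). The
mediator model is a multinomial logit for 3-level stage (reference:
localized) or a Bernoulli logit for binary debulking (reference: optimal) —
clinically natural baselines. A single tract-level latent effect
U_g ~ N(0, σ_u²) enters both linear predictors, scaled by λ_T in the hazard
and λ_M in the mediator model. It represents unobserved contextual
confounding shared by the survival and mediator processes; the grouping is
at census-tract level because every exposure is a tract attribute (an
individual-frailty fallback is obtained by giving each participant their
own tract). The latent effect is modeled as independent of exposure and
modifiers; a dependence of U on (X, C) is conceivable but is not
implemented.

Two identifiability facts shape the implementation:

- Sign: (U, λ_T, λ_M) → (−U, −λ_T, −λ_M) leaves the likelihood invariant,
  so λ_T is constrained positive (sampled on the log scale); λ_M is free.
- Scale: only the products λ_T·σ_u and λ_M·σ_u are likelihood-identified.
  All three parameters are retained (with their priors providing weak
  identification), the sampler includes a dedicated "ridge" move that
  rescales (σ_u, U) by c and (λ_T, λ_M) by 1/c so the chain traverses the
  ridge, and convergence is judged on the identified products
  `lt_sigma = λ_T σ_u` and `lm_sigma = λ_M σ_u`, which are also stored as
  derived draws.

## Priors

- Regression coefficients (β, α): Normal(0, 3.16²) — weakly informative,
  sd ≈ √10.
- log κ: Normal(0, 2²). A half-normal on log κ would force κ ≥ 1 and
  exclude decreasing hazards, which real survival data often show, so the
  symmetric form is used.
- σ_u and λ_T: half-Normal(1) on the natural scale (sampled as logs with
  the Jacobian included). λ_M: Normal(0, 1).
- GVS indicators: Bernoulli(0.5) a priori.

Scale-parameter prior densities are used in unnormalized form (constants
drop out of every Metropolis ratio); the test-suite's independent
re-summation uses the same convention.

## Sampler

Metropolis-within-Gibbs: single-site adaptive random-walk updates for each
coefficient, vectorized elementwise Metropolis for the latent vector (the
U_g are conditionally independent given the rest), and two joint moves that
fix the slow directions: the ridge move above, and a "timescale" move that
proposes log κ and compensates β₀ along β₀ + κ·mean(log t) = const, since
those two parameters are strongly negatively correlated in a Weibull model.
Proposal scales adapt toward a 20–45% acceptance rate during burn-in only
and are frozen afterwards to preserve detailed balance. Chains are
independently seeded; runs are deterministic given (seed, chain count).
Split-R-hat above 1.1 on any monitored parameter is flagged in the fit
report (never silently); R-hat/ESS tables come from arviz.

## Gibbs variable selection and the two-phase workflow

Candidate modifiers are age, BMI, income category, smoking, and
physical-activity guideline adherence. Categorical modifiers are
dummy-coded against declared references (never-smoker, PAGA = yes, lowest
income) and missing categorical values become explicit missing-indicator
columns rather than dropping rows (the cohort's income and activity
missingness is ~7–9%; deletion would distort the survival sample).
Sporadic missingness in continuous modifiers (~0.5%) is mean-imputed with a
logged warning.

Selection follows the Dellaportas indicator scheme: one binary γ_j per
modifier toggles all of that modifier's columns in the **hazard** linear
predictor; when a modifier is out, its coefficients are Gibbs-drawn from
pseudo-priors (posterior mean/sd of a pilot run with all modifiers in).
The mediator model always carries the full candidate modifier set. Two
reasons: (a) selection is introduced for the hazard's modifier term, and
the published layout reports a single frequency per modifier; (b) a shared
indicator toggling both models would pay the spike-vs-slab (Bartlett)
penalty once per coefficient across up to six columns and two models
(≈ −13 log-odds for a 6-column modifier under the sd-3.16 slab), so no
realistic modifier could ever be selected — inconsistent with the observed
near-0.5 frequencies. The workflow is two-phase: pilot → pseudo-priors →
GVS run recording inclusion frequencies → refit keeping only modifiers
with frequency strictly above 0.5 (a frequency exactly at the threshold is
excluded). Frequencies of forced-in modifiers are exactly 1 by
construction.

## Mediation estimand

For an exposure contrast x₀ → x₁ (default 0 → 1 on the standardized scale,
i.e., one SD):

- direct effect: exp(β_X (x₁ − x₀)) per posterior draw;
- indirect effect through level k: exp(β_Mk · Δp̄_k), with
  Δp̄_k = mean over participants (empirical modifier rows, the draw's
  latent values) of P(M = k | x₁, C, U) − P(M = k | x₀, C, U);
- total effect through k: the draw-wise product, so
  total = direct × indirect holds exactly for every draw.

This is a product-of-coefficients decomposition on the log-hazard scale,
conditional on U and averaged over the empirical covariate distribution.
The reference level has β_M ≡ 0 by coding, so its own indirect HR is
exactly 1 (its probability shift is still computed and reported). Whether
the estimand should instead marginalize over U, or target a natural rather
than controlled decomposition, is a genuine ambiguity; the implemented
estimand is therefore validated against a brute-force counterfactual
Monte-Carlo oracle (`true_mediation_effects`) that simulates mediator
categories at both exposure values over a large population — agreement
within combined Monte-Carlo error is the package's headline correctness
property rather than an algebraic claim. Intervals are equal-tailed 95%
percentile intervals (not HPD); an interval excluding HR = 1 is flagged
"well estimated". Tables print at 3 decimals.

## Multiple imputation of debulking status

Missingness in debulking is treated as MAR. The imputation model is a
logistic regression of observed status on study site, histology, stage,
adjuvant therapy, neoadjuvant therapy, and age, plus the Nelson–Aalen
cumulative hazard at the participant's follow-up time and the event
indicator (the survival-aware covariates of the White–Royston approach;
the Nelson–Aalen estimator itself comes from lifelines and is checked
against a brute-force risk-set computation). Proper MI: each of m = 25
datasets uses a fresh coefficient draw from the large-sample normal
approximation to the posterior (bootstrap would also be defensible; the
normal approximation is standard and cheap), and each missing value is a
Bernoulli draw. Perfect separation triggers a ridge-stabilized IRLS
fallback (λ = 1 on non-intercept terms) with a logged warning. The
analysis dataset is the per-participant mode across the 25 imputations;
ties break toward suboptimal, the worse-prognosis category (conservative;
with odd m ties arise only in degenerate configurations, but the rule must
exist). Observed values are never modified. A CA125-based deterministic
recode (post-adjuvant CA125 < 35 → optimal) is provided for cohorts that
carry the marker instead of a debulking field. Analysis models use the
consensus dataset; pooling estimates across the 25 fits (Rubin's rules) is
deliberately out of scope.

## Synthetic cohort generator

The generator draws from exactly the generative structure the joint model
assumes, so model fits on its output are correctly specified, plus the
clinical structure needed to make the imputation problem real. Defaults
define the emulated study conditions:

- n = 558 participants in 186 census tracts (~3 per tract), 11 sites;
- exposures are tract-level: each index value is mean + sd × (±0.6 F_g +
  noise) with a shared tract deprivation factor F_g, signs following each
  index's direction, and means/sds from the published cohort table
  (e.g., age 58.04 (10.90), BMI 32.82 (8.42), URB −0.40 (0.85),
  ADI 108.84 (19.99), CDI 0.00 (3.92));
- structural coefficients: β_X = log 0.731 per SD of URB, stage effects
  (0.5, 1.0) on the log-hazard, κ = 1.1, λ_T σ_u = 0.3, and mediator slopes
  α_X = (−0.10, −0.25), giving small per-level indirect effects (≈ 0.95 for
  the distant level) like those printed for this design;
- β₀ = −9.72 and a uniform administrative censoring window of 6–10.7 years
  with 5% early dropout, calibrated so the death fraction is ≈ 0.60 (a
  helper computes the implied death probability by numeric integration, and
  the test-suite checks the empirical fraction against it);
- debulking, when stage is the structural mediator, follows a passive
  clinical model: suboptimal rates ≈ (4%, 15%, 42%) by stage, per-site
  intercepts with sd 0.7 (inter-institutional variation in optimal-debulking
  rates is large), and +0.04/yr of age — the dependence structure that
  makes site/stage/age genuinely informative for imputation;
- missingness: debulking is blanked MAR through a logistic model in stage
  and event calibrated to ≈ 34% overall; modifiers and exposures get
  background MCAR missingness at the cohort's observed per-column rates.

Every generated cohort carries its generating truth (direct and per-level
indirect HRs computed by the MC oracle, plus the latent values), enabling
recovery tests. What the generator does **not** emulate: real census
geography or spatial autocorrelation between tracts, exposure measurement
error, competing risks, non-proportional hazards, or any dependence of the
latent effect on exposure. Passing tests therefore demonstrate correctness
of the machinery under the assumed model, not robustness to violations of
it.

## Problem sizes and numerical choices

Verification studies run at desk scale, chosen to finish in minutes: oracle
agreement on an n = 400 cohort with 10⁶ oracle draws; recovery over 20
replicates of n = 400 with 2 chains × 800 iterations (300 burn-in);
imputation accuracy averaged over 5 cohorts of n = 558 with m = 25. Full
analysis fits default to 2 chains × 1500 iterations (500 burn-in), which
brings all monitored R-hats near 1 on default-sized cohorts. Percentages in
descriptive tables use round-half-up to one decimal with non-missing
denominators, matching the published tables' conventions; with L levels
rounded independently, level percentages sum to 100 within L × 0.05.
Degenerate inputs fail loudly: non-positive times and unknown category
labels are rejected row-by-row at validation, zero-variance exposures raise,
κ ≤ 0 has log-posterior −∞.

## Known limitations

- The per-level indirect effect is one of several defensible estimands for
  a categorical mediator; conclusions about indirect paths should be read
  together with the reported probability shifts.
- The scale redundancy of (σ_u, λ_T, λ_M) means those parameters are
  individually prior-dependent; only their products are data-identified.
- GVS inclusion frequencies depend on the slab width (sd 3.16) through the
  usual Bartlett sensitivity; they are reported as evidence of modifier
  importance, not posterior model probabilities.
- The consensus-mode analysis understates imputation uncertainty relative
  to Rubin-pooled estimates; the between-imputation coefficient spread is
  written out as a diagnostic.
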