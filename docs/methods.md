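# Methods

This note documents the statistical model behind `cmrdiet`, the
assumptions of its synthetic cohort generator, the tunable parameters, and
the numerical choices made where the design was genuinely open.

## Composite risk score

Fourteen measures (BMI, WC, PBF, SBP, DBP, MAP, TG, TC, HDL-C, LDL-C,
TG:HDL ratio, fasting glucose, insulin, HOMA-IR) are standardized as
`z = (value − stratum mean) / stratum SD`, with strata defined by sex ×
integer age in years. Derived measures use:

* BMI = weight (kg) / height (m)²;
* MAP = DBP + 0.33 (SBP − DBP), in mmHg;
* HOMA-IR = insulin (μU/L) × glucose (mg/dL) / 405, with glucose converted
  from mmol/L at 18.0 mg/dL per mmol/L (panels carry glucose in mmol/L).

The composite is `CMRS = z(WC) + z(BP̄) + z(glucose) − z(HDL) + z(TG)`,
where BP̄ is the per-child mean of SBP and DBP standardized *as a single
variable*, i.e. z((SBP+DBP)/2). The alternative reading,
(z(SBP)+z(DBP))/2, differs only through the SBP–DBP correlation; the
literal single-variable form is implemented. CMRS is missing whenever any
of its five components is missing.

Numerical choices for standardization:

* **Stratum floor.** Strata with fewer than 20 children (configurable)
  borrow the nearest age stratum within the same sex that meets the floor;
  if no age stratum of that sex qualifies, the whole sex pools; failing
  that, the whole cohort. This keeps per-stratum SDs estimable in small
  cohorts while leaving large cohorts fully stratified.
* **Baseline-frozen reference.** The reference is fitted on the baseline
  visit only and reused at follow-up, so Δz measures real physiological
  change rather than drift in the reference population. Change scores are
  follow-up minus baseline.
* A stratum with zero variance in any measure is an error (it would make
  z undefined), reported with the measure and stratum.

Effect sizes for changes are classified at |d| thresholds 0.2/0.5/0.8 SD
for individual factors, and 1.0/2.5/4.0 for CMRS (which sums five
component Z-scores and therefore has a wider natural scale).

## Dietary features

Recall records (child × day × item, grams, kcal) are mapped to 26 food
groups through a frozen packaged map; per-group grams are summed within
day, averaged over the child's recall days, and divided by mean daily
energy: `g/100 kcal = 100 × mean g/day / mean kcal/day`. Averaging is
done *before* energy adjustment (adjusting per day and then averaging
differs when energy varies day-to-day; the analysis unit is the child, so
the child-level ratio is used). Items never reported by a child count as
zero consumption, not missing.

Exclusions: mean daily energy strictly below 300 or strictly above 3500
kcal/day (fixed kcal thresholds, configurable), children without any
dietary assessment, and children missing every cardiometabolic
measurement. Counts per reason are logged.

## Importance ranking

The cohort is split 50/50 (seeded) into training and test halves. Three
families are tuned on the training half by grid search scored with 5-fold
cross-validated R²:

| family | estimator | grid (defaults) |
|---|---|---|
| linear | elastic net | alpha ∈ {1e-4 … 1e-1}, l1_ratio ∈ {0.05, 0.5, 0.95} |
| forest | random forest, 500 trees | max_features ∈ {5, 9, 17}, max_depth ∈ {6, 12} |
| boosting | gradient boosting, 500 trees | max_depth ∈ {2, 3}, learning rate ∈ {0.05, 0.1}, row subsample 0.8, column subsample 0.8 |

The train-vs-CV R² gap is logged as an overfitting diagnostic. The family
with the best *held-out* R² wins (ties break in the fixed order linear <
forest < boosting). Its variable importances are permutation importances
computed on the test half (model-agnostic, hence comparable across
families; impurity importance is available for the forest), floored at
zero, and normalized to percentages summing to 100 across all 26 groups.
A degenerate all-zero importance vector (possible on pure-noise cohorts
where the elastic net shrinks everything away) normalizes to a uniform
attribution. The top-k groups (default nine) are the leading determinants.

## Healthy Diet Score

For each leading group, intakes are dichotomized at the baseline median —
groups with median zero dichotomize as zero vs any consumption — and the
adjusted mean ΔCMRS is compared between strata using the cluster-adjusted
baseline model (age, sex, baseline CMRS, class random intercept). A group
is *healthy-high* when high intake carries the lower adjusted ΔCMRS, else
*healthy-low*.

* **Unweighted score** (integer 0..k): one point per group strictly above
  the median (healthy-high) or at/below it (healthy-low). At the exact
  median a healthy-high group scores 0 and a healthy-low group scores 1,
  so a child at every median scores 6 under the default 3-high/6-low
  pattern.
* **Weighted score** (real in [0,1]): per-group sub-score prorated
  linearly between anchors — for healthy-high groups,
  s = clip(intake/p80, 0, 1); for healthy-low groups,
  s = clip(1 − intake/p80, 0, 1) — weighted by the importance
  contributions of the k groups renormalized to sum to 1. Renormalization
  (rather than raw percentages) fixes the score range at [0,1]; it changes
  the scale, never the ordering. Straight-line interpolation between the
  anchors is assumed for intermediate intakes.

Cutpoints, anchors, and weights are frozen from baseline and reused at
follow-up, so the HDS change reflects dietary change and not cutpoint
drift. The definition serializes to JSON and can be applied unchanged to
an external cohort. Scores band into ≤3, 4, 5, 6, 7, ≥8 for description
and association analysis.

## Association models

Outcomes are one-year change scores, modelled as linear mixed models with
a random intercept for class-within-school (statsmodels MixedLM, REML,
default BFGS optimizer with a Powell retry; an OLS fallback is used below
two clusters or on numerical failure — the fast l-bfgs path was dropped
after it returned corrupted fixed effects when the variance estimate hit
the boundary). Adjustment sets are nested:

* **M1**: age, sex, baseline value of the outcome;
* **M2**: + intervention arm, grade, puberty, baseline BMI, MET, baseline
  energy, fiber, vegetable, fruit, pork, and nuts/legumes intake;
* **M3**: + birthweight, breastfeeding, household income, parental BMI and
  education.

Band exposure is coded against the lowest band (≤3); the trend p comes
from a second fit with the band index entered continuously and is the
headline p for multiplicity control (the continuous-score trend is
available via the `hds_continuous` exposure). Confidence intervals use the
large-n normal approximation. Categorical confounders carry an explicit
`Missing` level; continuous covariates are complete-case. The BH step-up
rule is applied at q = 0.05 across the family of outcomes per exposure,
reporting the data-dependent p cutoff; pairwise band contrasts are
Bonferroni-adjusted (×C(6,2)=15, capped at 1). Moderation models add
exposure-by-modifier product terms (joint Wald test) and report
per-stratum slopes; strata without exposure variation are omitted with a
warning. Sensitivity analyses re-run the identical pipeline on the
control or intervention arm.

Note on the ICC→0 limit: when the true cluster variance is zero the mixed
fit is statistically equivalent to OLS, but the REML estimate does not
collapse exactly to the boundary on finite samples, so coefficients agree
to a fraction of a standard error rather than to machine precision. The
test suite checks agreement within 0.5 SE; exact equality holds for the
explicit fixed-effects fallback.

## Synthetic cohort generator

The generator emulates the data-generating process the analysis assumes;
it is the ground truth against which every stage is validated.

* **Diet.** Each group's g/100 kcal intake is zero-inflated lognormal
  (consumption probability 1−zero_prob; many groups need SD > mean, hence
  the point mass at zero plus right skew). Latent Gaussian copula
  correlations: 0.3 within declared food blocks (staples, treats, plants,
  animal, dairy), with pairwise overrides encoding the rice-vs-wheat
  staple-pattern opposition (rice anti-correlated with wheat, refined
  grains, fried foods, sweetened beverages; positively with seafood).
  Without these overrides the favorable rice signal is masked by its
  adverse neighbours, which contradicts the dietary-pattern structure the
  analysis is meant to detect. Daily recalls add lognormal within-child
  day-to-day noise with CV 30% (a free parameter — cohort reports rarely
  publish within-child recall variance; flagged in the config docs) over
  3 days per visit; follow-up intakes share latent correlation 0.6 with
  baseline. Energy is truncated normal (1269 ± 529 kcal, clipped to
  400–3400 so that default cohorts pass the exclusion filters at full n);
  per-item energies are allocated proportionally to grams × a per-group
  energy density.
* **Outcomes.** Baseline panels are drawn on physiological scales
  (glucose 4.5 ± 0.55 mmol/L, SBP ~100 mmHg, BMI ~17 kg/m², WC ~58 cm,
  insulin lognormal ~9 μU/L) with age/sex trends and realistic
  cross-correlations (WC–BMI, SBP–DBP ~0.55, TC–LDL). Follow-up equals
  baseline + drift + planted signal + noise, matching a change-score
  analysis.
* **Planted effect.** A latent change signal
  u = Σ_g β_g · x̃_g + confounder effects + class intercept + ε
  (x̃ the cohort-standardized g/100 kcal intake) is distributed equally
  across the five CMRS components in raw units (u/5 × component SD, HDL
  negated), so the pipeline's own Z-scoring recovers u as ΔCMRS. β is the
  `effect_vector` (units: ΔCMRS per SD of intake). Defaults: ε SD 0.6,
  per-component measurement noise 0.2 × component SD (≈0.45 ΔCMRS units
  jointly), class intercept SD 0.23 (ICC ≈ 0.05). These give a one-year
  ΔCMRS residual SD near 0.8 — smaller than large field cohorts show,
  chosen so the planted signals at the configured magnitudes are
  identifiable at the simulated sample sizes; conclusions about absolute
  power in real cohorts should not be read off these defaults.
* **Confounding.** Age, sex, intervention (assigned at school level),
  MET, and income have small outcome effects; income also shifts selected
  food intakes, so the nested adjustment models are genuinely
  distinguishable. The `null` fixture removes both the planted effects and
  the income→diet coupling, making diet and outcome marginally
  independent.
* **Fixtures.** `paper-like` (n=3000) plants nine effects among 26 groups
  with |β| ∈ [0.05, 0.3]: favorable (negative) for seafood, rice, and red
  meat other than pork; adverse for refined grains, fried foods,
  sugar-sweetened beverages, wheat, fungi/algae, and roots/tubers.
  `tiny` (n=50) serves unit tests; `null` (n=2000) has no diet effect.

What the generator does *not* emulate: seasonal variation in intakes,
item-level dietary diversity (one representative item per group),
nutrient composition beyond energy, informative missingness, attrition,
and any causal effect of the intervention program beyond a mean shift.
Passing tests therefore demonstrate that the pipeline recovers structure
it is designed for, not that it is robust to every artifact of real field
data.

## Validation studies and problem sizes

The test suite's statistical checks (all seeded) use these scales:

* BH FDR: 2000 replicate families of 50 two-sample tests (40 null, 10
  with 0.5 SD effects, n=200/arm); empirical FDR must stay ≤ 5% + 1.5
  Monte-Carlo points. `scripts/acceptance.py` recomputes this number.
* Brute-force oracle: all derived quantities (energy adjustment, MAP,
  HOMA-IR, BMI, CMRS, both HDS variants) recomputed with plain Python
  loops on the 50-child fixture; agreement to 1e-10.
* Ranking recovery: 20 paper-like cohorts (n=3000); the winner's top nine
  must contain ≥8 planted groups in ≥80% of seeds. Tests use a reduced
  search budget (150 trees, single-candidate tree grids, 5 permutation
  repeats) — the package default (500 trees, full grids) is used for real
  analyses.
* Direction recovery: all nine planted directions in ≥90% of 20 seeds.
* Mixed-model calibration: 95% CI coverage of a planted top-band effect
  within 95% ± 2% over 500 trials (n=2000, full M3 adjustment); trend-test
  type-I error within 3.5–6.5% over 1000 null trials.
* Score contracts: range, boundary (all-median child scores 6), best-diet
  child scores exactly 1 on the weighted scale, and monotonicity under
  1000 random perturbations.

## Known limitations

* Variable importance attributes shared variance to correlated groups
  jointly; the ranking identifies *predictors*, not independent causes.
* Normal-approximation CIs understate uncertainty in very small cohorts
  (the `tiny` fixture); the mixed model's cluster variance is weakly
  identified when clusters are few.
* The weighted HDS depends on baseline percentile anchors; applying a
  serialized definition to a cohort with a very different intake scale
  shifts the score's effective range.
* Trend tests use the band index (0–5); a strictly linear dose metric in
  the raw score is available via the continuous exposure but is not the
  default.
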