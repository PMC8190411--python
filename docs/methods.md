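# Methods

This note documents the statistical model behind `dietrrr`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real survey data.

## Reduced rank regression

**Model.** Predictors `X` are the n × 34 z-standardized usual food-group
intakes; responses `Y` are z-standardized, energy-adjusted Zn (mg/day) and
PUFA (g/day) intakes. RRR is implemented in the identity response metric:
factors maximize explained response *variance*, obtained by
eigendecomposition of `ŶᵀŶ` where `Ŷ` is the OLS fit of `Y` on `X`. The
canonical-correlation weighting (which rescales responses by their residual
covariance) is deliberately not used: the target quantity is "variation in
responses explained", and with two z-scored responses the identity metric is
the direct formalization. Because the factor score `fₖ = Ŷ vₖ` is the
orthogonal projection of the response score `tₖ = Y vₖ` onto the predictor
span, factor scores of distinct factors are exactly orthogonal, and
per-response explained variation (squared correlation with `fₖ`) accumulates
additively over factors.

**Numerics.** `(XᵀX)⁺` is a pseudo-inverse (`scipy.linalg.pinvh`), so exactly
collinear food groups do not break the fit; rank deficiency is reported as a
warning. Eigenvalues are clipped at zero and sorted descending; factors with
numerically zero eigenvalue (≤ 1e−12 relative) are flagged rather than
dropped. Standardization uses the sample SD (n − 1); constant columns are
dropped with a warning. The sign of each factor is fixed so that its
correlation with the Zn response is non-negative (ties resolved on PUFA) —
an arbitrary but deterministic convention that makes "Zn-rich" patterns
point in the positive direction.

**Loadings.** Default loadings are Pearson correlations between each
standardized food group and the factor score. Some PLS software instead
reports predictor-projection loadings `Xᵀf / fᵀf`; both are implemented
(`factor_loadings(..., kind="projection")`), correlations are the default
because the 0.20 membership threshold is conventionally applied to
correlation-type loadings. Two factors are retained by default — the
retention count is a parameter, not inferred from the data.

**Simplified score and quintiles.** Groups with |loading| ≥ 0.20 (boundary
included) contribute their z-scored intake, signed by the loading. Quintile
assignment is purely rank-based with stable tie-breaking by input order;
group sizes differ by at most one. Quintile cut-points are always computed
within a sex stratum, since every analytic stage is sex-stratified.

**Independent oracle.** The eigen-solution's first factor is validated
against `grid_search_max_explained`, a brute-force maximizer of mean
squared correlation over a dense spherical grid of unit predictor-weight
vectors (with local refinement). The grid search never touches the eigen
path, so agreement (observed ≲ 1e−7 at n = 200, p = 4) is a genuine
cross-check, not a tautology.

## Misreporting screen

Predicted total energy expenditure (MJ/day) uses the Vinken equation with
coefficients (7.377, −0.073·age, +0.0806·weight, +0.0135·height,
−1.363·sex). The plausibility band is the ±1 SD propagation
`sqrt(CV²_wEI/d + CV²_wpTEE + CV²_tmTEE)/100` with CVs 32.3 %, 20.2 %,
8.2 % and d = 2 recall days, i.e. 0.3157. Choices the source material left
open, fixed here and documented:

* EI for the screen is the **mean of the two recall days** (the standard
  choice for this screen family; per-day screening is not offered).
* Boundary ratios (exactly 1 ± SD) are **plausible** — the band is closed.
* kcal→MJ conversion is fixed at 0.004184.
* ±1 SD bounds exactly as printed, not ±2 SD, and no Goldberg-style
  PAL-stratified cutoffs.

Exclusions run in the stated order: age < 20, pregnancy, missing data
(weight, height, PUFA intake, Zn intake, serum LA, serum DGLA — covariate
missingness is *not* an exclusion), then under/over-reporting. Serum Zn
below 75 µg/dL is flagged for prevalence reporting only, never excluded.

## Usual intake

Two 24-h recalls cannot identify the full Multiple Source Method (which
additionally models consumption probability for episodically eaten foods).
The package therefore uses a declared plug-in shrinkage estimator: per food
group, a one-way ANOVA on persons splits the day-to-day variance into
between-person (σ²_b) and within-person (σ²_w) components, and

    usual_i = μ + (mean_i − μ) · σ²_b / (σ²_b + σ²_w/2).

Negative σ²_b estimates are truncated at zero (full shrinkage to the
population mean). This achieves the downstream purpose — attenuating
within-person noise before pattern extraction — and is exact in both limits
(identical days ⇒ identity; no between-person variance ⇒ population mean).
Usual-intake estimation is applied to food groups only; nutrient intakes
enter as two-day means.

## Energy adjustment

The regression residual method: nutrient regressed on total energy with
intercept, adjusted value = residual + nutrient mean. The adjusted vector is
exactly uncorrelated with energy in-sample and may be negative. Energy
adjustment is applied to the RRR responses (Zn, PUFA) *before* pattern
extraction, and energy is additionally retained as a model-2 covariate and
as the adjustment variable in food/nutrient trend tests (serum trend tests
are unadjusted, matching the published table conventions).

## Association layer

Partial correlations residualize both variables on energy (OLS with
intercept) and test the residual Pearson r on n − 3 df; a constant control
degenerates gracefully to the plain Pearson correlation. Trend tests regress
the person-level outcome on the ordinal quintile index 1..5 (an alternative
trend variable — the median score per quintile — was considered and not
adopted; the index is the common reading of "linear trend"). Chi-square
tests are Pearson, without continuity correction; expected counts < 5 are
flagged. Outcome regressions: model 1 is score-only; model 2 adds age,
energy, PIR, BMI, race, education, two vigorous-activity indicators,
lipid-lowering medication and supplement use, with categorical covariates
contrasted against the largest level in the stratum (recorded in the result
for reproducibility). All p-values are two-sided at the 0.05 convention; no
multiple-testing correction. Collinear designs and insufficient
complete-case counts raise errors naming the offending columns.

## Synthetic cohort generator

The generator defines the study conditions for all recovery tests. Defaults
(per sex stratum, n = 800):

| parameter | default | meaning |
|---|---|---|
| within_person_cv | 0.50 | day-to-day CV of each group intake |
| between_person_cv | 0.50 | person-to-person CV of usual intake |
| pattern2_strength | 0.60 | correlation of planted groups with the latent adherence factor |
| beta_ratio | −0.8 | planted slope of LA/DGLA per unit true pattern score |
| beta_dgla | +4.0 | planted slope of serum DGLA (µmol/L) |
| outcome_noise_sd | 6.0 | residual SD of the ratio (DGLA uses 7×) |
| misreport_fraction | 0.12 | planted under/over-reporters (split evenly) |
| misreport_factors | 0.5 / 1.6 | multiplicative reporting error |
| energy_balance_cv | 0.12 | log-normal deviation of true EI from pTEE |
| nutrient_noise_cv | 0.05 | measurement noise on nutrient/energy totals |

Intakes are log-normal (positive, right-skewed, as food intakes are); the
planted "rich in Zn, poor in PUFA" pattern raises low-fat dairy (G1),
whole-fat dairy (G2), red meat (G3) and fortified breakfast cereals (G17)
and lowers cakes/pastries (G13) and salad dressing (G30) — food groups whose
default Zn/PUFA densities make the contrast nutritionally coherent. Each
person's intakes are rescaled so expected energy equals Vinken pTEE times a
log-normal energy-balance deviation; diet *composition* (and with it the
planted pattern) varies at fixed energy, which is exactly the contrast the
energy-adjusted RRR is meant to find, and it makes the EI/pTEE screen
operate on ratios centred at 1. Misreporting multiplies *all reported*
quantities of a person by a single factor, so the screen can detect it;
true usual intakes and outcomes are untouched. Group medians and densities
were calibrated once so that a default cohort brackets population-scale
intake levels (Zn ≈ 9–13 mg/day, PUFA ≈ 15–21 g/day across sexes and
quintiles, serum Zn deficiency prevalence a few percent) and then frozen.

**What passing tests show — and don't.** Recovery of planted signs, planted
effects and nominal null coverage demonstrates that the pipeline's
statistics are implemented correctly and are jointly consistent under a
data-generating process with the assumed structure. They do not show that
two recall days suffice for real usual-intake estimation, that real food
groups are log-normal or independent beyond the planted structure, or that
survey-design features (weights, clustering, nonresponse) are ignorable —
none of which the generator emulates.

## Problem sizes

Unit tests run at n = 40–2000; cohort-scale recovery checks use 20 seeds at
n = 800 and 100+100 simulations at n = 500, sizes at which the planted
effects are comfortably identified while the whole suite stays
interactive-fast on a single CPU.

## Known limitations

* Real-data mode is schema-complete but best-effort: it has not been run
  against an actual NHANES download within this repository, and
  item-level (food-code) ingestion requires a user-supplied FNDDS mapping
  (a toy mapping ships for tests).
* The shrinkage usual-intake estimator ignores episodic consumption and
  covariate-dependent reporting error.
* No survey weights, mixed models, mediation, or multiple-testing
  correction — deliberately out of scope.
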