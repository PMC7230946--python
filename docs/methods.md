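# Methods

`dietcluster` implements a data-driven workflow for nutritional
epidemiology: derive a large panel of correlated diet-exposure variables
from 7-day food diaries, reduce them to a small set of non-redundant
representative exposures by clustering the *variables*, and estimate
prevalence ratios of a composite cardiometabolic-risk (CMR) outcome
across exposure quartiles. A synthetic-cohort generator with planted
structure provides ground truth for every stage. This note records the
models, the defaults and why they are what they are, the numerical
choices, and what the synthetic validation does and does not show.

## 1. Diary model and the 45 exposures

A diary is a long table of participant x day x eating-occasion rows over
eight predefined occasion slots (before breakfast, breakfast,
mid-morning, lunch, tea, evening meal, later evening, other), each row
carrying energy (kcal) and protein, carbohydrate, sugar, fat, saturated
fat (g) and fibre (g). Derivation rules:

* **Valid recording day**: total energy >= 500 kcal (inclusive); all
  averages run over valid days only. Participants are excluded
  sequentially — missing diet information, fewer than 5 valid days,
  chronic disease, incomplete outcome — and each exclusion is tallied
  under the first applicable reason.
* **Eating occasion**: any slot with >= 50 kcal (inclusive).
* **Meals**: breakfast slot -> breakfast, lunch -> lunch, evening meal ->
  dinner (configurable, since "tea" vs "evening meal" conventions vary);
  snack energy is the day total minus the three meal energies, so the
  four components sum to the day total exactly.
* **Energy-adjusted intake**: percent of energy via Atwater factors
  4/4/9 kcal/g (sugar as carbohydrate, saturated fat as fat; alcohol is
  not modelled). Fibre is expressed as g/1000 kcal. Meal-specific
  compositions use that meal's energy as denominator and are averaged
  over the days the meal was actually eaten (a day without the meal
  contributes *missing*, not zero, to composition — the composition of a
  non-eaten meal is undefined — but zero to meal energy). Daily
  compositions are computed per day and averaged (not ratio of
  averages); both choices are configurable.
* **Frequencies**: percent of valid days on which the occasion reaches
  50 kcal; the combined morning + late-night snack variable requires
  both on the same day. Denominators use valid days (the natural
  companion of the 5-valid-day inclusion rule); this is configurable.
* **Irregularity score** for an intake series x_1..x_d over valid days:
  mean(|x_i - mean(x)|) / mean(x) * 100. Zero means perfectly regular;
  the score is invariant under common positive rescaling, needs >= 2
  valid days, and is undefined (NaN) when the mean is zero. Scores are
  computed for daily energy, each macronutrient's daily grams, fibre,
  and the three meal energies (meal irregularity is on meal *energy*
  only). A constant series returns exactly 0 (short-circuited before the
  floating-point arithmetic).

The 45 variables (units: kcal, % energy, g/1000 kcal, occasions/day, %
of days, score) are registered centrally with group labels
(fat/carb/protein/frequency/energy/irregularity) and written with a JSON
metadata sidecar. Undefined values propagate as NaN and flag the
participant as having missing diet information.

**Transformation.** Each variable is mapped y = log(x + 1) — the offset
keeps exact zeros (frequencies, irregularity scores) defined; it is
configurable — then centred and scaled to unit *population* SD
(ddof = 0). With that convention the squared Euclidean distance between
two transformed columns is exactly 2 n (1 - r), which the clustering
stage relies on. Constant columns map to zero columns with a warning.

## 2. Clustering the variables

The objects clustered are the 45 transformed columns, viewed as points
whose pairwise distances are the column distances. An exact embedding is
obtained from the thin SVD of the transformed matrix (coordinates V·S,
then centred — distances are translation-invariant — and null directions
dropped), giving at most 44 dimensions without any distance distortion.

* **k-means**: Lloyd's algorithm with k-means++ seeding, best of
  `n_restarts` (default 100) initializations, deterministic given a
  seed (scikit-learn backend). On 45 points the k-means objective has
  many near-ties; more restarts stabilize the WCSS at each k.
* **Choice of k**: spherical-Gaussian BIC,
  `BIC(k) = n d ln(WCSS/(n d)) + k d ln(n)` with n = 45 variables and
  d the embedding dimension; lowest BIC wins, ties to the smallest k,
  WCSS floored at machine epsilon. The formula is one of several
  k-means BICs in use; it is recorded in run output and pluggable.
* **Index battery** (soft guidance, not selection): Calinski–Harabasz,
  average silhouette width, Hartigan's rule (smallest k with statistic
  <= 10), Davies–Bouldin, and a reduced-replicate gap statistic, each
  voting for its optimal k over the same partitions.
* **Hierarchical view**: agglomerative clustering (complete linkage by
  default) on the same distances, exported as Newick with branch
  lengths from merge heights (leaf labels quoted so underscores
  survive round-trips).
* **Silhouettes**: classical definition s = (b - a)/max(a, b) with a the
  mean distance to own-cluster members and b the smallest mean distance
  to another cluster's members; singletons score 0. A centroid-based
  variant (distances to centroids instead of members) is provided
  because descriptions of silhouette-style scores sometimes mean that;
  classical is the default.
* **Representatives**: per cluster, the member with the highest
  silhouette (ties broken to the lexicographically smaller name, so the
  choice is reproducible); the second-highest member is retained as an
  additional exposure exactly when |Pearson r| between the two
  transformed columns is below 0.50.

## 3. Outcome and association models

**CMR classifier.** A participant is a case when at least 3 of 5 criteria
hold: central adiposity (waist >= 94 cm men / >= 80 cm women);
dyslipidemia (HDL < 1.0 / < 1.3 mmol/L by sex, or non-HDL >= 4.0 mmol/L,
or lipid-lowering medication); elevated blood pressure (SBP >= 130 or
DBP >= 85 mmHg or medication); inflammation (CRP in [3, 10) mg/L — 10 or
above is treated as acute infection and does not qualify); impaired
glucose control (HbA1c >= 5.7 % or medication). All boundaries are
applied exactly as stated (inclusive `>=`, exclusive `<`). The glucose
criterion alone is the sensitivity outcome. Missing fields make the
outcome undefined, mapping to the incomplete-outcome exclusion.

**Quartiles.** Cut points are the 25/50/75 sample percentiles (linear
interpolation); values equal to a cut point fall into the lower
quartile, so heavy ties produce unequal quartile sizes (reported, not
hidden). Per-quartile n, mean, SD, range and median are tabulated.

**Models.** Logistic regression of the outcome on quartile indicators
(Q1 reference) with Wald 95% CIs. Model 1 adjusts for age, sex, and the
quartile *categories* of the other clusters' representative exposures;
model 2 additionally adjusts for region, education, work hours and
sleep duration (categoricals enter as drop-first dummies; constant
columns are dropped before fitting — in small samples empty dummy
levels otherwise make the Hessian singular). Non-convergence or
separation raises a fit error; the pipeline degrades per-exposure with
a warning.

**Prevalence ratios.** Because the outcome is common, odds ratios
overstate prevalence ratios; they are converted with
`PR = OR / (1 - P0 + P0·OR)`, P0 being the observed outcome proportion
in the reference quartile. The same P0 is applied to the point estimate
and both CI bounds, so the PR intervals are approximate (this is the
standard behaviour of the conversion; it is noted in output). For
P0 in (0,1) the PR lies strictly between 1 and the OR, reaching the OR
as P0 -> 0.

**Trend.** The quartile indicators are replaced by one continuous
covariate carrying each participant's quartile median (raw scale); the
Wald p-value of its coefficient is p_trend.

**Stratified / interaction.** Models are refit within each stratum of a
binary stratifier (continuous stratifiers are median-split); the
interaction p-value is a likelihood-ratio test (3 df) comparing pooled
models with and without quartile x stratum products.

**Sensitivity.** (a) restrict to BMI >= 25 and add continuous BMI;
(b) refit with the glucose-only outcome.

No multiple-testing correction is applied (threshold 0.05), matching
standard practice for this kind of exploratory quartile analysis.

## 4. The synthetic-cohort generator

The generator is the package's ground truth, not a fixture: four latent
traits per participant (fat composition; meal frequency and energy;
carbohydrate/fibre; protein plus intake regularity) drive
participant-level "drivers" — breakfast carbohydrate share, snack-slot
presence propensity, day-to-day noise scale, and so on — each loading on
exactly one trait with loading sqrt(rho), rho being the within-block
target correlation (default 0.6). Diaries are then expanded day by day:

* Slot presence is Bernoulli per day with participant-specific logits
  (main meals ~90–97%, snacks 8–55%); the main-meal logit is driven by
  a shared meal-regularity driver and, weakly, by the energy-scale
  driver (larger habitual eaters skip fewer meals).
* Occasion energies are log-normal per slot with main meals larger than
  snack slots, so meal skipping and sub-50-kcal occasions arise
  naturally; a shared day factor, per-meal day noise, and
  occasion-level noise are all scaled per participant by irregularity
  drivers (one per score family, log-scale SD 0.5 — consistent with the
  roughly threefold spread between extreme irregularity quartiles seen
  in diary cohorts).
* Macronutrient shares live on the simplex via softmax of Gaussian
  logits (person SDs 0.30/0.24/0.24 for protein/carb/fat, matching
  published quartile spreads, e.g. carbohydrate ~39% to ~56% of energy
  across extreme quartiles); day-to-day logit noise is comparable to
  the person-level spread (ratio 1.2; protein 2.0). Sugar and saturated
  fat are logistic-normal fractions of carbohydrate and fat, so the
  subset constraints hold by construction; fibre density is log-normal
  around 8.5 g/1000 kcal.
* Each record's macronutrient grams then receive independent
  multiplicative measurement noise (log-SD 0.22), standing in for
  portion-size estimation and food-composition coding error — a
  documented, substantial error source in diary data. Occasion energy
  is recomputed from the noisy grams, so energy remains the exact
  Atwater sum and the percent-energy closure (protein% + carb% + fat% =
  100) is exact.
* Optional under-reporting multiplies a participant's energies by
  exp(-slope · max(BMI - 25, 0)) (default slope 0), to exercise the
  BMI-restricted sensitivity analysis.

**Outcome planting.** Case labels are drawn from a logistic model:
logit = logit(baseline prevalence, default 0.36) + per-quartile-step
log-odds for chosen exposures (defaults protective for carbohydrate %,
fibre density and eating occasions/day, magnitudes matching
prevalence-ratio effect sizes around 0.8–0.9 across extreme quartiles)
plus centred age and sex terms. Biomarkers are then sampled *consistent
with the drawn label*: a case's criterion count is drawn from {3,4,5},
a control's from {0,1,2}; which criteria hold is a weighted
without-replacement draw (Gumbel top-m), optionally tilting the glucose
criterion by an exposure's quartile so glucose-specific effects can be
planted without moving composite prevalence; each biomarker is sampled
strictly beyond or below its cutoff. The CMR classifier therefore
reproduces the planted labels exactly — a round-trip the tests assert.

**Calibration.** The generator's defaults were calibrated once so that
the *realized* exposure correlations express the intended near
compound-symmetric four-block structure — directly-driven same-block
pairs near 0.6, between-block pairs near 0 — rather than the mechanical
sub-blocks that naive settings produce (shared day draws otherwise make
the ten irregularity scores correlate at ~0.99). Mechanical couplings
that real data also exhibits remain: daily and per-meal compositions of
the same nutrient overlap (~0.7–0.8), sugar tracks carbohydrate,
carbohydrate % and fat % are strongly negatively correlated through the
simplex constraint, and cross-family same-block pairs attenuate to
0.3–0.5 through estimator noise.

**What the generator does not emulate.** Food items and portion
structure; weekday/weekend and seasonal patterns; correlation between
BMI and the planted biomarkers (waist is sampled around the criterion
cutoff, not from BMI); selective non-response. Passing tests therefore
show that the *method* behaves correctly under a known, realistic
correlation structure — not that any particular substantive finding
would replicate in a real cohort.

## 5. What the validation shows

* **Exclusion bookkeeping** on a 9018-participant fixture with planted
  exclusion groups reproduces the sequential tally exactly
  (150/277/499/2, leaving 8090).
* **Cluster recovery**: on default cohorts of n = 2000, the BIC scan
  selects k = 4 and k-means recovers the planted partition with
  adjusted Rand index 1.0 in >= 90% of seeds (measured ~95–97% over 80
  fresh seeds). The selection margin is intrinsically modest: the BIC
  above accepts a split whenever it removes more than about 8% of the
  WCSS (the threshold is n^(-1/n) with n = 45), and residual mechanical
  sub-structure occasionally crosses it.
* **Effect recovery**: a planted extreme-quartile prevalence ratio of
  0.8 at n = 8000 is recovered with ~94–100% CI coverage and >90% trend
  power over 50 seeds; under the null, quartile CIs cover 1 at ~95% and
  trend p-values are uniform (Kolmogorov–Smirnov).
* **Estimator attenuation**: 7-day estimates recover the participant's
  true (expected) exposure at r > 0.9 for daily energy and most daily
  compositions, ~0.85–0.9 for protein/carb/fat (which carry the largest
  day-to-day variation), ~0.6–0.7 for irregularity scores, and much
  lower for near-constant frequencies (dinner is eaten on ~97% of days;
  seven Bernoulli trials cannot rank participants on that). This
  hierarchy is intrinsic to short diaries, not a defect of the
  derivation; it is why simulation sizes of 1000+ participants are used
  for structure-recovery checks.

## 6. Numerical and reproducibility choices

* All randomness flows from `numpy.random.default_rng(seed)`;
  identical configuration + seed gives byte-identical outputs, which
  the pipeline manifest verifies with SHA-256 checksums of every text
  output (plots are excluded from checksums).
* Problem sizes in the test-suite simulations: n = 2000 cohorts and 20
  seeds for cluster recovery, n = 8000 and 50 seeds for effect
  recovery, 200 replicates of n = 2000 for null calibration; the
  modelling-stage simulations use the direct participant-level exposure
  sampler (`sample_exposure_matrix`), which preserves the planted joint
  structure while skipping diary expansion.
* Quartile boundaries use linear-interpolation percentiles; tie-breaks
  (quartile assignment, silhouette ties, BIC ties) are all "toward the
  lower/smaller" and deterministic.
* Logistic fits: statsmodels Newton MLE, 200 iterations, convergence
  required; constant design columns dropped; separation and
  non-convergence raise typed errors rather than returning numbers.

## 7. Known limitations

* The PR confidence intervals inherit the approximation of applying the
  reference-quartile P0 to both OR bounds.
* The k-means BIC formula is a convention; other formulas shift the
  chosen k and can be substituted.
* The silhouette definition used by variable-clustering analyses is not
  always stated precisely in the field; both the classical and the
  centroid variant are implemented, and on these data they order
  cluster members similarly but not identically.
* Irregularity scores from 7 days are noisy estimates of a
  participant's true day-to-day variability; analyses treating them as
  exact exposures understate attenuation.
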