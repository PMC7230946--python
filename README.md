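# dietcluster

Data-driven diet-exposure analysis for 7-day food diaries: derive 45
exposure variables (energy, macronutrient composition, meal frequencies,
intake-irregularity scores), reduce them to a non-redundant set by
clustering the *variables* themselves, and estimate prevalence ratios of
cardiometabolic risk (CMR) across exposure quartiles.

It is written for nutritional epidemiologists who face many highly
correlated candidate exposures — composition, timing, regularity — and
want a reproducible, testable way to pick a small set of primary
exposures before modelling, instead of running (and correcting for)
dozens of collinear regressions.

## The method

1. **Derivation.** From occasion-level diaries (8 predefined slots/day),
   derive per participant: average daily energy and energy-adjusted
   macronutrient intakes (% of energy via Atwater 4/4/9), fibre density
   (g/1000 kcal), the same per meal (breakfast/lunch/dinner, snacks as
   the daily remainder), meal and snack frequencies (% of valid days
   with >= 50 kcal in the slot), eating occasions/day, and irregularity
   scores — for series x over valid days,

       irregularity(x) = mean(|x_i - mean(x)|) / mean(x) * 100,

   0 = perfectly regular. A valid day has >= 500 kcal; participants
   need >= 5 valid days. Variables are log(x+1)-transformed and
   z-scaled.

2. **Variable clustering.** The 45 z-scaled columns are embedded exactly
   as points (squared distance 2n(1-r), r = Pearson correlation) and
   clustered with best-of-restarts k-means; the number of clusters is
   chosen by a spherical-Gaussian BIC, cross-checked by a battery of
   classical indices and a hierarchical dendrogram. Each cluster's
   **representative** is its highest-silhouette member; the runner-up is
   retained as a separate exposure when its correlation with the
   representative is below 0.50.

3. **Association.** CMR is >= 3 of 5 criteria (central adiposity,
   dyslipidemia, elevated blood pressure, inflammation, impaired glucose
   control). For each selected exposure, logistic models on quartiles
   (Q1 reference; adjusted for age, sex, and quartiles of the other
   clusters' representatives; model 2 adds region, education, work
   hours, sleep) give odds ratios that are converted to prevalence
   ratios with PR = OR / (1 - P0 + P0·OR), P0 the reference-quartile
   prevalence; trends are tested on quartile medians; stratified,
   interaction (likelihood-ratio), BMI-restricted and glucose-only
   analyses complete the suite.

Because real occupational-cohort diary data are access-restricted, the
package ships a first-class synthetic-cohort generator with planted
four-block correlation structure among the 45 variables and planted
exposure-outcome effects, so every stage can be validated against known
truth (see `docs/methods.md`).

## Worked example

```
dietcluster all --outdir runs/demo --seed 7 -n 2000
```

synthesizes a 2000-participant cohort, applies the exclusion chain,
derives and transforms the 45 exposures, clusters them, classifies CMR,
fits the quartile models, and prints:

```
{
 "chosen_k": 4,
 "selected_exposures": [
  "satfat_pct_daily",
  "irreg_energy",
  "sugar_pct_daily",
  "energy_kcal_daily"
 ],
 "exclusion_tally": {
  "missing_diet": 2,
  "too_few_valid_days": 13,
  "chronic_disease": 0,
  "missing_outcome": 0,
  "included": 1985
 }
}
```

The BIC scan chose four variable clusters (the planted truth) and one
representative per cluster — here saturated fat % (fat-composition
cluster), energy irregularity (protein/regularity cluster), sugar %
(carbohydrate cluster) and daily energy (frequency/energy cluster); no
runner-up cleared the 0.50 collinearity rule at this seed. 15 of 2000
participants were excluded (2 with undefined exposures, 13 with fewer
than 5 valid days). `runs/demo/results_main.md` then holds one block per
exposure and model, e.g.

```
### satfat_pct_daily (model 1)

| | Q1 | Q2 | Q3 | Q4 |
|---|---|---|---|---|
| Mean (SD) | 8.84 (1.54) | 12.24 (0.79) | 15.35 (1.02) | 20.55 (3.04) |
| Range | 3.68-10.85 | 10.85-13.61 | 13.62-17.17 | 17.18-33.66 |
| Cases/N | 118/497 | 124/496 | 147/496 | 124/496 |
| PR (95% CI) | 1.00 (ref) | 0.99 (0.78; 1.23) | 1.11 (0.88; 1.37) | 0.88 (0.68; 1.12) |

p_trend = 0.394
```

read as: participants in the top saturated-fat quartile (mean 20.6% of
energy) had an estimated CMR prevalence 0.88 times that of the bottom
quartile, CI spanning 1 — no association, consistent with no planted
saturated-fat effect. The run directory also contains the BIC scan,
cluster assignment with silhouettes, index votes, the dendrogram
(Newick), the correlation matrix, the outcome table, the sensitivity
tables, and a manifest with SHA-256 checksums (re-running the same
configuration reproduces them byte for byte).

The same workflow is available as a library — `generate_cohort`,
`derive_exposure_matrix`, `transform_exposures`, `bic_scan`,
`select_representatives`, `fit_quartile_model`, `or_to_pr`,
`trend_test`, ... — see the docstrings and `docs/methods.md`.

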