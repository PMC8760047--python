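# bmivol

Joint mixed-effects analysis of diagnosis, body mass index (BMI) and
subcortical brain volumes in multi-site case-control cohorts, with a gated
bootstrap mediation analysis of group differences through BMI.

## The problem

People with bipolar disorder (BD) are substantially more likely to be
overweight or obese than controls, and obesity itself is associated with
subcortical brain alterations. In case-control neuroimaging, an apparent
"diagnosis effect" on a regional volume may therefore be partly carried by
the groups' BMI difference. This package implements the full analysis chain
needed to ask that question on a long-format cohort table (one row per
subject x hemisphere x region of interest):

* **Per-ROI linear mixed models.** For each of eight bilateral subcortical
  ROIs (lateral ventricles, accumbens, amygdala, hippocampus, pallidum,
  putamen, caudate, thalamus), three models of volume are fitted — group
  only, BMI only, and group + BMI jointly — always with age, sex,
  hemisphere and total intracranial volume (ICV) as fixed covariates and
  random intercepts for data-collection site and for subject (hemispheres
  nest within subjects). Estimation is REML via `statsmodels` MixedLM.
* **Effect sizes from coefficients.** Group contrasts as Cohen's
  *d* = *t*(n₁+n₂)/(√DF·√(n₁n₂)); BMI associations as the partial
  correlation *r* = *t*/√(*t*²+DF); both with 95% CIs. *p*-values are
  Benjamini–Hochberg FDR-adjusted across the eight ROIs within each model
  family × term.
* **Gated mediation.** An ROI enters mediation analysis only if (1) group
  predicts its volume, (2) group predicts BMI, (3) BMI stays significant in
  the joint model, and (4) adjusting for BMI shrinks the group coefficient.
  The indirect effect a·b (group→BMI path times BMI→volume path) gets a
  percentile CI from 5000 participant-level bootstrap resamples (stratified
  by site), a proportion mediated 100·|a·b|/|c|, and a Sobel *z*
  cross-check.
* **Descriptives.** Welch two-sample *t* tests (Welch–Satterthwaite df),
  Pearson chi-square tests, WHO BMI categories.

Because the multi-site cohorts this analysis is designed for are not
publicly distributable, the package ships a synthetic-cohort generator
(`bmivol.cohort`) that reproduces the statistical structure — site and
subject variance components, group covariate shifts, QC-style missingness,
and a *known, configurable* indirect effect — so every stage is testable
against ground truth.

## Worked example

The `analysis/` scripts run the whole chain on a generated reference-scale
cohort (17 sites, 2735 subjects, 1601/1134 control/case target split):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_descriptives.py
python analysis/03_fit_models.py
python analysis/04_mediation.py
python analysis/05_medication_posthoc.py
python analysis/06_simulation_studies.py
```

Step 01 reports the generated cohort and its built-in mediated path:

```
cohort: 2735 subjects (1597 control / 1138 case), 41588 hemisphere x ROI rows
group BMI means: 24.53 vs 26.74 kg/m^2
built-in ventricular indirect effect: 122.15 mm^3
```

Step 03 fits 24 mixed models and FDR-adjusts within each family; on this
realization the diagnosis is associated with larger ventricles and smaller
amygdala, hippocampus, pallidum and caudate, BMI positively with ventricles
and amygdala and negatively with pallidum, and no group x BMI or BMI x site
interaction survives screening:

```
group_only: significant after FDR -> lateral_ventricles (group: +0.17),
  amygdala (group: -0.09), hippocampus (group: -0.15), pallidum (group: -0.17),
  caudate (group: -0.17)
bmi_only:   significant after FDR -> lateral_ventricles (bmi: +0.12),
  amygdala (bmi: +0.08), pallidum (bmi: -0.05)
group x BMI interactions retained: none
BMI x site random-slope signals: none
group variance differences span 0.7-7.5% across ROIs
```

Step 04 evaluates the four mediation criteria per ROI — only the lateral
ventricles pass (the amygdala fails criterion 4: adjusting for BMI
*strengthens* its group effect, a suppression pattern) — and bootstraps the
ventricular indirect effect:

```
gate lateral_ventricles: passes
gate amygdala: fails: criterion 4: coefficient_attenuated
...
indirect effect a*b = 175.07 mm^3 (95% CI 108.32; 250.35)
proportion mediated = 30.13% (95% CI 16.34; 60.09)
Sobel Z = 4.73, p = 0.0000
```

(The point estimate sits within sampling error of the built-in 122 mm³;
step 06 quantifies this: across 200 simulated cohorts the mean recovery
bias is a few percent and the bootstrap CI covers the truth ~93% of the
time.)

A `bmivol` CLI exposes the same stages on any cohort CSV
(`bmivol simulate|descriptives|fit|mediate|report|all --help`).

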