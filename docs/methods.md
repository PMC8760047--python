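# Methods

## Model

The substrate is a tidy long table: one row per subject × hemisphere × ROI,
with site, diagnostic group (control/case), age (years), sex, BMI (kg/m²),
total ICV (mm³), hemisphere and volume (mm³). For an ROI volume *y* the
working model is

    y_ijk = Xβ + u_site(i) + u_subj(j) + ε_ijk,
    u_site ~ N(0, σ²_site),  u_subj ~ N(0, σ²_subj),  ε ~ N(0, σ²_res)

with fixed effects X covering group, BMI, age, sex, hemisphere and ICV (the
subsets depending on the model family). The hemisphere-level residual plus
the subject intercept is the minimal structure that makes
"hemisphere-within-subject" variation estimable with one observation per
subject × hemisphere; the hemisphere mean offset is a fixed effect.
Estimation is REML through `statsmodels` MixedLM, with site as the grouping
factor and subject intercepts as a variance component. ML is used whenever
likelihoods are compared (AIC ranking of random structures; the
random-slope LRT).

**Degenerate inputs.** A deterministic outcome (zero residual after the
fixed effects) is returned as the exact interpolating least-squares
solution rather than handed to the optimizer; a spec with no random terms
reduces to OLS. Variance components estimated at the boundary (zero) are
recorded as notes, not treated as failures; true optimizer non-convergence
is flagged on the result and surfaced by the pipeline.

**Denominator DF.** Published mega-analyses of this design report
containment-style denominator DFs. The default convention is

    DF = n_obs − (#fixed coefficients) − (#subjects + #sites consumed),

which reproduces that magnitude pattern; `df_method="residual"` gives the
plain n_obs − p convention. The true DF convention of any particular
published table cannot be pinned without its per-ROI QC counts, so this is
deliberately configurable rather than asserted.

**Effect sizes.** Group contrasts: Cohen's d = t·(n₁+n₂)/(√DF·√(n₁n₂)) —
the unequal-group-size form used in large consortium analyses; its CI uses
SE_d = √((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))). BMI associations: partial
r = t/√(t²+DF), CI by Fisher z with effective n = DF + 2. Report rounding
is half-up to two decimals.

**Multiplicity.** Benjamini–Hochberg across the eight ROIs within each
model family × term (the family matching the per-column star pattern of the
usual results table), α = 0.05 by default. Gating decisions use the
FDR-adjusted p-values.

**Interaction screens.** Group × BMI enters as a fixed product term,
FDR-adjusted across ROIs, retained only when significant. BMI × site is
tested as an ML likelihood-ratio test of a site-level random BMI slope
(slope variable centered so the slope variance is not confounded with the
site intercept); since the null pins one variance at the boundary, the
p-value uses the ½χ²₀ + ½χ²₁ mixture.

## Mediation

Paths: a = group coefficient of the mediator model BMI ~ group + age + sex
+ (1|site) on subject-level rows; b and c′ = BMI and group coefficients of
the joint outcome model; c = group coefficient of the group-only outcome
model. Indirect effect a·b; proportion mediated 100·|a·b|/|c| (magnitudes,
flagged as "inconsistent mediation" when indirect and total effects have
opposite signs). The four-condition gate (group→volume, group→BMI, BMI
significant jointly, |c′| < |c|) must pass before bootstrapping, unless
explicitly forced.

**Bootstrap.** The resampling unit is the participant (both hemispheres
travel together), with replacement, stratified by site with the original
per-site counts — unstratified resampling can empty a site and break the
site term. The 95% CI is the 2.5/97.5 percentile interval of the replicate
a·b values (the plain percentile interval is the reported method; BCa is
not). One master `SeedSequence` spawns per-replicate substreams, so
enlarging n_boot extends rather than reshuffles the replicate sequence.
Replicates whose fits fail are dropped and counted; more than 5% dropped is
a hard failure.

**Refit modes.** `mode="full"` (default) refits the hemisphere-level mixed
models in every replicate. `mode="collapsed"` refits ordinary least squares
with site fixed effects on subject-level bilateral means — the same
estimands, point estimates essentially identical (site dummies absorb the
site intercepts; hemisphere averaging is exact for subject-level
predictors), at ~1000× the speed. The simulation studies and the
reference-scale bootstrap in the analysis scripts use the collapsed mode;
the full mode is exercised in the test suite at small n_boot.

**Sobel cross-check.** Z = a·b/√(a²SE_b² + b²SE_a²) with a two-sided normal
p-value, reported alongside the bootstrap CI (the bootstrap is the primary
inference; the Sobel test is known to be the more conservative of the two).

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes:

* 17 sites × ~161 subjects by default (2735 total), case fraction
  1134/2735; per-site case counts are deterministic (rounded) so the split
  tracks the target.
* Age: control 35.47 (12.63), case 41.72 (12.66) years, truncated to
  [18, 90]. Sex: P(female) 0.5721 / 0.6032. BMI: 24.43 (4.12) vs 26.80
  (5.22) kg/m², floored at 14 after the group shift. ICV: 1.5e6 (1.5e5)
  mm³, independent of group.
* The group→BMI path a is either implied by the per-group means (2.37
  kg/m²) or set explicitly (`bmi_path_a`), in which case BMI is the control
  distribution plus an additive case shift. The built-in indirect effect on
  each ROI is a·β_BMI and is recorded in the provenance JSON emitted next
  to every generated CSV.
* Per-ROI group and BMI coefficients default to the joint-model magnitudes
  of the reference analysis under case-positive coding (e.g. ventricles
  +500.84 mm³ direct group effect, +51.54 mm³ per BMI unit; amygdala −29.70
  and +3.55 — the sign combination that produces the suppression pattern).
  ROI means, covariate slopes and variance components are field-realistic
  values chosen once (e.g. per-hemisphere ventricle mean 8000 mm³ with
  subject SD 3500; hippocampus 3800 with SD 380); volumes are floored at
  1 mm³, which binds only deep in the ventricular tail.
* QC-style missingness withholds both hemispheres of a subject × ROI
  jointly at rate 0.05 by default, mimicking ROI-level quality failure.
* Optional medication fields: medication-class count 0–3 and lithium
  (rate 0.455) among cases, with optional loadings of a shared latent
  driver onto medication count, BMI and ventricular volume to construct
  overlapping-predictor scenarios; loadings default to zero
  (independence).
* Group coding: case = 1, so a positive group coefficient means larger
  volumes in cases. Published tables using the opposite coding are
  reproduced by the report layer's `legacy_sign` toggle, which flips group
  coefficients and their effect-size CIs in the rendered table only.

What the generator does **not** emulate: non-Gaussian volume distributions,
scanner/protocol heterogeneity beyond a site intercept, covariate-dependent
QC failure, and any causal (as opposed to merely associative) structure.
Passing tests therefore demonstrate the statistical machinery under the
assumed data-generating process, not robustness of the scientific
conclusions to violations of it.

## Simulation studies and problem sizes

* **Recovery/coverage** (`mediation_recovery_study`): single-ROI cohorts of
  10 sites × 60 subjects with a = 2.4, β_BMI = +47 and direct effect
  +501.2 mm³ (true indirect 112.8 mm³, proportion mediated 18.4%);
  200–600 simulations, 500 bootstrap replicates each. Variance components
  for this study (site 300, subject 1500, residual 400 mm³ SD) are kept
  moderate so the Monte-Carlo error of the bias and coverage estimates is
  small relative to the quantities themselves. Measured behavior: recovery
  bias within a few percent; percentile-CI coverage ≈ 93% (the familiar
  slight undercoverage of percentile intervals for coefficient products).
* **Size control** (`bootstrap_null_study`): same conditions with a = 0;
  500 simulations. The CI excludes zero in ≲5–7% of runs.
* **FDR null** (`fdr_null_study`): eight-ROI cohorts of 8 sites × 40
  subjects with all group/BMI effects zero, 60 simulations (480+ ROI
  tests); model fits use the subject-collapsed structure so the study runs
  in seconds — the FDR step under test is identical to the
  hemisphere-level path.

## Numerical choices

* Continuous predictors are scaled (not centered) by their SD internally
  for optimizer conditioning; coefficients and SEs are transformed back
  exactly, so centering a covariate changes the intercept only.
* Perfect collinearity in the fixed design raises a design error for model
  fits but is reported as an infinite VIF by the collinearity check.
* Marginal/conditional R² follow the variance-partition definition:
  var(Xβ̂) over (var(Xβ̂) + σ²_site + σ²_subj + σ²_res), the conditional
  version crediting the random-effect variances to the numerator.
* The linear-mediation identity c = c′ + a·b is exact (machine precision)
  only when all three regressions condition on the same covariate set; the
  mediator model follows the reporting convention (age, sex, site — no
  ICV/hemisphere), so on finite samples the identity holds to ~1e-3
  relative rather than exactly. Tests verify the exact identity with a
  matched-covariate path-a oracle.

## Known limitations

* The subject variance component is fitted as per-site dummy blocks, which
  scales to a few hundred subjects per site; very large sites would need a
  sparse two-level solver.
* The bootstrap full-refit mode is 2–3 orders of magnitude slower than the
  collapsed mode and is impractical for thousands of replicates at
  reference scale.
* Welch tests on generated cohorts compare truncated normals (age bounds,
  BMI floor), so generated t statistics sit slightly below the values
  implied by the untruncated parameters.
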