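# Methods

This note documents the statistical model behind each stage, the defaults
and their rationale, what the cohort simulator does and does not emulate,
and the package's numerical choices and known limitations.

## Cohort simulator

The simulator is the package's study-conditions definition: every
operating-characteristic claim in the test suite is a statement about data
generated this way.

**Site structure.** The default configuration replicates a reference
88-sample healthy cohort: per-site sample sizes (18,605 participants at
full scale), age windows, age means/SDs (ages drawn from per-site truncated
normals) and per-site male fractions (48.3% male overall) are taken from
the bundled `site_descriptors.csv`.  `scale` multiplies all site sizes
(minimum 5) so structurally identical smaller cohorts can be generated; the
pipeline default is `sim_scale = 0.65` (~12,000 rows), chosen so a complete
run finishes in well under a minute on one core while every stratum keeps
hundreds of observations.

**Observation model.** For site i, region r, hemisphere h:

    y = δ_ir · ( μ_r(age, sex) + b·(ICV − ICV₀) + ε_rh ) + γ_ir

with γ_ir ~ N(0, site_shift_sd²) and δ_ir ~ U(site_scale_range), both drawn
per site and region; ICV ~ N(1.5·10⁶, (1.5·10⁵)²) mm³ and b = 0.002 mm³/mm³
for every region (a realistic order for subcortical-volume–head-size
coupling); left/right noise correlation fixed at 0.8.  The multiplicative
site effect is applied before the additive one, matching the location-scale
model ComBat removes.  Noise SDs are per region (95 mm³ accumbens to
1,600 mm³ ventricles, roughly 8–30% CV); for the heteroscedastic regions
(ventricles, hippocampus, amygdala) the SD grows linearly in age
(28 / 6 / 2.5 mm³ per year), emulating rising inter-individual dispersion in
late life.  A configurable fraction of rows (default 0.3%) is displaced by
±6 noise SDs in all 16 volumes to exercise the outlier screen.

**Trajectory archetypes.** Three piecewise-linear ground-truth shapes:
early peak (age 8) with linear decline (basal ganglia); rise to age 25, an
exactly flat plateau to `plateau_end`, then linear decline (thalamus,
hippocampus, amygdala — the "flattened inverted U"); and monotonic linear
increase from age 3 (ventricles).  Piecewise-linear truths make the plateau
and monotonicity contracts exactly testable; the cost is that no fractional
polynomial can represent the flat-plateau-plus-kink shape perfectly (see
Limitations).  Sex enters as an additive male−female difference.

**What is not emulated:** longitudinal (within-person) structure, scanner
drift over time, age×sex interactions, non-Gaussian measurement error,
segmentation failures that corrupt single structures rather than whole
rows.  Passing tests therefore demonstrate the estimators' behaviour under
a clean location-scale site model, not robustness to all real-data
pathologies.

## Quality control

Complete-case filtering requires age, sex, ICV and all 16 volumes.  The
outlier screen computes squared Mahalanobis distances of the 16-volume
vector from the pooled mean and covariance (pooling across sites after
merging); a ridge of 1e−6 × mean diagonal is added to the covariance before
inversion.  Rows beyond the χ²(1−α, 16) quantile are excluded; α defaults
to 0.001 (expected false-exclusion rate 0.1% under normality, threshold
39.25).  α = 0 disables the screen; a per-site variant is available.  The
variable set (volumes only) and the cut-off are configuration options
because reasonable practice varies.

## ICV adjustment

Within each site and structure, `adjusted = raw − b·(ICV − mean ICV)` with
b the within-site OLS slope.  This is an analysis-of-covariance adjustment:
it zeroes the within-site volume-on-ICV slope exactly and preserves the
site mean.  Sites with fewer than 10 complete rows inherit a pooled slope
(site-centered regression across all rows) combined with their own ICV
mean, since a 3-row slope estimate is noise.  The pipeline flag
`icv_adjust=false` reruns everything on unadjusted volumes as a sensitivity
path.

## Site harmonization (ComBat)

Parametric empirical-Bayes ComBat on the features × subjects matrix of the
16 volumes.  Standardization regresses the data on batch indicators plus
the covariate design, with the grand mean taken as the size-weighted
average of batch intercepts and the pooled variance from the full residual.
The preserved design is intercept, sex contrast (±0.5, so the intercept is
the cross-sex mean) and a cubic polynomial of (age − 45)/45 — flexible
enough not to bend trajectories, linear in parameters, and
configuration-exposed.  Per-batch location (normal prior) and scale
(inverse-gamma prior) estimates are shrunk with method-of-moments
hyperparameters and iterated conditional posterior means until the maximum
relative change is below 1e−4 (cap 100 iterations) — reference
implementation values.  The implementation agrees with the R reference
(`sva::ComBat`) to ~1e−14 on shared fixtures, which one test asserts.

Choices: joint 16-feature harmonization by default (per-hemisphere flag
available); scanner identifiers are the batch labels; a single-batch input
passes through with a warning; `eb=False` skips shrinkage and gives exact
per-batch mean/variance matching (useful as an oracle and for tiny feature
sets where across-feature priors are meaningless — the code also falls back
to it automatically when the across-feature spread of scale estimates is
degenerate).

Caveat: when batch and age are strongly confounded (sites with narrow,
disjoint age windows), part of the true age signal lives in between-site
means and is partially absorbed by the batch effects; the marginal age
slope after harmonization can be attenuated by a few percent.  This is a
property of the ComBat model itself, shared by the reference
implementation, and is why the covariate-preservation test uses overlapping
site age windows.

## Fractional-polynomial trajectories

Degree-m fractional polynomials transform x = age/10 (the conventional
preliminary scaling, recorded in `FPSpec` so curves are reproducible) with
powers p₁ ≤ … ≤ pₘ from {−2, −1, −0.5, 0, 0.5, 1, 2, 3}, 0 meaning ln x
and a repeated power contributing the previous column × ln x.  Fits are
Gaussian OLS with the ±0.5 sex contrast; deviance is n·ln(RSS/n);
standard errors are cluster-sandwich by site with a G/(G−1)·(n−1)/(n−k)
small-sample factor (heteroscedasticity-robust when one site);
`partial_r2_age` is the R² gain of the full model over the age-free model.

Degree selection is a closed test at α = 0.01 (strict, to resist
overfitting where the age distribution is dense).  The best FP of each
degree 1..3 is found by exhaustive search (8/36/120 candidates); then:
best FP₃ vs the age-free model (χ², 6 df) — if not significant the age-free
model is returned; FP₃ vs the straight line (partial F, 5 numerator df);
FP₃ vs best FP₁ (χ², 4 df); FP₃ vs best FP₂ (χ², 2 df); the lowest degree
not significantly worse wins.  Gating on the age-free comparison first is
what gives the procedure its family type-I control at ~α, which the suite
verifies by simulation; the complete comparison trace is stored on every
fit for audit.  2 df per degree step (power + coefficient) is the standard
convention.

Degenerate inputs: an exactly noise-free response makes the likelihood
ratio infinite and raises with advice to jitter; collinear bases (constant
age) raise.  Sex-stratified fits drop the sex column and skip a sex with
fewer than 50 rows.  Age-band Pearson correlations (6–29 / 30–59 / 60–90)
are emitted pooled and per sex; bands with < 3 rows or zero variance report
a missing value.

## Inter-individual variability

The band statistic is ln(Σeᵢ²/nₜ) with residuals from the pooled-sex
selected FP fit (the primary reported model).  Rows aged 3–5 precede the
early band and are excluded from band analyses only.  The omnibus test
across bands is Brown–Forsythe (median-centered Levene) by default —
robust to non-normal residuals — with Bartlett behind a flag; its size and
power are verified by simulation.  The family threshold is 0.05/16 =
0.003125 (reported to three decimals as 0.003).

The meta-analytic view computes each site's SD of the adjusted volume
(overall and per band), transforms to ln s + 1/(2(n−1)) with sampling
variance 1/(2(n−1)) (the first-order bias correction is toggleable), and
pools by DerSimonian–Laird with τ² truncated at zero.  Sites with n < 2 or
zero SD are dropped with a warning; fewer than two usable sites is an
error, and a band absent everywhere is omitted with a warning.

## LMS centiles

The age-conditional distribution of each positive volume is Box-Cox
Cole–Green: z = ((y/μ)^λ − 1)/(λσ) (λ ≠ 0; the log branch at λ = 0), with
the log-likelihood Σ[λ ln(y/μ) − ln σ − z²/2] up to data constants; the
positivity-truncation term is omitted as usual for σ ≪ 1.  λ is an
age-constant scalar (stable in the small-df regime; a curve adds little for
these data), ln μ and ln σ are unpenalized B-spline expansions with knots
at age quantiles.  For each (df_μ, df_σ) in the default grid
{3,4,5,6} × {2,3,4} the likelihood is maximized by L-BFGS-B (λ bounded to
[−3, 3]; ln μ initialized by regressing ln y on the basis, ln σ at the
residual SD) and the model minimizing GAIC = −2ℓ + k·(1 + df_μ + df_σ)
with k = 3 (between AIC's 2 and BIC's ln n) is kept, with the full grid
trace.  A single-entry grid skips the search.  Centile curves are
μ(1 + λσz_p)^{1/λ} (μ·e^{σz_p} at λ = 0), strictly increasing in the level
at every age; `centile_of` inverts them exactly.  Extrapolation beyond the
fitted age range raises unless explicitly allowed.  Strata are structure ×
hemisphere × sex (32 per run); the log link keeps μ, σ positive by
construction, and nonpositive input volumes (possible for simulated
ventricles at young ages) are dropped per stratum with a log entry.
Default reported levels are {5, 25, 50, 75, 95}, configurable.

## Pipeline and reproducibility

Stage order: read-or-simulate → complete cases → Mahalanobis exclusion →
ICV adjustment (unless bypassed) → ComBat → 16 trajectory selections
(+ sex-stratified fits and band correlations) → 16 variance reports +
overall and per-band lnSD meta-analyses → 32 centile strata.  All tables
are UTF-8 CSV, all models JSON, configuration YAML; the manifest records
the configuration, its hash, the seed, package version and artefact list,
and contains no timestamps, so a rerun regenerates every output
bit-identically.  Exit codes: 0 success, 2 validation failure, 3 numerical
failure.  The CLI (`simulate`, `qc`, `harmonize`, `fit-trajectories`,
`variability`, `centiles`, `run-all`) is a thin layer over these functions.

## Known limitations

- A degree-≤3 fractional polynomial cannot represent a truth that is
  exactly flat over a long plateau and then kinks into decline; the best
  achievable fitted-vs-true curve correlation for the inverted-U archetype
  under the reference age distribution is ≈0.992–0.994 even noiselessly,
  and realized end-to-end values are ≈0.986–0.990.  Interpretation of the
  plateau-adjacent ages should rely on the fitted curve's confidence band,
  not its point shape.  Relatedly, for the early-decline archetype the
  closed test may choose power 2 instead of 1 when young-childhood rise
  data are present; both fit comparably.
- ComBat assumes site effects are location-scale and not fully confounded
  with covariates; with disjoint site age windows some true age signal is
  absorbed (see above).
- The variance analysis contrasts three fixed bands; it is not a
  variance-trajectory model.
- Robust (MCD) Mahalanobis screening, non-parametric ComBat, mixed-effects
  or spline trajectory alternatives, and four-parameter (kurtotic) centile
  families are out of scope.
- Centiles estimated from synthetic or convenience cohorts are not clinical
  reference ranges.
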