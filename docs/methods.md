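# Methods

`metabocontrast` implements an extreme-contrast molecular epidemiology
workflow: a mortality-trained metabolomic score is projected for every
participant, individuals at the score extremes (population cohorts) or the
most score-discordant monozygotic co-twins (twin registry) are selected, and
cytokine and plasma-proteomics panels are tested for association with the
high/low contrast. Because the real cohort data are not redistributable, the
package ships a synthetic-data generator that reproduces the *statistical
structure* of such a study, with known ground truth, so every stage is
testable end to end.

## The generative model

Each participant carries a latent health trait `L`. In the population
cohorts

    L = a·A + sqrt(1 − a²)·R + b_age·(age − mean(age))/10 + b_sex·(sex − ½)

with `A` the additive-genetic component, `R` the non-genetic remainder
(both standard normal), `a² = h2_true` (default 0.4). In the twin registry
the classical ACE decomposition is used instead:

    L = a·A + c·C + e·E,   a² = h2_true,  c² = c2_true,  e² = 1 − a² − c²

where `A` is identical within MZ pairs and correlates 0.5 within DZ pairs
(no assortative mating, no dominance — the assumptions under which the
Falconer estimator is unbiased), `C` is fully shared within a pair and `E`
is individual. The trait has unit variance before the age/sex terms, so
`h2_true` is directly the squared genetic path coefficient. Co-twins share
age and sex; defaults `b_age = 0.25` per decade, `b_sex = 0.10`.

Three omics layers hang off the trait, all generated on the log scale and
exponentiated so that values are strictly positive:

* **Metabolites** (14 analytes): `log x_j = μ + l_j·L + σ_m·ε`. The analyte
  set defines the score, so the latent trait is *identified with the score's
  systematic component*: loadings are ±1 (signs matching the direction each
  analyte moves with poorer health) and the residual noise `σ_m = 0.05`
  represents technical measurement precision (≈5% CV, a realistic figure
  for targeted NMR quantification). Two consequences were checked
  analytically and by simulation: (i) the projected score correlates > 0.999
  with `L`, so the score-scale heritability equals `h2_true` up to a
  negligible proxy attenuation (`r²`); (ii) score measurement noise `u`
  enters within-pair difference regressions with variance `2·var(u)` against
  a reduced trait-difference variance `2(1 − rMZ)·var(L)`, while it enters
  population regressions once against the full `var(L)`. With noisy
  analytes this errors-in-variables asymmetry makes attenuation bias
  relatively stronger in the within-pair design — a real phenomenon of
  discordant-twin analyses, and the reason the noise default is kept at
  technical-precision level: the package's attenuation comparison is meant
  to isolate *genetic confounding*, not measurement-error geometry. This is
  also the main caveat when reading the synthetic results onto real data,
  where analyte noise is larger.
* **Cytokines** (15, Luminex-style): log-normal with an additive trait
  effect and a recorded lower detection limit (LOD). Six panel members have
  their LOD placed one SD above their median, reproducing the situation
  where a feature is undetected in most samples and must be excluded rather
  than imputed. Censoring is applied by `apply_detection_limit` as a mask
  plus recorded LOD — never by value substitution — because the
  detectability analysis downstream needs the mask itself. The real assay's
  LODs and dilution-specific limits are not public; the defaults are free
  parameters of the generator.
* **Proteins** (66, MS-proteomics-style): three planted classes.
  `null` proteins are pure noise (false-positive controls); `environmental`
  proteins follow `β·L`; `pleiotropic` proteins follow `β·L + γ·A`, i.e.
  they share genetic influences with the trait. Six additional null
  proteins carry a 30% missingness rate so the missingness filter has real
  work to do; the remainder default to 1% (`inject_missingness`, MCAR).

Covariates (BMI, lymphocyte %, monocyte %, medication indicators) are
generated with configurable trait slopes (lymphocyte % decreasing by
default, mirroring the inflammation-linked lymphopenia the score tracks).
Ages are uniform within cohort-specific ranges chosen to preserve the
age contrast between a middle-aged cohort (~57), an older cohort (~74) and
a young twin registry (~36). All randomness flows from a single seed
through named substreams, so outputs are bit-identical across runs.

## Score projection and selection

The score is `Σ_j w_j z_j` over log-transformed, per-cohort z-scaled
analytes. Analytes containing any zero use `log(x + 1)` for *all* of their
values; all-positive analytes use the natural log (the base is irrelevant
after z-scaling). z-scaling uses the n−1 sample SD. The shipped coefficient
table (`data/synthetic_score_coefficients.tsv`) is synthetic — signs are
direction-faithful, magnitudes arbitrary — because the published
coefficients belong to an external reference; any user-supplied table with
`analyte`/`weight` columns is accepted.

Selection operates on the age-independent part of the score: the OLS
residual of score on chronological age (mean-zero, age-uncorrelated,
idempotent). Cases are the top-n residual scores. Controls are admitted
greedily in ascending score order, each requiring at least one case of
identical sex within ±2.5 years (the tolerance is configurable; the value
halves a 5-year matching bin, standard in nested case-control designs).
Greedy admission, not optimal bipartite matching, is intentional: the
design is "the lowest scorers that have at least one admissible case".
In the twin registry, complete MZ pairs are ranked by absolute within-pair
score difference; the top pairs are taken and the higher-scoring co-twin
is the case. All orderings tie-break lexicographically on sample/pair id.

## Panel preprocessing

Cytokines: detectability 2×2 tables (detected/undetected × case/control)
per feature with two-sided Fisher exact tests (BH-adjusted); features
undetected in strictly more than 65% of samples are removed; the 5-SD
outlier rule runs on the raw scale with mean and SD from a single pass
including the candidates; the survivors get log + per-cohort z.

Proteomics: features with strictly more than 5% missing values are removed
(an absolute-count mode exists as an alternative); 5-SD outliers are masked
to missing; the remaining holes are imputed with NIPALS; then log +
per-cohort z. Two deliberate choices here:

* **Imputation on the log scale.** On raw log-normal intensities a low-rank
  reconstruction can undershoot below zero, leaving the subsequent log
  undefined; on the log scale the additive PCA model is the natural one for
  multiplicative intensity data and imputations stay in-domain.
* **NIPALS with refinement sweeps.** Score/loading updates restrict all
  sums to observed cells. A single greedy pass (fit, deflate, repeat) is
  not the joint least-squares optimum when cells are missing, so the
  implementation follows the sequential pass with sweeps that re-fit each
  component against the residual of the others and re-estimate feature
  means from the completed matrix, until the imputed cells change by less
  than `tol` (default 1e-6; components default 5, small relative to the
  analyzed sample count). This converges to the completion an
  alternating-least-squares or EM-PCA solver finds (tested against both on
  exact low-rank matrices), recovers rank-1 matrices to machine-level
  relative error, and never touches an observed cell. Non-convergence is a
  warning, not an error.

All exclusion thresholds use strictly-greater semantics: a feature at
exactly 65% undetected, exactly 5% missing, or a value at exactly k SD is
retained. Whether z-scaling should use the analyzed extremes only or the
full cohort is not determinable from the design; the package scales over
the analyzed set (the default elsewhere would leak unselected samples into
location/scale estimates of a case-control analysis), and the functions
accept any cohort-label vector if a caller wants otherwise.

## Association models

`AssociationScan` fits, per feature, OLS of the prepared feature on
`[intercept, status, covariates]` over complete cases; the estimate is the
status coefficient (case-minus-control difference in feature-SD units),
with t-based two-sided p (df = n − k) and 95% CI. Covariate sets are named
("age_sex", "age_sex_bmi", "full" — the latter adding BMI, cell
percentages and medication indicators); BH-FDR is applied within each
platform × covariate-set family, matching per-platform reporting. When the
data are complete the scan solves all features against the shared design
matrix in one pass; the path is numerically identical to the per-feature
fit (asserted in tests) and cross-checked against statsmodels OLS. A
cohort fixed effect is deliberately *not* included in combined-cohort
models (features are already z-scaled per cohort, and the per-cohort scans
plus meta-analysis are the instrument for cohort heterogeneity).

`RandomEffectsMeta` pools per-study estimates under
`y_i ~ N(μ, v_i + τ²)`; τ² maximises the restricted likelihood (profiled
over μ) by bounded scalar optimisation with the boundary τ² = 0 checked
explicitly, pooled estimate = inverse-variance weighted mean at the REML
τ², pooled SE = (Σw)^(−1/2). With one study the pooled result is that study
and τ² = 0; with τ² = 0 the estimator coincides with fixed-effect pooling.

`WithinPairModel` is the discordant-twin analogue: a pair random-intercept
model `y = Xβ + u_pair + ε` fitted by REML, profiling the restricted
likelihood over λ = σ²_pair/σ²_resid after rotating each pair into
(sum, difference)/√2 coordinates, where the covariance is diagonal. λ is
floored at 0 (the fit then equals OLS); a zero residual variance is a hard
error. Inference uses a deliberately conservative df = n_pairs −
rank(between-pair design) − 1 rather than a Satterthwaite approximation.
The status coefficient equals the mean within-pair case-minus-control
difference whenever covariates are pair-constant (asserted against a
paired-difference oracle, and against statsmodels MixedLM).

Twin resemblance uses the double-entry Pearson correlation (each pair
contributes both orderings, removing labelling arbitrariness) with Fisher-z
CIs at effective n = number of pairs — double entry must not halve the SE.
Heritability is Falconer's `h² = 2(rMZ − rDZ)`; values outside [0, 1]
(possible by sampling error) warn rather than raise. The pipeline computes
twin correlations on the age-residualised score: co-twins share age, so
pair-shared age variance would otherwise inflate both correlations equally
and attenuate the h² estimate; linear age effects are removed exactly by
the residualisation.

## The attenuation comparison

The mechanistic signature of genetic confounding is that a pleiotropic
protein's *population* association with the score exceeds its *within-MZ-
pair* association, while a purely environmental protein shows the same
slope in both designs. This comparison is made on per-score-unit slopes
(`population_score_slopes`, `within_pair_score_slopes`): regression of
log-intensity on the score in the cohort, and of within-pair intensity
differences on within-pair score differences across the selected discordant
pairs. Slopes are the right scale here because selecting samples on the
regressor leaves OLS slopes unbiased, whereas case/control coefficients on
within-set z-scaled features shrink with the realized score contrast — the
twin design's contrast is roughly half the population design's (visible in
the pipeline's `score_contrasts`), which would fake attenuation for every
protein class. Under the default conditions the pleiotropic class shows a
within-pair/population slope-magnitude ratio of ≈ 0.66 while the
environmental class sits at ≈ 1.00 with a non-significant paired difference
over 200 replicates.

## Pipeline, sizes and numerical conventions

`run_pipeline` executes simulate → censor/missingness → score → select →
prep → scans (combined and per cohort) → REML meta → twin analyses →
concordance → cytokine/metabolite correlations, writing every stage as TSV
(values at 17 significant digits; below-LOD flagged as `<LOD` tokens in a
companion mask file; missing = empty cell) plus a schema-validated
`summary.json` and a `MANIFEST.json` of SHA-256 hashes. Re-running with the
same config and seed reproduces every byte. Default problem sizes are the
study-scale conditions: cohorts of 2,300 and 2,900, a registry of 726 MZ +
450 DZ pairs, 25 cases/controls and 25 discordant pairs, 14 + 15 + 66
features; a full run takes a couple of seconds on one CPU. The reproduction
experiments in `metabocontrast.experiments` use 200 replicates/seeds for
averaged quantities.

Other conventions: two-sided Fisher p by the point-probability rule (the
convention of standard exact-test implementations, verified against exact
integer enumeration over all small-margin tables); perfect-fit OLS reports
a vanishing p rather than erroring; BH adjustment is capped at 1 and
order-preserving; REML tolerances 1e-10 (τ², λ); lexicographic tie-breaks
everywhere selection or ranking occurs.

## Known limitations

* The generator is a linear-Gaussian idealisation: no platform batch
  effects beyond cohort location/scale, MCAR missingness (real proteomics
  missingness is partly intensity-dependent), no assortative mating or
  dominance, same-sex DZ pairs only, and analyte noise at technical
  precision (see above). Passing tests demonstrate the statistical
  machinery is correct under these assumptions, not that real data meet
  them.
* Falconer's formula is a moment estimator; it ignores the ACE boundary
  and can leave [0, 1]. Full variance-component twin modelling is out of
  scope.
* Below-LOD cytokine values are masked, not modelled; a censored-likelihood
  (Tobit) treatment is out of scope by design.
* The matched-control search is greedy; an adversarial score/covariate
  configuration admitting a feasible optimal matching could still fail the
  greedy pass.
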