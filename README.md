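# metabocontrast

Analysis toolkit for **extreme-contrast studies of a metabolomic mortality
score**: which circulating cytokines and plasma proteins differ between
people with very high and very low values of an NMR-metabolomics health
score, and how much of that association survives a genetically matched
(discordant monozygotic twin) comparison?

It is aimed at molecular epidemiologists running nested case-control
designs on top of biobank metabolomics: the package projects the score,
selects the contrast groups, preprocesses left-censored cytokine panels and
missingness-ridden proteomics panels, and runs the association, replication
and heritability analyses. Because cohort data of this kind cannot be
redistributed, a first-class synthetic-data generator reproduces the
statistical structure of a three-cohort study (two population cohorts plus
a twin registry) with known ground truth, so the entire workflow runs — and
is tested — end to end out of the box.

## What it computes

* **Score projection** — for sample *i* with z-scaled log analytes
  *z<sub>ij</sub>* and coefficients *w<sub>j</sub>*:
  *S<sub>i</sub> = Σ<sub>j</sub> w<sub>j</sub> z<sub>ij</sub>*, followed by
  residualisation on age (selection uses the age-independent score).
* **Contrast selection** — top-*n* scorers as cases with greedily admitted
  sex-matched, age-tolerant controls (population mode); the *n* most
  score-discordant complete MZ pairs, higher scorer = case (twin mode).
* **Panel preprocessing** — per-feature case/control detectability with
  two-sided Fisher exact tests; exclusion of features undetected in > 65% of
  samples or missing in > 5%; 5-SD outlier masking; NIPALS imputation of
  remaining holes (observed-cells-only updates, never altering a measured
  value); log + per-cohort z-scaling.
* **Association scans** — per-feature OLS of the prepared feature on case
  status plus named covariate sets (age/sex … full clinical), BH-FDR within
  platform × covariate-set; cross-cohort pooling by a REML random-effects
  meta-analysis (*y<sub>i</sub> ~ N(μ, v<sub>i</sub> + τ²)*); within-pair
  random-intercept mixed models (REML) for the twin design; beta-beta
  concordance between designs; feature-feature correlation maps.
* **Twin heritability** — double-entry Pearson twin correlations with
  Fisher-z CIs and Falconer's *h² = 2(r<sub>MZ</sub> − r<sub>DZ</sub>)*.

The statistical core follows the Model → `fit()` → Results convention
(`AssociationScan`, `RandomEffectsMeta`, `WithinPairModel`), each Results
object carrying estimates, standard errors, CIs, p/FDR and a `summary()`.

## Worked example

Estimate the heritability of the score in a simulated registry of 726 MZ
and 450 DZ twin pairs with true heritability 0.4:

```python
from metabocontrast import (SimConfig, simulate_twin_registry,
                            score_pipeline, default_coefficients,
                            twin_correlations)

cfg = SimConfig(seed=7)                      # defaults: h2_true = 0.4
samples, mats, truth = simulate_twin_registry(cfg)
scores = score_pipeline(mats["metabolomics"], default_coefficients(), samples)
print(twin_correlations(scores["age_residual_score"], samples).summary())
```

```
Twin correlations: rMZ = 0.403 (95% CI 0.340-0.462, 726 pairs), rDZ = 0.186 (95% CI 0.095-0.274, 450 pairs)
Falconer h^2 = 2(rMZ - rDZ) = 0.434
```

The MZ correlation estimates the trait's a² (0.4), the DZ correlation ½a²,
and the Falconer estimate recovers the simulated heritability within its
single-draw sampling envelope (SE ≈ 0.12 at these pair counts; the mean
over 200 seeds lands within ±0.03 of 0.4).

The full pipeline — simulate three cohorts, score, select 25+25 extremes
per population cohort and 25 discordant MZ pairs, preprocess both panels,
scan, meta-analyze and run the twin analyses — is one call (or
`metabocontrast run --out outdir --seed 7` on the command line):

```python
from metabocontrast import PipelineConfig, run_pipeline
summary = run_pipeline(PipelineConfig(seed=7), "outdir")
```

Highlights of `outdir/summary.json` from that run:

```
cytokines excluded : ['GRO1a', 'IFNg', 'IL1b', 'IL2', 'PAI1', 'TRAIL']   (6 of 15, >65% undetected)
significant counts : proteomics age_sex = 41, twin_proteomics age_sex = 42 (of 60 analyzed)
heritability       : h2 = 0.434  (rMZ = 0.403, rDZ = 0.186)
score contrasts    : LLS = 17.95, RS = 18.19, NTR = 8.93
concordance        : 40 proteins significant in both designs, 20+, 20-, 0 sign flips
```

Reading the numbers: the six cytokines with detection limits above most of
their distribution are excluded rather than imputed; the planted
environmental and pleiotropic proteins (40 of 60) are detected in both the
population and within-pair scans with fully concordant signs; and the twin
design's realized score contrast (8.9) is roughly half the population
extremes' (~18) — discordant co-twins cannot differ in the heritable part
of the score, which is the design's point. Every output file is listed with
its SHA-256 in `outdir/MANIFEST.json`; re-running with the same seed
reproduces each byte.

## Command-line interface

```
metabocontrast simulate|score|select|prep|associate|meta|twin|run ...
```

Each subcommand is a thin wrapper over the library; `--help` documents the
options. Exit codes: 0 success, 2 validation error, 1 runtime failure.

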