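"""Mortality-score projection from a 14-analyte metabolomic panel.

The score is a weighted sum of log-transformed, per-cohort z-scaled analyte
levels. Analytes containing any zero use ``log(x + 1)`` (so zero maps to
zero); all-positive analytes use the plain natural log. Because z-scaling
follows the log, multiplying an all-positive analyte by a constant (a unit
change) has no effect on the score.

Sample selection downstream operates on the age-independent part of the
score: the residual of an ordinary least-squares regression of the score on
chronological age.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import FeatureMatrix, ScoreCoefficients


def default_coefficients() -> ScoreCoefficients:
    """The synthetic coefficient fixture shipped with the package.

    Weights are synthetic: signs follow the direction each analyte moves
    with poorer health, magnitudes are arbitrary. They are NOT the published
    mortality-score coefficients, which are external reference material.
    """
    with resources.files("metabocontrast").joinpath(
        "data/synthetic_score_coefficients.tsv"
    ).open("rb") as fh:
        table = pd.read_csv(fh, sep="\t")
    return ScoreCoefficients(list(table["analyte"]), table["weight"].to_numpy(float))


def log_transform(matrix: FeatureMatrix) -> FeatureMatrix:
    """Natural-log transform; analytes containing any zero get ``log(x+1)``.

    The +1 shift applies to *every* value of a zero-containing analyte, not
    just to its zero cells, so the transform stays monotone per analyte.
    Negative values are a hard error (they indicate a unit or parsing
    problem upstream, not a measurable concentration).
    """
    values = matrix.values
    neg = values.lt(0)
    if neg.to_numpy().any():
        feat = neg.any(axis=0).idxmax()
        sample = neg[feat].idxmax()
        raise ValueError(
            f"negative value in analyte {feat!r} at sample {sample!r}; "
            "log transform undefined"
        )
    has_zero = values.eq(0).any(axis=0)
    out = matrix.copy()
    shifted = values.add(has_zero.astype(float), axis=1)
    out.values = np.log(shifted)
    return out


def zscale_per_cohort(
    matrix: FeatureMatrix, cohort_labels: pd.Series
) -> FeatureMatrix:
    """Standardise each feature to mean 0, sample SD 1 (n-1 denominator)
    within each cohort; masks are untouched."""
    cohort_labels = pd.Series(cohort_labels).reindex(matrix.sample_ids)
    if cohort_labels.isna().any():
        missing = matrix.sample_ids[cohort_labels.isna()][0]
        raise ValueError(f"no cohort label for sample {missing!r}")
    out = matrix.copy()
    scaled = out.values.copy()
    for cohort, idx in cohort_labels.groupby(cohort_labels).groups.items():
        block = out.values.loc[idx]
        n_distinct = block.nunique(dropna=True)
        n_obs = block.notna().sum()
        bad = (n_distinct < 2) | (n_obs < 2)
        if bad.any():
            feat = bad.idxmax()
            raise ValueError(
                f"feature {feat!r} is constant (or <2 observations) within "
                f"cohort {cohort!r}; cannot z-scale"
            )
        scaled.loc[idx] = (block - block.mean()) / block.std(ddof=1)
    out.values = scaled
    return out


def project_score(
    matrix: FeatureMatrix, coeffs: ScoreCoefficients
) -> pd.DataFrame:
    """Raw score per sample: the dot product of the z-scaled analytes with
    the coefficient weights. Refuses silently-imputed input: any missing
    value in a scored analyte is an error."""
    missing_cols = [a for a in coeffs.analyte_names if a not in matrix.feature_names]
    if missing_cols:
        raise ValueError(f"analyte column(s) absent from matrix: {missing_cols}")
    block = matrix.values[coeffs.analyte_names]
    if block.isna().to_numpy().any():
        nas = block.isna()
        feat = nas.any(axis=0).idxmax()
        sample = nas[feat].idxmax()
        raise ValueError(
            f"missing value in scored analyte {feat!r} at sample {sample!r}; "
            "no silent imputation"
        )
    raw = block.to_numpy() @ coeffs.weights
    return pd.DataFrame({"raw_score": raw}, index=matrix.sample_ids)


def residualize_on_age(scores: pd.DataFrame, ages: pd.Series) -> pd.DataFrame:
    """Add the age-independent score: OLS residual of ``raw_score`` on age.

    Residuals are mean-zero and uncorrelated with age within the fitting
    population by construction. Idempotent: residualising a residual score
    again changes nothing (beyond floating noise).
    """
    ages = pd.Series(ages).reindex(scores.index)
    if ages.isna().any():
        raise ValueError(f"no age for sample {scores.index[ages.isna()][0]!r}")
    if len(scores) < 3:
        raise ValueError("need at least 3 samples to residualise on age")
    x = ages.to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("age vector is constant; residualisation undefined")
    y = scores["raw_score"].to_numpy(float)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    out = scores.copy()
    out["age_residual_score"] = y - X @ beta
    return out


def score_pipeline(
    metabolites: FeatureMatrix,
    coeffs: ScoreCoefficients,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """log -> per-cohort z-scale -> project -> residualise on age."""
    transformed = zscale_per_cohort(log_transform(metabolites), samples["cohort"])
    scores = project_score(transformed, coeffs)
    return residualize_on_age(scores, samples["age"])
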