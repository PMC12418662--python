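"""Cytokine and proteomics panel preprocessing.

Cytokines arrive left-censored: an assay's lower detection limit (LOD)
truncates low concentrations, so the first question is whether cases and
controls *differ in detectability* (Fisher exact test per feature), and
features undetected in most samples are dropped rather than imputed.
Proteomics arrives with scattered missing values instead: heavily missing
features are dropped, gross outliers (beyond k SDs from the feature mean)
are masked, and the remainder is imputed with NIPALS — an iterative PCA that
tolerates missing cells — before the shared log + per-cohort z transform.

Fixed stage order (matching the study's preprocessing):

* cytokines:   detectability -> filter_undetected -> mask_outliers -> prep_transform
* proteomics:  filter_missing -> mask_outliers -> nipals_impute -> prep_transform

All exclusion thresholds use strictly-greater semantics: a feature sitting
exactly on the boundary is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ContrastDesign, FeatureMatrix
from .score import log_transform, zscale_per_cohort
from .association import bh_fdr


@dataclass
class DetectabilityResult:
    """Per-feature 2x2 detected/undetected counts by case status, with the
    two-sided Fisher exact p and its BH-adjusted value."""

    counts: pd.DataFrame  # columns: case_detected, case_undetected, control_detected, control_undetected
    fisher_p: pd.Series
    fdr_adjusted_p: pd.Series

    def table(self, feature: str) -> np.ndarray:
        row = self.counts.loc[feature]
        return np.array(
            [
                [row["case_detected"], row["case_undetected"]],
                [row["control_detected"], row["control_undetected"]],
            ],
            dtype=int,
        )


@dataclass
class PrepReport:
    """Audit trail of a preprocessing run."""

    excluded_features: list = field(default_factory=list)  # (name, {reason: frac})
    outlier_cells: list = field(default_factory=list)  # (sample, feature)
    imputed_cells: list = field(default_factory=list)  # (sample, feature)
    warnings: list = field(default_factory=list)

    def merge(self, other: "PrepReport") -> "PrepReport":
        return PrepReport(
            self.excluded_features + other.excluded_features,
            self.outlier_cells + other.outlier_cells,
            self.imputed_cells + other.imputed_cells,
            self.warnings + other.warnings,
        )

    def to_dict(self) -> dict:
        return {
            "excluded_features": [
                {"feature": str(f), "reasons": r} for f, r in self.excluded_features
            ],
            "outlier_cells": [[str(s), str(f)] for s, f in self.outlier_cells],
            "imputed_cells": [[str(s), str(f)] for s, f in self.imputed_cells],
            "warnings": list(self.warnings),
        }


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table (point-probability
    rule: sum the hypergeometric probabilities of all tables with the same
    margins that are no more likely than the observed one)."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def detectability_table(
    matrix: FeatureMatrix, design: ContrastDesign
) -> DetectabilityResult:
    """Count detected/undetected (below-LOD) cells per feature and group, and
    test each feature's 2x2 table with the Fisher exact test (BH-adjusted
    across features)."""
    status = design.status(matrix.sample_ids)  # raises on uncovered sample
    case_ids = status.index[status == 1]
    ctrl_ids = status.index[status == 0]
    undet = matrix.below_lod
    rows = {}
    for feat in matrix.feature_names:
        cu = int(undet.loc[case_ids, feat].sum())
        uu = int(undet.loc[ctrl_ids, feat].sum())
        rows[feat] = {
            "case_detected": len(case_ids) - cu,
            "case_undetected": cu,
            "control_detected": len(ctrl_ids) - uu,
            "control_undetected": uu,
        }
    counts = pd.DataFrame.from_dict(rows, orient="index").loc[matrix.feature_names]
    pvals = pd.Series(
        {
            feat: fisher_exact_2x2(
                [
                    [row["case_detected"], row["case_undetected"]],
                    [row["control_detected"], row["control_undetected"]],
                ]
            )
            for feat, row in counts.iterrows()
        }
    ).loc[matrix.feature_names]
    return DetectabilityResult(counts, pvals, pd.Series(bh_fdr(pvals.to_numpy()), index=pvals.index))


def filter_undetected(
    matrix: FeatureMatrix, max_undetected_frac: float = 0.65
) -> tuple[FeatureMatrix, PrepReport]:
    """Drop features undetected (below LOD) in strictly more than
    ``max_undetected_frac`` of samples; exactly at the boundary is kept."""
    if not 0 <= max_undetected_frac <= 1:
        raise ValueError("max_undetected_frac must lie in [0, 1]")
    frac = matrix.below_lod.mean(axis=0)
    drop = frac.index[frac > max_undetected_frac]
    report = PrepReport(
        excluded_features=[
            (f, {"undetected_frac": float(frac[f])}) for f in drop
        ]
    )
    keep = [f for f in matrix.feature_names if f not in set(drop)]
    return matrix.select_features(keep), report


def filter_missing(
    matrix: FeatureMatrix,
    max_missing_frac: float = 0.05,
    max_missing_count: int | None = None,
) -> tuple[FeatureMatrix, PrepReport]:
    """Drop features with strictly more than ``max_missing_frac`` missing
    values (or, alternatively, more than ``max_missing_count`` absolute
    missing cells); boundary values are kept."""
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must lie in [0, 1]")
    miss = matrix.missing
    frac = miss.mean(axis=0)
    if max_missing_count is not None:
        drop = frac.index[miss.sum(axis=0) > max_missing_count]
    else:
        drop = frac.index[frac > max_missing_frac]
    report = PrepReport(
        excluded_features=[(f, {"missing_frac": float(frac[f])}) for f in drop]
    )
    keep = [f for f in matrix.feature_names if f not in set(drop)]
    return matrix.select_features(keep), report


def mask_outliers(
    matrix: FeatureMatrix, k_sd: float = 5.0
) -> tuple[FeatureMatrix, PrepReport]:
    """Mask values strictly more than ``k_sd`` sample SDs from their feature
    mean. Mean and SD are computed in a single pass over all observed values,
    outlier candidates included; features with fewer than 3 observations are
    skipped with a warning."""
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    out = matrix.copy()
    report = PrepReport()
    values = out.values
    for feat in out.feature_names:
        col = values[feat]
        obs = col.dropna()
        if len(obs) < 3:
            msg = f"feature {feat!r} has {len(obs)} observed values; outlier check skipped"
            warnings.warn(msg)
            report.warnings.append(msg)
            continue
        mu, sd = obs.mean(), obs.std(ddof=1)
        flag = (col - mu).abs() > k_sd * sd
        for sid in col.index[flag.fillna(False)]:
            report.outlier_cells.append((sid, feat))
        values[feat] = col.mask(flag)
    out.values = values
    return out, report


def nipals_impute(
    matrix: FeatureMatrix,
    n_components: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[FeatureMatrix, PrepReport]:
    """Impute missing cells from a NIPALS principal-component model.

    NIPALS fits one component at a time by alternating score/loading
    regressions whose sums run over observed cells only, so no prior
    imputation is needed. Missing entries are replaced by the
    rank-``n_components`` reconstruction plus feature means; observed
    entries are never altered. Convergence is declared when each
    component's eigenvalue changes by less than ``tol`` relatively;
    exhaustion of ``max_iter`` is a warning, not an error.
    """
    unobs = matrix.values.isna()
    if not unobs.to_numpy().any():
        return matrix.copy(), PrepReport()
    all_missing = unobs.all(axis=0)
    if all_missing.any():
        raise ValueError(
            f"feature {all_missing.idxmax()!r} has no observed values; cannot impute"
        )
    n, p = matrix.shape
    if n_components >= min(n, p):
        raise ValueError(
            f"n_components={n_components} must be below min(n_samples, n_features)"
            f"={min(n, p)}"
        )

    X = matrix.values.to_numpy(float)
    obs = ~np.isnan(X)
    report = PrepReport()

    def _power_iterate(R, t):
        """NIPALS score/loading alternation on the observed cells of residual
        R, started from score vector t; returns (t, p, converged)."""
        eig_old = 0.0
        p_vec = np.zeros(R.shape[1])
        for _ in range(max_iter):
            # loadings: per-feature regression of observed cells on t
            num = (R * t[:, None] * obs).sum(axis=0)
            den = ((t**2)[:, None] * obs).sum(axis=0)
            p_vec = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
            norm = np.linalg.norm(p_vec)
            if norm == 0:
                return t * 0.0, p_vec, True
            p_vec /= norm
            # scores: per-sample regression of observed cells on p
            num_t = (R * p_vec[None, :] * obs).sum(axis=1)
            den_t = ((p_vec**2)[None, :] * obs).sum(axis=1)
            t = np.divide(num_t, den_t, out=np.zeros_like(num_t), where=den_t > 0)
            eig = float(t @ t)
            if eig > 0 and abs(eig - eig_old) / eig < tol:
                return t, p_vec, True
            eig_old = eig
        return t, p_vec, False

    # sequential NIPALS pass
    col_means = np.nanmean(X, axis=0)
    R = np.where(obs, X - col_means, 0.0)
    scores_, loadings_ = [], []
    for h in range(n_components):
        t0 = R[:, int(np.argmax((R**2).sum(axis=0)))].copy()
        t, p_vec, converged = _power_iterate(R, t0)
        if not converged:
            msg = f"NIPALS component {h + 1} did not converge in {max_iter} iterations"
            warnings.warn(msg)
            report.warnings.append(msg)
        scores_.append(t)
        loadings_.append(p_vec)
        R = np.where(obs, R - np.outer(t, p_vec), 0.0)

    # refinement sweeps: greedy deflation is not the joint observed-cell
    # least-squares optimum, so re-fit each component against the residual of
    # the others (and re-estimate means from the completed matrix) until the
    # imputed cells stabilise
    recon = sum(np.outer(t, p) for t, p in zip(scores_, loadings_))
    holes = ~obs
    filled = np.where(obs, X, col_means + recon)
    for _ in range(max_iter):
        col_means = filled.mean(axis=0)
        for h in range(n_components):
            partial = recon - np.outer(scores_[h], loadings_[h])
            R_h = np.where(obs, X - col_means - partial, 0.0)
            t0 = scores_[h] if np.any(scores_[h]) else R_h[:, int(np.argmax((R_h**2).sum(axis=0)))]
            t, p_vec, _ = _power_iterate(R_h, t0.copy())
            scores_[h], loadings_[h] = t, p_vec
            recon = partial + np.outer(t, p_vec)
        new_holes = (col_means + recon)[holes]
        delta = np.max(np.abs(new_holes - filled[holes]) / (1.0 + np.abs(new_holes)))
        filled[holes] = new_holes
        if delta < tol:
            break
    else:
        msg = "NIPALS refinement did not stabilise the imputed cells"
        warnings.warn(msg)
        report.warnings.append(msg)

    out = matrix.copy()
    out.values = pd.DataFrame(
        filled, index=matrix.sample_ids, columns=matrix.feature_names
    )
    # after imputation no cell is censored any more: below-LOD holes were
    # filled like ordinary missing cells
    out.below_lod = pd.DataFrame(
        False, index=matrix.sample_ids, columns=matrix.feature_names
    )
    holes = unobs.to_numpy()
    for i, j in zip(*np.nonzero(holes)):
        report.imputed_cells.append((matrix.sample_ids[i], matrix.feature_names[j]))
    return out, report


def prep_transform(matrix: FeatureMatrix, cohort_labels: pd.Series) -> FeatureMatrix:
    """Final log + per-cohort z-scale (same contracts as the score module)."""
    return zscale_per_cohort(log_transform(matrix), cohort_labels)


# ----------------------------------------------------------- stage pipelines
def prep_cytokines(
    matrix: FeatureMatrix,
    design: ContrastDesign,
    cohort_labels: pd.Series,
    max_undetected_frac: float = 0.65,
    k_sd: float = 5.0,
) -> tuple[FeatureMatrix, DetectabilityResult, PrepReport]:
    """detectability -> filter_undetected -> mask_outliers -> log+z."""
    detect = detectability_table(matrix, design)
    kept, rep1 = filter_undetected(matrix, max_undetected_frac)
    masked, rep2 = mask_outliers(kept, k_sd)
    return prep_transform(masked, cohort_labels), detect, rep1.merge(rep2)


def prep_proteomics(
    matrix: FeatureMatrix,
    cohort_labels: pd.Series,
    max_missing_frac: float = 0.05,
    k_sd: float = 5.0,
    n_components: int = 5,
) -> tuple[FeatureMatrix, PrepReport]:
    """filter_missing -> mask_outliers -> log -> nipals_impute -> per-cohort z.

    Outlier masking applies the k-SD rule on the raw intensity scale;
    imputation runs on the log scale, where the additive low-rank PCA model
    suits log-normal intensities and imputed values stay in the domain of
    the transform."""
    kept, rep1 = filter_missing(matrix, max_missing_frac)
    masked, rep2 = mask_outliers(kept, k_sd)
    imputed, rep3 = nipals_impute(log_transform(masked), n_components=n_components)
    return (
        zscale_per_cohort(imputed, cohort_labels),
        rep1.merge(rep2).merge(rep3),
    )
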