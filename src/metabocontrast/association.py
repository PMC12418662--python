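"""Covariate-adjusted association scans and random-effects meta-analysis.

The scan fits, per feature, an ordinary least-squares model of the
(preprocessed, z-scaled) feature on case/control status plus a named set of
covariates; the reported estimate is the status coefficient — the adjusted
case-minus-control difference in feature SD units. P-values come from the t
distribution with the residual degrees of freedom, and Benjamini-Hochberg
FDR is applied within each covariate-set family.

Cross-cohort pooling uses the random-effects model
``y_i ~ N(mu, v_i + tau^2)`` with the between-study variance ``tau^2``
estimated by restricted maximum likelihood (REML), the estimator the
meta-analysis literature recommends as nearly unbiased; the pooled estimate
is the inverse-variance weighted mean at the REML ``tau^2``.

Model classes follow the Model -> fit() -> Results convention; the
module-level functions are thin wrappers kept for pipeline use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .containers import ContrastDesign, FeatureMatrix

RESULT_COLUMNS = [
    "feature", "estimate", "se", "ci_low", "ci_high", "p", "fdr", "n",
    "covariate_set",
]

DEFAULT_COVARIATE_SETS: dict[str, list[str]] = {
    "age_sex": ["age", "sex"],
    "age_sex_bmi": ["age", "sex", "bmi"],
    "full": [
        "age", "sex", "bmi", "lymphocyte_pct", "monocyte_pct",
        "lipid_med", "bp_med",
    ],
}


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving,
    capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals <= 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


# ------------------------------------------------------------------ OLS core
def _ols_inference(y: np.ndarray, X: np.ndarray, names: Sequence[str]):
    """Least-squares fit with t-based inference; raises on rank deficiency,
    naming the collinear columns."""
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        collinear = []
        for j in range(k):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                collinear.append(names[j])
        raise ValueError(f"design matrix rank-deficient; collinear columns: {collinear}")
    if n <= k:
        raise ValueError(f"n={n} too small for {k} parameters")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = np.where(
        se > 0,
        2 * stats.t.sf(np.abs(np.where(se > 0, tstat, 0.0)), df),
        np.finfo(float).tiny,  # zero residual variance: below machine floor
    )
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    tcrit = stats.t.ppf(0.975, df)
    return beta, se, p, df, tcrit


@dataclass
class AssocResult:
    """One feature's association with case status."""

    feature: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    covariate_set: str = "none"
    fdr: float = np.nan

    def to_series(self) -> pd.Series:
        return pd.Series({c: getattr(self, c) for c in RESULT_COLUMNS})


def fit_linear_assoc(
    y: pd.Series,
    status: pd.Series,
    covars: pd.DataFrame | None = None,
    feature: str = "feature",
    covariate_set: str = "none",
) -> AssocResult:
    """OLS of ``y`` on [intercept, status, covariates], complete cases only.

    The estimate is the status coefficient; with no covariates it equals the
    case-minus-control mean difference. Two-sided p from the t distribution
    with ``n - k`` residual degrees of freedom; 95% CI as estimate ± t_0.975·se.
    """
    y = pd.Series(y).astype(float)
    status = pd.Series(status).reindex(y.index).astype(float)
    frames = [status.rename("status")]
    names = ["intercept", "status"]
    if covars is not None and len(covars.columns):
        covars = covars.reindex(y.index).astype(float)
        frames.append(covars)
        names += list(covars.columns)
    design = pd.concat(frames, axis=1)
    keep = y.notna() & design.notna().all(axis=1)
    yv = y[keep].to_numpy()
    X = np.column_stack([np.ones(keep.sum()), design[keep].to_numpy()])
    beta, se, p, df, tcrit = _ols_inference(yv, X, names)
    est, s = float(beta[1]), float(se[1])
    return AssocResult(
        feature=feature,
        estimate=est,
        se=s,
        ci_low=est - tcrit * s,
        ci_high=est + tcrit * s,
        p=float(p[1]),
        n=int(keep.sum()),
        covariate_set=covariate_set,
    )


def _batch_assoc(
    values: pd.DataFrame,
    status: pd.Series,
    cov: pd.DataFrame | None,
    set_name: str,
) -> list["AssocResult"]:
    """All-features OLS against one shared complete design matrix;
    numerically identical to the per-feature path."""
    n = len(values)
    parts = [np.ones(n), status.to_numpy(float)]
    names = ["intercept", "status"]
    if cov is not None and len(cov.columns):
        parts += [cov[c].to_numpy(float) for c in cov.columns]
        names += list(cov.columns)
    X = np.column_stack(parts)
    k = X.shape[1]
    if np.linalg.matrix_rank(X) < k:
        # fall back for the detailed collinearity diagnostics
        return [
            fit_linear_assoc(values[f], status, cov, feature=f, covariate_set=set_name)
            for f in values.columns
        ]
    Y = values.to_numpy(float)
    XtX = X.T @ X
    B = np.linalg.solve(XtX, X.T @ Y)
    resid = Y - X @ B
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    v_status = np.linalg.inv(XtX)[1, 1]
    se = np.sqrt(np.maximum(sigma2 * v_status, 0.0))
    est = B[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / se, 0.0)
    p = np.where(
        se > 0,
        np.clip(2 * stats.t.sf(np.abs(t), df), np.finfo(float).tiny, 1.0),
        np.finfo(float).tiny,
    )
    tcrit = stats.t.ppf(0.975, df)
    return [
        AssocResult(
            feature=feat,
            estimate=float(est[j]),
            se=float(se[j]),
            ci_low=float(est[j] - tcrit * se[j]),
            ci_high=float(est[j] + tcrit * se[j]),
            p=float(p[j]),
            n=n,
            covariate_set=set_name,
        )
        for j, feat in enumerate(values.columns)
    ]


class AssociationScan:
    """Per-feature case/control association model over a feature matrix.

    Parameters
    ----------
    matrix
        Preprocessed feature matrix (already log + z-scaled).
    design
        Population-mode contrast design; only samples it covers are used.
    covars
        Sample table providing the covariate columns.
    covariate_sets
        Mapping of family name -> covariate column list. BH-FDR is applied
        within each family separately.
    """

    def __init__(
        self,
        matrix: FeatureMatrix,
        design: ContrastDesign,
        covars: pd.DataFrame,
        covariate_sets: Mapping[str, Sequence[str]] | None = None,
    ):
        if design.mode != "population":
            raise ValueError("AssociationScan expects a population design")
        if matrix.shape[1] == 0:
            raise ValueError("empty feature set")
        self.matrix = matrix
        self.design = design
        self.covars = covars
        self.covariate_sets = dict(covariate_sets or {"age_sex": ["age", "sex"]})

    def fit(self) -> "AssociationScanResults":
        ids = [sid for sid in self.matrix.sample_ids if sid in set(self.design.all_ids)]
        status = self.design.status(ids)
        values = self.matrix.values.loc[ids]
        rows = []
        for set_name, columns in self.covariate_sets.items():
            cov = self.covars.loc[ids, list(columns)] if columns else None
            complete = not values.isna().to_numpy().any() and (
                cov is None or not cov.isna().to_numpy().any()
            )
            if complete:
                # shared design matrix: solve all features in one pass
                results = _batch_assoc(values, status, cov, set_name)
            else:
                results = [
                    fit_linear_assoc(
                        values[feat], status, cov,
                        feature=feat, covariate_set=set_name,
                    )
                    for feat in self.matrix.feature_names
                ]
            fdr = bh_fdr([r.p for r in results])
            for r, q in zip(results, fdr):
                r.fdr = float(q)
                rows.append(r.to_series())
        frame = pd.DataFrame(rows)[RESULT_COLUMNS].reset_index(drop=True)
        return AssociationScanResults(frame)


@dataclass
class AssociationScanResults:
    """Tidy results table with one row per feature per covariate set."""

    frame: pd.DataFrame

    def significant(self, alpha: float = 0.05, covariate_set: str | None = None) -> pd.DataFrame:
        sub = self.frame if covariate_set is None else self.frame[
            self.frame["covariate_set"] == covariate_set
        ]
        return sub[sub["fdr"] <= alpha]

    def summary(self, alpha: float = 0.05) -> str:
        lines = ["Association scan (OLS on case status)"]
        for set_name, sub in self.frame.groupby("covariate_set"):
            sig = sub[sub["fdr"] <= alpha]
            lines.append(
                f"  covariates={set_name}: {len(sub)} features, "
                f"{len(sig)} with FDR<={alpha} "
                f"({int((sig['estimate'] > 0).sum())} positive, "
                f"{int((sig['estimate'] < 0).sum())} negative)"
            )
        top = self.frame.sort_values("p").head(8)
        lines.append(top.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_association_scan(
    matrix: FeatureMatrix,
    design: ContrastDesign,
    covars: pd.DataFrame,
    covariate_sets: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    return AssociationScan(matrix, design, covars, covariate_sets).fit().frame


# ------------------------------------------------------------- meta-analysis
def _reml_nll(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = float(w @ y / w.sum())
    return 0.5 * (
        np.log(v + tau2).sum() + np.log(w.sum()) + float(w @ (y - mu) ** 2)
    )


class RandomEffectsMeta:
    """Random-effects pooling of per-study estimates with known sampling
    variances; ``tau^2`` by REML (bounded scalar optimisation of the
    restricted likelihood, floored at zero)."""

    def __init__(self, estimates: Sequence[float], ses: Sequence[float]):
        self.y = np.asarray(estimates, dtype=float)
        self.se = np.asarray(ses, dtype=float)
        if self.y.size == 0:
            raise ValueError("need at least one study")
        if np.any(self.se <= 0) or not np.all(np.isfinite(self.se)):
            raise ValueError("standard errors must be positive and finite")

    def fit(self, tol: float = 1e-10) -> "MetaResults":
        y, v = self.y, self.se**2
        if y.size == 1:
            tau2 = 0.0
        else:
            upper = max(10.0 * float(np.var(y)), 10.0 * float(v.max()), 1.0)
            res = optimize.minimize_scalar(
                _reml_nll, args=(y, v), bounds=(0.0, upper), method="bounded",
                options={"xatol": tol},
            )
            tau2 = float(res.x)
            if _reml_nll(0.0, y, v) <= _reml_nll(tau2, y, v):
                tau2 = 0.0
        w = 1.0 / (v + tau2)
        pooled = float(w @ y / w.sum())
        pooled_se = float(w.sum() ** -0.5)
        z = pooled / pooled_se
        return MetaResults(
            pooled_estimate=pooled,
            pooled_se=pooled_se,
            tau2=tau2,
            p=float(2 * stats.norm.sf(abs(z))),
            ci_low=pooled - 1.959963984540054 * pooled_se,
            ci_high=pooled + 1.959963984540054 * pooled_se,
            per_study=list(zip(self.y.tolist(), self.se.tolist())),
        )


@dataclass
class MetaResults:
    pooled_estimate: float
    pooled_se: float
    tau2: float
    p: float
    ci_low: float
    ci_high: float
    per_study: list = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"REML random-effects meta-analysis over {len(self.per_study)} studies\n"
            f"  pooled = {self.pooled_estimate:.4f} (SE {self.pooled_se:.4f}, "
            f"95% CI [{self.ci_low:.4f}, {self.ci_high:.4f}]), "
            f"tau^2 = {self.tau2:.5f}, p = {self.p:.3g}"
        )


def reml_meta(estimates: Sequence[float], ses: Sequence[float]) -> MetaResults:
    return RandomEffectsMeta(estimates, ses).fit()


def meta_analyze_scans(
    per_study_frames: Mapping[str, pd.DataFrame], covariate_set: str | None = None
) -> pd.DataFrame:
    """Pool per-feature estimates across study-level scan frames; BH-FDR over
    pooled p-values within each covariate set."""
    frames = {
        name: (f if covariate_set is None else f[f["covariate_set"] == covariate_set])
        for name, f in per_study_frames.items()
    }
    shared = None
    for f in frames.values():
        feats = set(f["feature"])
        shared = feats if shared is None else shared & feats
    rows = []
    sets = sorted({cs for f in frames.values() for cs in f["covariate_set"].unique()})
    for cset in sets:
        sub_rows = []
        for feat in sorted(shared):
            est, ses = [], []
            for f in frames.values():
                row = f[(f["feature"] == feat) & (f["covariate_set"] == cset)]
                if len(row):
                    est.append(float(row["estimate"].iloc[0]))
                    ses.append(float(row["se"].iloc[0]))
            if not est:
                continue
            r = RandomEffectsMeta(est, ses).fit()
            sub_rows.append(
                {
                    "feature": feat,
                    "estimate": r.pooled_estimate,
                    "se": r.pooled_se,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p": r.p,
                    "tau2": r.tau2,
                    "n_studies": len(est),
                    "covariate_set": cset,
                }
            )
        fdr = bh_fdr([r["p"] for r in sub_rows])
        for r, q in zip(sub_rows, fdr):
            r["fdr"] = float(q)
            rows.append(r)
    return pd.DataFrame(rows)


# -------------------------------------------------------- concordance & corr
def beta_beta_concordance(
    res_a: pd.DataFrame, res_b: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """Compare two scans: among features significant (FDR <= alpha) in both,
    count sign-agreeing positives/negatives and disagreements; returns the
    paired per-feature estimates for plotting."""
    a = res_a.set_index("feature")
    b = res_b.set_index("feature")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("scans share no feature names")
    merged = pd.DataFrame(
        {
            "estimate_a": a.loc[shared, "estimate"],
            "fdr_a": a.loc[shared, "fdr"],
            "estimate_b": b.loc[shared, "estimate"],
            "fdr_b": b.loc[shared, "fdr"],
        }
    )
    both = merged[(merged["fdr_a"] <= alpha) & (merged["fdr_b"] <= alpha)]
    agree = both[np.sign(both["estimate_a"]) == np.sign(both["estimate_b"])]
    return {
        "n_shared": int(len(shared)),
        "n_significant_both": int(len(both)),
        "n_agree_positive": int((agree["estimate_a"] > 0).sum()),
        "n_agree_negative": int((agree["estimate_a"] < 0).sum()),
        "n_disagree": int(len(both) - len(agree)),
        "pairs": merged,
    }


def correlate_features(
    mat_a: FeatureMatrix, mat_b: FeatureMatrix, min_pairs: int = 3
) -> pd.DataFrame:
    """Pearson correlations between every feature of ``mat_a`` and every
    feature of ``mat_b`` over pairwise-complete samples; pairs with fewer
    than ``min_pairs`` complete observations are skipped with a warning."""
    import warnings as _warnings

    shared = mat_a.sample_ids.intersection(mat_b.sample_ids)
    if len(shared) == 0:
        raise ValueError("matrices share no samples")
    A = mat_a.values.loc[shared]
    B = mat_b.values.loc[shared]
    rows = []
    for fa in A.columns:
        xa = A[fa]
        for fb in B.columns:
            xb = B[fb]
            ok = xa.notna() & xb.notna()
            n = int(ok.sum())
            if n < min_pairs:
                _warnings.warn(
                    f"<{min_pairs} complete pairs for ({fa!r}, {fb!r}); skipped"
                )
                continue
            r, p = stats.pearsonr(xa[ok], xb[ok])
            rows.append({"feature_a": fa, "feature_b": fb, "r": float(r),
                         "p": float(p), "n": n})
    return pd.DataFrame(rows)
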