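"""Twin-pair correlations, Falconer heritability, and the within-pair
linear mixed model for discordant-MZ association scans.

Twin resemblance is measured by the double-entry Pearson correlation: each
pair contributes both member orderings, which makes the estimate symmetric
to arbitrary within-pair labelling (an intraclass-style estimator). The 95%
CI uses the Fisher z transform with the number of *pairs* as effective n —
double entry must not be allowed to halve the standard error.

Falconer's formula ``h^2 = 2(rMZ - rDZ)`` converts the MZ/DZ correlation gap
into a narrow-sense heritability estimate under the classical assumptions
(additive genetics, DZ genetic correlation 0.5, equal shared environments).
Sampling error can push it outside [0, 1]; that draws a warning, not an
error.

The within-pair scan fits a random-intercept model
``y = X b + u_pair + e`` by REML, profiling the restricted likelihood over
the variance ratio ``u/e``. Because case status varies within every pair
while pair identity absorbs everything shared (genome, household, age, sex),
the status coefficient is free of between-pair confounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .association import RESULT_COLUMNS, AssocResult, bh_fdr
from .containers import ContrastDesign, FeatureMatrix


@dataclass
class HeritabilityResult:
    r_mz: float
    r_dz: float
    ci_mz: tuple[float, float]
    ci_dz: tuple[float, float]
    h2: float
    n_mz_pairs: int
    n_dz_pairs: int

    def summary(self) -> str:
        return (
            f"Twin correlations: rMZ = {self.r_mz:.3f} "
            f"(95% CI {self.ci_mz[0]:.3f}-{self.ci_mz[1]:.3f}, "
            f"{self.n_mz_pairs} pairs), rDZ = {self.r_dz:.3f} "
            f"(95% CI {self.ci_dz[0]:.3f}-{self.ci_dz[1]:.3f}, "
            f"{self.n_dz_pairs} pairs)\n"
            f"Falconer h^2 = 2(rMZ - rDZ) = {self.h2:.3f}"
        )

    def to_dict(self) -> dict:
        return {
            "r_mz": self.r_mz, "r_dz": self.r_dz,
            "ci_mz": list(self.ci_mz), "ci_dz": list(self.ci_dz),
            "h2": self.h2, "n_mz_pairs": self.n_mz_pairs,
            "n_dz_pairs": self.n_dz_pairs,
        }


def _complete_pairs(values: pd.Series, covars: pd.DataFrame, zygosity: str):
    sub = covars[covars["zygosity"] == zygosity]
    pairs = []
    for fam, members in sub.groupby("family_id").groups.items():
        members = sorted(members, key=str)
        if len(members) != 2:
            continue
        v = values.reindex(members)
        if v.notna().all():
            pairs.append((float(v.iloc[0]), float(v.iloc[1])))
    return pairs


def _double_entry_r(pairs: list[tuple[float, float]]) -> float:
    x = np.array([p[0] for p in pairs] + [p[1] for p in pairs])
    y = np.array([p[1] for p in pairs] + [p[0] for p in pairs])
    return float(np.corrcoef(x, y)[0, 1])


def _fisher_ci(r: float, n_pairs: int) -> tuple[float, float]:
    if n_pairs <= 3:
        return (-1.0, 1.0)
    z = np.arctanh(r)
    half = 1.959963984540054 / np.sqrt(n_pairs - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def twin_correlations(
    values: pd.Series, covars: pd.DataFrame
) -> HeritabilityResult:
    """Double-entry Pearson correlations per zygosity with Fisher-z CIs and
    the Falconer heritability of the measured trait."""
    result = {}
    counts = {}
    for zyg in ("MZ", "DZ"):
        pairs = _complete_pairs(pd.Series(values), covars, zyg)
        if len(pairs) < 3:
            raise ValueError(
                f"need at least 3 complete {zyg} pairs, found {len(pairs)}"
            )
        result[zyg] = _double_entry_r(pairs)
        counts[zyg] = len(pairs)
    h2 = falconer_h2(result["MZ"], result["DZ"])
    return HeritabilityResult(
        r_mz=result["MZ"],
        r_dz=result["DZ"],
        ci_mz=_fisher_ci(result["MZ"], counts["MZ"]),
        ci_dz=_fisher_ci(result["DZ"], counts["DZ"]),
        h2=h2,
        n_mz_pairs=counts["MZ"],
        n_dz_pairs=counts["DZ"],
    )


def falconer_h2(r_mz: float, r_dz: float) -> float:
    """Falconer's moment estimator ``2 * (r_mz - r_dz)``; values outside
    [0, 1] (possible by sampling error) trigger a warning."""
    if not (np.isfinite(r_mz) and np.isfinite(r_dz)):
        raise ValueError("twin correlations must be finite")
    h2 = 2.0 * (r_mz - r_dz)
    if not 0.0 <= h2 <= 1.0:
        warnings.warn(f"Falconer h^2 = {h2:.3f} falls outside [0, 1]")
    return h2


# --------------------------------------------------------- within-pair model
def _pair_whiten(y, X, pair_index):
    """Rotate each complete pair into (sum, difference)/sqrt(2) coordinates.
    In those coordinates the random-intercept covariance is diagonal:
    Var(sum-row) = sigma_e^2 (1 + 2 lambda), Var(diff-row) = sigma_e^2."""
    ys, Xs, yd, Xd = [], [], [], []
    for _, idx in pair_index.items():
        i, j = idx
        ys.append((y[i] + y[j]) / np.sqrt(2.0))
        Xs.append((X[i] + X[j]) / np.sqrt(2.0))
        yd.append((y[i] - y[j]) / np.sqrt(2.0))
        Xd.append((X[i] - X[j]) / np.sqrt(2.0))
    return np.array(ys), np.array(Xs), np.array(yd), np.array(Xd)


def _reml_criterion(lam, ys, Xs, yd, Xd):
    """-2 x restricted log-likelihood (up to constants) profiled over beta
    and sigma_e^2, as a function of the variance ratio lambda."""
    n = len(ys) + len(yd)
    w_s = 1.0 / (1.0 + 2.0 * lam)
    X = np.vstack([Xs * np.sqrt(w_s), Xd])
    y = np.concatenate([ys * np.sqrt(w_s), yd])
    k = X.shape[1]
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    if rss <= 0:
        raise ValueError("degenerate fit: zero residual variance")
    sigma2 = rss / (n - k)
    sign, logdet = np.linalg.slogdet(X.T @ X)
    return (
        (n - k) * np.log(sigma2)
        + len(ys) * np.log(1.0 + 2.0 * lam)
        + logdet
    ), beta, sigma2, X


class WithinPairModel:
    """Random-intercept (pair) linear mixed model for complete twin pairs.

    Parameters
    ----------
    y, status, pair_ids
        Per-sample outcome, 0/1 case indicator, and pair identifier; every
        pair must appear exactly twice with both members observed.
    covars
        Optional covariate columns (pair-constant covariates are absorbed by
        the pair rotation and contribute only through the between stratum).
    """

    def __init__(
        self,
        y: pd.Series,
        status: pd.Series,
        pair_ids: pd.Series,
        covars: pd.DataFrame | None = None,
    ):
        y = pd.Series(y).astype(float)
        status = pd.Series(status).reindex(y.index).astype(float)
        pair_ids = pd.Series(pair_ids).reindex(y.index)
        frames = [status.rename("status")]
        names = ["intercept", "status"]
        if covars is not None and len(covars.columns):
            covars = covars.reindex(y.index).astype(float)
            frames.append(covars)
            names += list(covars.columns)
        design = pd.concat(frames, axis=1)
        keep = y.notna() & design.notna().all(axis=1) & pair_ids.notna()
        counts = pair_ids[keep].value_counts()
        incomplete = sorted(str(p) for p in counts.index[counts != 2]) + sorted(
            str(p) for p in pair_ids[~keep].dropna().unique()
            if p not in set(counts.index[counts == 2])
        )
        if incomplete:
            raise ValueError(f"incomplete pairs: {sorted(set(incomplete))}")
        self.names = names
        self.y = y[keep].to_numpy()
        self.X = np.column_stack([np.ones(int(keep.sum())), design[keep].to_numpy()])
        positions = {sid: i for i, sid in enumerate(y.index[keep])}
        self.pair_index = {
            pid: [positions[sid] for sid in idx]
            for pid, idx in pair_ids[keep].groupby(pair_ids[keep]).groups.items()
        }

    def fit(self, tol: float = 1e-10) -> "WithinPairResults":
        ys, Xs, yd, Xd = _pair_whiten(self.y, self.X, self.pair_index)
        n_pairs = len(ys)

        def crit(lam):
            return _reml_criterion(lam, ys, Xs, yd, Xd)[0]

        res = optimize.minimize_scalar(
            crit, bounds=(0.0, 1e6), method="bounded", options={"xatol": tol}
        )
        lam = float(res.x)
        if crit(0.0) <= crit(lam):
            lam = 0.0
        _, beta, sigma2_e, Xw = _reml_criterion(lam, ys, Xs, yd, Xd)
        cov = sigma2_e * np.linalg.inv(Xw.T @ Xw)
        se = np.sqrt(np.diag(cov))
        # conservative df: pairs minus the between-pair design dimension
        between_rank = int(np.linalg.matrix_rank(Xs))
        df = max(n_pairs - between_rank - 1, 1)
        tcrit = stats.t.ppf(0.975, df)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, 0.0)
        p = np.clip(2 * stats.t.sf(np.abs(t), df), np.finfo(float).tiny, 1.0)
        return WithinPairResults(
            params=pd.Series(beta, index=self.names),
            bse=pd.Series(se, index=self.names),
            pvalues=pd.Series(p, index=self.names),
            sigma2_pair=lam * sigma2_e,
            sigma2_resid=sigma2_e,
            df=df,
            n_pairs=n_pairs,
            tcrit=float(tcrit),
        )


@dataclass
class WithinPairResults:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    sigma2_pair: float
    sigma2_resid: float
    df: int
    n_pairs: int
    tcrit: float

    def conf_int(self) -> pd.DataFrame:
        lo = self.params - self.tcrit * self.bse
        hi = self.params + self.tcrit * self.bse
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    def summary(self) -> str:
        tab = pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "p": self.pvalues}
        ).join(self.conf_int())
        return (
            f"Within-pair mixed model ({self.n_pairs} pairs, REML)\n"
            f"  sigma^2(pair) = {self.sigma2_pair:.5f}, "
            f"sigma^2(resid) = {self.sigma2_resid:.5f}, df = {self.df}\n"
            + tab.to_string(float_format=lambda v: f"{v:.4g}")
        )


def fit_within_pair_lmm(
    y: pd.Series,
    status: pd.Series,
    pair_ids: pd.Series,
    covars: pd.DataFrame | None = None,
    feature: str = "feature",
    covariate_set: str = "none",
) -> AssocResult:
    """Status coefficient from the pair random-intercept REML fit, packaged
    like a population scan result."""
    results = WithinPairModel(y, status, pair_ids, covars).fit()
    est = float(results.params["status"])
    se = float(results.bse["status"])
    ci = results.conf_int().loc["status"]
    return AssocResult(
        feature=feature,
        estimate=est,
        se=se,
        ci_low=float(ci["ci_low"]),
        ci_high=float(ci["ci_high"]),
        p=float(results.pvalues["status"]),
        n=2 * results.n_pairs,
        covariate_set=covariate_set,
    )


# ----------------------------------------------------- attenuation analysis
def population_score_slopes(
    matrix: FeatureMatrix,
    scores: pd.Series,
    covars: pd.DataFrame | None = None,
    covariates: Sequence[str] = ("age", "sex"),
) -> pd.Series:
    """Per-feature OLS slope of the feature on the continuous score
    (covariate-adjusted), over all samples — the population association per
    score unit. Because selection on the regressor does not bias OLS slopes,
    this estimand is comparable across selected and unselected samples."""
    scores = pd.Series(scores).reindex(matrix.sample_ids).astype(float)
    cols = []
    if covars is not None:
        cols = [c for c in covariates if c in covars.columns]
        cov = covars.loc[matrix.sample_ids, cols].astype(float)
    out = {}
    for feat in matrix.feature_names:
        y = matrix.values[feat]
        keep = y.notna() & scores.notna()
        X = [np.ones(int(keep.sum())), scores[keep].to_numpy()]
        if cols:
            keep &= cov.notna().all(axis=1)
            X = [np.ones(int(keep.sum())), scores[keep].to_numpy()] + [
                cov.loc[keep, c].to_numpy() for c in cols
            ]
        beta, *_ = np.linalg.lstsq(np.column_stack(X), y[keep].to_numpy(), rcond=None)
        out[feat] = float(beta[1])
    return pd.Series(out, name="score_slope")


def within_pair_score_slopes(
    matrix: FeatureMatrix, scores: pd.Series, design: ContrastDesign
) -> pd.Series:
    """Per-feature within-pair slope: regression through the origin of the
    co-twin difference in the feature on the co-twin difference in the
    score, over the design's pairs. Shared genetics and environment cancel
    in the differences, so this is the genetically unconfounded analogue of
    :func:`population_score_slopes`."""
    if design.mode != "twin":
        raise ValueError("within-pair slopes require a twin design")
    scores = pd.Series(scores).astype(float)
    out = {}
    for feat in matrix.feature_names:
        y = matrix.values[feat]
        dx, dy = [], []
        for pid, (hi, lo, _) in design.pair_map.items():
            if pd.notna(y.get(hi)) and pd.notna(y.get(lo)):
                dx.append(scores[hi] - scores[lo])
                dy.append(y[hi] - y[lo])
        dx, dy = np.asarray(dx), np.asarray(dy)
        if len(dx) < 3 or np.all(dx == 0):
            out[feat] = np.nan
            continue
        out[feat] = float(dx @ dy / (dx @ dx))
    return pd.Series(out, name="within_pair_score_slope")


def run_within_pair_scan(
    matrix: FeatureMatrix,
    design: ContrastDesign,
    covars: pd.DataFrame,
    covariate_sets: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-feature within-pair scans over a twin contrast design, BH-FDR
    within each covariate-set family."""
    if design.mode != "twin":
        raise ValueError("within-pair scan expects a twin design")
    ids = [sid for sid in matrix.sample_ids if sid in set(design.all_ids)]
    status = design.status(ids)
    pair_ids = design.pair_id_of().reindex(ids)
    covariate_sets = dict(covariate_sets or {"none": []})
    rows = []
    for set_name, columns in covariate_sets.items():
        cov = covars.loc[ids, list(columns)] if columns else None
        results = []
        for feat in matrix.feature_names:
            y = matrix.values.loc[ids, feat]
            # censoring/missingness: use only pairs with both members observed
            ok = y.notna()
            if cov is not None:
                ok &= cov.notna().all(axis=1)
            pair_ok = pair_ids[ok].value_counts()
            complete = set(pair_ok.index[pair_ok == 2])
            use = [sid for sid in ids if ok[sid] and pair_ids[sid] in complete]
            if len(use) < 6:
                warnings.warn(
                    f"feature {feat!r}: only {len(use) // 2} complete pairs; skipped"
                )
                continue
            results.append(
                fit_within_pair_lmm(
                    y.loc[use], status.loc[use], pair_ids.loc[use],
                    None if cov is None else cov.loc[use],
                    feature=feat, covariate_set=set_name,
                )
            )
        fdr = bh_fdr([r.p for r in results])
        for r, q in zip(results, fdr):
            r.fdr = float(q)
            rows.append(r.to_series())
    return pd.DataFrame(rows)[RESULT_COLUMNS].reset_index(drop=True)
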