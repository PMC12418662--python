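"""Reproduction experiments: the package's headline quantities recomputed
from scratch on synthetic cohorts.

Each function simulates under the default study-scale conditions (two
population cohorts, a 726 MZ / 450 DZ twin registry, trait heritability 0.4),
runs the corresponding analysis through the public API, and returns the
measured quantity. They power both the acceptance script and the
integration-level tests, so the numbers reported anywhere are always the
product of a fresh end-to-end computation.
"""

from __future__ import annotations

import hashlib
import json
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .association import run_association_scan
from .containers import FeatureMatrix
from .prep import nipals_impute
from .score import default_coefficients, log_transform, score_pipeline
from .select import select_discordant_pairs, select_extremes_design
from .simulate import (
    ProteinSpec,
    SimConfig,
    simulate_population,
    simulate_twin_registry,
)
from .twins import (
    falconer_h2,
    population_score_slopes,
    twin_correlations,
    within_pair_score_slopes,
)


def _sub_seed(base_seed: int, tag: str, k: int = 0) -> int:
    payload = f"{base_seed}:{tag}:{k}".encode()
    return int.from_bytes(hashlib.sha256(payload).digest()[:4], "big") % (2**31)


def falconer_worked_example() -> float:
    """The printed twin correlations of the mortality score (rMZ = 0.432,
    rDZ = 0.230) through the Falconer estimator."""
    return falconer_h2(0.432, 0.230)


def heritability_recovery(
    base_seed: int = 0,
    n_seeds: int = 200,
    h2_true: float = 0.4,
    n_mz_pairs: int = 726,
    n_dz_pairs: int = 450,
) -> dict:
    """Simulate the twin registry repeatedly, project the score, and estimate
    h^2 = 2(rMZ - rDZ) from the age-residualised score each time."""
    coeffs = default_coefficients()
    estimates, r_mz = [], []
    for k in range(n_seeds):
        cfg = SimConfig(
            n_mz_pairs=n_mz_pairs,
            n_dz_pairs=n_dz_pairs,
            h2_true=h2_true,
            c2_true=0.0,
            seed=_sub_seed(base_seed, "h2", k),
        )
        samples, mats, _ = simulate_twin_registry(cfg)
        scores = score_pipeline(mats["metabolomics"], coeffs, samples)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = twin_correlations(scores["age_residual_score"], samples)
        estimates.append(res.h2)
        r_mz.append(res.r_mz)
    return {
        "mean_h2": float(np.mean(estimates)),
        "sd_h2": float(np.std(estimates, ddof=1)),
        "single_draw_h2": float(estimates[0]),
        "mean_r_mz": float(np.mean(r_mz)),
        "n_seeds": n_seeds,
        "h2_true": h2_true,
    }


def _null_protein_config(seed: int, n_proteins: int) -> SimConfig:
    panel = [
        ProteinSpec(name=f"NULL{i + 1:03d}", protein_class="null")
        for i in range(n_proteins)
    ]
    return SimConfig(
        n_per_cohort={"LLS": 400},
        n_mz_pairs=2,
        n_dz_pairs=2,
        protein_panel=panel,
        seed=seed,
    )


def fdr_null_control(
    base_seed: int = 0,
    n_reps: int = 200,
    n_proteins: int = 250,
    n_cases: int = 50,
    alpha: float = 0.05,
) -> dict:
    """Realized false-discovery proportion of the BH-controlled scan when
    every protein is null: simulate, select 50+50 score extremes, scan the
    100-sample panel, and count discoveries (all false by construction)."""
    coeffs = default_coefficients()
    fdp = []
    for k in range(n_reps):
        cfg = _null_protein_config(_sub_seed(base_seed, "fdr", k), n_proteins)
        samples, mats, _ = simulate_population(cfg, "LLS")
        scores = score_pipeline(mats["metabolomics"], coeffs, samples)
        design = select_extremes_design(scores, samples, n_cases=n_cases,
                                        age_tolerance=5.0)
        scan = run_association_scan(
            log_transform(mats["proteomics"]).select_samples(design.all_ids),
            design,
            samples,
            {"age_sex": ["age", "sex"]},
        )
        n_disc = int((scan["fdr"] <= alpha).sum())
        fdp.append(1.0 if n_disc > 0 else 0.0)  # every discovery is false
    return {
        "mean_fdp": float(np.mean(fdp)),
        "n_reps": n_reps,
        "n_proteins": n_proteins,
        "alpha": alpha,
    }


def nipals_rank1_benchmark(base_seed: int = 0, n: int = 80, p: int = 15,
                           mask_rate: float = 0.05) -> dict:
    """Recovery of a rank-1 matrix with 5% of cells masked, plus the
    observed-cells-untouched guarantee."""
    rng = np.random.default_rng(_sub_seed(base_seed, "nipals"))
    X = np.outer(rng.normal(size=n), rng.normal(size=p))
    holes = rng.random(X.shape) < mask_rate
    Xm = np.where(holes, np.nan, X)
    frame = pd.DataFrame(
        Xm,
        index=[f"s{i}" for i in range(n)],
        columns=[f"f{j}" for j in range(p)],
    )
    out, _ = nipals_impute(FeatureMatrix(frame), n_components=1, tol=1e-12,
                           max_iter=2000)
    filled = out.values.to_numpy()
    rel = np.abs(filled[holes] - X[holes]) / np.abs(X[holes])
    observed_unchanged = bool((filled[~holes] == X[~holes]).all())
    return {
        "max_rel_error": float(rel.max()),
        "observed_unchanged": observed_unchanged,
        "n_masked": int(holes.sum()),
    }


def attenuation_experiment(base_seed: int = 0, n_reps: int = 200,
                           n_pairs: int = 25) -> dict:
    """Population vs within-MZ-pair protein-score slopes by protein class.

    Pleiotropic proteins load on the genetic component of the trait, which
    inflates the population slope but cancels within genetically identical
    pairs; environmental proteins should show no systematic gap. Slopes are
    per score unit (log-intensity per score), the scale on which selection
    does not bias the estimate.
    """
    coeffs = default_coefficients()
    classes = ("environmental", "pleiotropic")
    pop = {c: [] for c in classes}
    twin = {c: [] for c in classes}
    for k in range(n_reps):
        cfg = SimConfig(seed=_sub_seed(base_seed, "atten", k))
        samples, mats, truth = simulate_population(cfg, "LLS")
        scores = score_pipeline(mats["metabolomics"], coeffs, samples)
        pop_slopes = population_score_slopes(
            log_transform(mats["proteomics"]), scores["age_residual_score"],
            samples,
        )
        tsamples, tmats, ttruth = simulate_twin_registry(cfg)
        tscores = score_pipeline(tmats["metabolomics"], coeffs, tsamples)
        design = select_discordant_pairs(tscores, tsamples, n_pairs=n_pairs)
        twin_slopes = within_pair_score_slopes(
            log_transform(tmats["proteomics"]), tscores["age_residual_score"],
            design,
        )
        for cls in classes:
            feats = truth.protein_classes.index[truth.protein_classes == cls]
            pop[cls].append(float(pop_slopes[feats].abs().mean()))
            twin[cls].append(float(twin_slopes[feats].abs().mean()))
    out = {"n_reps": n_reps}
    for cls in classes:
        p_arr, t_arr = np.array(pop[cls]), np.array(twin[cls])
        tstat, pval = stats.ttest_rel(p_arr, t_arr)
        out[cls] = {
            "mean_abs_population_slope": float(p_arr.mean()),
            "mean_abs_within_pair_slope": float(t_arr.mean()),
            "attenuation_ratio": float(t_arr.mean() / p_arr.mean()),
            "paired_t": float(tstat),
            "paired_p": float(pval),
        }
    return out


def determinism_check(seed: int = 0) -> dict:
    """Run the full pipeline twice at the same seed in fresh directories and
    compare summary and MANIFEST byte for byte."""
    from .pipeline import PipelineConfig, run_pipeline

    config = PipelineConfig(seed=seed)
    payloads = []
    with tempfile.TemporaryDirectory() as tmp:
        for tag in ("a", "b"):
            out = Path(tmp) / tag
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                summary = run_pipeline(config, out)
            payloads.append(
                (
                    (out / "summary.json").read_bytes(),
                    (out / "MANIFEST.json").read_bytes(),
                    summary,
                )
            )
    identical = (
        payloads[0][0] == payloads[1][0] and payloads[0][1] == payloads[1][1]
    )
    return {"identical": bool(identical), "summary": payloads[0][2]}
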