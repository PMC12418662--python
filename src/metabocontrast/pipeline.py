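"""End-to-end pipeline: simulate -> score -> select -> prep -> associate ->
meta -> twin analyses, with a summary report and a hashed output MANIFEST.

Every stage draws randomness from a named substream of the single config
seed, so re-running the pipeline with the same config reproduces every
output byte for byte, and individual stages can be re-run in isolation
without disturbing the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .association import (
    DEFAULT_COVARIATE_SETS,
    beta_beta_concordance,
    correlate_features,
    meta_analyze_scans,
    run_association_scan,
)
from .containers import ContrastDesign, FeatureMatrix, write_sample_table
from .prep import prep_cytokines, prep_proteomics
from .score import default_coefficients, score_pipeline
from .select import select_discordant_pairs, select_extremes_design
from .simulate import SimConfig, apply_detection_limit, inject_missingness, stage_rng
from .twins import run_within_pair_scan, twin_correlations

log = logging.getLogger("metabocontrast")


class SelectionConfig(BaseModel):
    n_cases: int = Field(default=25, gt=0)
    age_tolerance: float = Field(default=2.5, ge=0)
    n_pairs: int = Field(default=25, gt=0)


class PrepConfig(BaseModel):
    max_undetected_frac: float = Field(default=0.65, ge=0, le=1)
    k_sd: float = Field(default=5.0, gt=0)
    max_missing_frac: float = Field(default=0.05, ge=0, le=1)
    nipals_components: int = Field(default=5, gt=0)


class PipelineConfig(BaseModel):
    simulate: SimConfig = Field(default_factory=SimConfig)
    selection: SelectionConfig = Field(default_factory=SelectionConfig)
    prep: PrepConfig = Field(default_factory=PrepConfig)
    covariate_sets: dict[str, list[str]] = Field(
        default_factory=lambda: {
            "age_sex": list(DEFAULT_COVARIATE_SETS["age_sex"]),
            "full": list(DEFAULT_COVARIATE_SETS["full"]),
        }
    )
    alpha: float = Field(default=0.05, gt=0, lt=1)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(payload)


class PipelineSummary(BaseModel):
    """Schema of the summary report; validated before writing."""

    seed: int
    version: str
    thresholds: dict
    cohorts: dict[str, int]
    cytokines_excluded: list[str]
    proteins_excluded: list[str]
    n_cytokines_analyzed: int
    n_proteins_analyzed: int
    significant_counts: dict[str, dict[str, int]]
    heritability: dict
    concordance: dict[str, int]
    score_contrasts: dict[str, float]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _merge_population_designs(designs: dict[str, ContrastDesign]) -> ContrastDesign:
    cases, controls, matching = [], [], {}
    for d in designs.values():
        cases += list(d.case_ids)
        controls += list(d.control_ids)
        matching.update(d.matching_map)
    return ContrastDesign("population", cases, controls, matching_map=matching)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis on freshly simulated data and write all
    stage outputs plus ``summary.json`` and ``MANIFEST.json`` under
    ``out_dir``. Returns the summary as a dict. On a stage failure the
    outputs written so far are retained and the MANIFEST notes the aborted
    stage."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "init"

    def save_frame(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)

    def save_matrix(matrix: FeatureMatrix, name: str) -> None:
        path = out / name
        matrix.write(path)
        written.append(path)
        mask = path.with_suffix(".mask.tsv")
        if mask.exists():
            written.append(mask)

    try:
        sim = config.simulate.model_copy(update={"seed": config.seed})

        stage = "simulate"
        log.info("[simulate] generating cohorts %s + twin registry",
                 sorted(sim.n_per_cohort))
        cohorts: dict[str, dict] = {}
        from .simulate import simulate_population, simulate_twin_registry

        for label in sorted(sim.n_per_cohort):
            samples, mats, truth = simulate_population(sim, label)
            cohorts[label] = {"samples": samples, "mats": mats, "truth": truth}
        ntr_samples, ntr_mats, ntr_truth = simulate_twin_registry(sim)
        cohorts["NTR"] = {"samples": ntr_samples, "mats": ntr_mats, "truth": ntr_truth}

        lods = None
        for label, c in cohorts.items():
            meta = c["mats"]["cytokines"].feature_meta
            lods = meta["lod"]
            c["mats"]["cytokines"] = apply_detection_limit(c["mats"]["cytokines"], lods)
            rates = c["mats"]["proteomics"].feature_meta["missing_rate"]
            c["mats"]["proteomics"] = inject_missingness(
                c["mats"]["proteomics"], rates,
                seed=int(stage_rng(config.seed, "missingness", label).integers(2**31)),
            )

        stage = "score"
        coeffs = default_coefficients()
        for label, c in cohorts.items():
            c["scores"] = score_pipeline(c["mats"]["metabolomics"], coeffs, c["samples"])
            log.info("[score] %s: %d samples scored", label, len(c["scores"]))

        stage = "select"
        pop_labels = sorted(sim.n_per_cohort)
        designs = {
            label: select_extremes_design(
                cohorts[label]["scores"], cohorts[label]["samples"],
                n_cases=config.selection.n_cases,
                age_tolerance=config.selection.age_tolerance,
            )
            for label in pop_labels
        }
        twin_design = select_discordant_pairs(
            cohorts["NTR"]["scores"], cohorts["NTR"]["samples"],
            n_pairs=config.selection.n_pairs,
        )
        combined = _merge_population_designs(designs)
        for label, d in designs.items():
            d.write(out / f"design_{label}.tsv")
            written += [out / f"design_{label}.tsv", out / f"design_{label}.json"]
        twin_design.write(out / "design_NTR.tsv")
        written += [out / "design_NTR.tsv", out / "design_NTR.json"]

        score_contrasts = {}
        for label, d in {**designs, "NTR": twin_design}.items():
            s = cohorts[label]["scores"]["age_residual_score"]
            score_contrasts[label] = float(
                s.loc[d.case_ids].mean() - s.loc[d.control_ids].mean()
            )

        stage = "prep"
        pop_ids = combined.all_ids
        pop_samples = pd.concat([cohorts[l]["samples"] for l in pop_labels]).loc[pop_ids]
        cyto_all = FeatureMatrix(
            pd.concat([cohorts[l]["mats"]["cytokines"].values for l in pop_labels]),
            pd.concat([cohorts[l]["mats"]["cytokines"].below_lod for l in pop_labels]),
        ).select_samples(pop_ids)
        prot_all = FeatureMatrix(
            pd.concat([cohorts[l]["mats"]["proteomics"].values for l in pop_labels]),
            pd.concat([cohorts[l]["mats"]["proteomics"].below_lod for l in pop_labels]),
        ).select_samples(pop_ids)

        cyto_prepped, detect, cyto_report = prep_cytokines(
            cyto_all, combined, pop_samples["cohort"],
            max_undetected_frac=config.prep.max_undetected_frac,
            k_sd=config.prep.k_sd,
        )
        prot_prepped, prot_report = prep_proteomics(
            prot_all, pop_samples["cohort"],
            max_missing_frac=config.prep.max_missing_frac,
            k_sd=config.prep.k_sd,
            n_components=config.prep.nipals_components,
        )
        log.info("[prep] cytokines %d->%d, proteins %d->%d features",
                 cyto_all.shape[1], cyto_prepped.shape[1],
                 prot_all.shape[1], prot_prepped.shape[1])
        save_matrix(cyto_prepped, "cytokines_prepped.tsv")
        save_matrix(prot_prepped, "proteomics_prepped.tsv")
        detect_frame = detect.counts.copy()
        detect_frame["fisher_p"] = detect.fisher_p
        detect_frame["fdr"] = detect.fdr_adjusted_p
        detect_frame.index.name = "feature"
        save_frame(detect_frame.reset_index(), "cytokine_detectability.tsv")
        (out / "prep_report.json").write_text(
            json.dumps(
                {"cytokines": cyto_report.to_dict(), "proteomics": prot_report.to_dict()},
                indent=1, sort_keys=True,
            )
        )
        written.append(out / "prep_report.json")

        stage = "associate"
        scans = {}
        for platform, prepped in (("cytokines", cyto_prepped), ("proteomics", prot_prepped)):
            scans[platform] = run_association_scan(
                prepped, combined, pop_samples, config.covariate_sets
            )
            save_frame(scans[platform], f"assoc_{platform}_combined.tsv")
        per_cohort = {}
        for label in pop_labels:
            sub_prot = prot_prepped.select_samples(
                [sid for sid in designs[label].all_ids]
            )
            per_cohort[label] = run_association_scan(
                sub_prot, designs[label], pop_samples, {"age_sex": config.covariate_sets.get("age_sex", ["age", "sex"])}
            )
            save_frame(per_cohort[label], f"assoc_proteomics_{label}.tsv")

        stage = "meta"
        meta_frame = meta_analyze_scans(per_cohort)
        save_frame(meta_frame, "meta_proteomics.tsv")

        stage = "twin"
        herit = twin_correlations(
            cohorts["NTR"]["scores"]["age_residual_score"], cohorts["NTR"]["samples"]
        )
        log.info("[twin] %s", herit.summary().replace("\n", " | "))
        (out / "heritability.json").write_text(
            json.dumps(herit.to_dict(), indent=1, sort_keys=True)
        )
        written.append(out / "heritability.json")

        twin_ids = twin_design.all_ids
        twin_samples = cohorts["NTR"]["samples"]
        twin_cyto, _, _ = prep_cytokines(
            cohorts["NTR"]["mats"]["cytokines"].select_samples(twin_ids),
            twin_design, twin_samples.loc[twin_ids, "cohort"],
            max_undetected_frac=config.prep.max_undetected_frac,
            k_sd=config.prep.k_sd,
        )
        twin_prot, _ = prep_proteomics(
            cohorts["NTR"]["mats"]["proteomics"].select_samples(twin_ids),
            twin_samples.loc[twin_ids, "cohort"],
            max_missing_frac=config.prep.max_missing_frac,
            k_sd=config.prep.k_sd,
            n_components=config.prep.nipals_components,
        )
        twin_scans = {}
        for platform, prepped in (("cytokines", twin_cyto), ("proteomics", twin_prot)):
            twin_scans[platform] = run_within_pair_scan(
                prepped, twin_design, twin_samples,
                {"age_sex": config.covariate_sets.get("age_sex", ["age", "sex"])},
            )
            save_frame(twin_scans[platform], f"assoc_twin_{platform}.tsv")

        stage = "concordance"
        pop_age_sex = scans["proteomics"][scans["proteomics"]["covariate_set"] == "age_sex"]
        twin_age_sex = twin_scans["proteomics"][
            twin_scans["proteomics"]["covariate_set"] == "age_sex"
        ]
        conc = beta_beta_concordance(pop_age_sex, twin_age_sex, alpha=config.alpha)
        conc_pairs = conc.pop("pairs")
        conc_pairs.index.name = "feature"
        save_frame(conc_pairs.reset_index(), "beta_beta_pairs.tsv")

        stage = "correlate"
        met_prepped = score_metabolite_panel(cohorts, pop_labels, pop_ids, pop_samples)
        corr = correlate_features(cyto_prepped, met_prepped)
        save_frame(corr, "cytokine_metabolite_correlations.tsv")

        stage = "summary"
        sig_counts = {}
        for platform, frame in scans.items():
            sig_counts[platform] = {
                cset: int((sub["fdr"] <= config.alpha).sum())
                for cset, sub in frame.groupby("covariate_set")
            }
        for platform, frame in twin_scans.items():
            sig_counts[f"twin_{platform}"] = {
                cset: int((sub["fdr"] <= config.alpha).sum())
                for cset, sub in frame.groupby("covariate_set")
            }
        summary = PipelineSummary(
            seed=config.seed,
            version=__version__,
            thresholds={
                "alpha": config.alpha,
                "max_undetected_frac": config.prep.max_undetected_frac,
                "k_sd": config.prep.k_sd,
                "max_missing_frac": config.prep.max_missing_frac,
                "nipals_components": config.prep.nipals_components,
                "age_tolerance": config.selection.age_tolerance,
            },
            cohorts={label: len(c["samples"]) for label, c in cohorts.items()},
            cytokines_excluded=sorted(
                str(f) for f, _ in cyto_report.excluded_features
            ),
            proteins_excluded=sorted(str(f) for f, _ in prot_report.excluded_features),
            n_cytokines_analyzed=int(cyto_prepped.shape[1]),
            n_proteins_analyzed=int(prot_prepped.shape[1]),
            significant_counts=sig_counts,
            heritability=herit.to_dict(),
            concordance={k: v for k, v in conc.items()},
            score_contrasts=score_contrasts,
        )
        (out / "summary.json").write_text(
            json.dumps(summary.model_dump(), indent=1, sort_keys=True)
        )
        written.append(out / "summary.json")
    except Exception as exc:
        manifest = {
            "complete": False,
            "aborted_stage": stage,
            "error": f"{type(exc).__name__}: {exc}",
            "files": {p.name: _sha256(p) for p in written if p.exists()},
        }
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "complete": True,
        "files": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return summary.model_dump()


def score_metabolite_panel(cohorts, pop_labels, pop_ids, pop_samples) -> FeatureMatrix:
    """log + per-cohort z-scaled metabolite panel over the analyzed samples,
    for the cytokine/metabolite correlation map."""
    from .prep import prep_transform

    met_all = FeatureMatrix(
        pd.concat([cohorts[l]["mats"]["metabolomics"].values for l in pop_labels])
    ).select_samples(pop_ids)
    return prep_transform(met_all, pop_samples["cohort"])
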