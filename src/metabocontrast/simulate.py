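"""Synthetic multi-cohort, multi-omics data generator.

Emulates the statistical structure the downstream analysis assumes: a latent
health trait per participant, 14 metabolomic analytes loading on that trait
(from which the mortality-style score is projected), a cytokine panel with
lower detection limits, and a plasma-protein panel with planted associations
of three classes:

``null``
    no relation to the trait — false-positive control;
``environmental``
    protein tracks the trait through non-genetic paths only, so population
    and within-MZ-pair associations agree in expectation;
``pleiotropic``
    protein additionally loads on the *genetic* component of the trait, so
    the population association is inflated relative to the within-MZ-pair
    association — the mechanism behind attenuated apolipoprotein signals in
    discordant-twin designs.

The twin registry follows the classical ACE decomposition
``L = a*A + c*C + e*E`` with ``a^2 = h2_true``, ``c^2 = c2_true``; the
additive-genetic component ``A`` correlates 1 within MZ pairs and 0.5 within
DZ pairs. The latent trait has unit variance before age/sex effects, so
``h2_true`` is directly the squared genetic path and the Falconer estimator
``2(rMZ - rDZ)`` recovers it in expectation.

Detection-limit censoring and missingness are *not* baked into the generated
matrices; they are applied by :func:`apply_detection_limit` and
:func:`inject_missingness` so each mechanism is separately testable.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .containers import FeatureMatrix


def stage_rng(seed: int, *context) -> np.random.Generator:
    """Deterministic substream: one generator per (seed, context) pair."""
    keys = [zlib.crc32(str(c).encode()) for c in context]
    return np.random.default_rng(np.random.SeedSequence((int(seed), *keys)))


# --------------------------------------------------------------- panel specs
class CytokineSpec(BaseModel):
    name: str
    log_mean: float
    log_sd: float = Field(gt=0)
    lod: float = Field(gt=0, description="lower detection limit, raw scale")
    trait_effect: float = 0.0


class ProteinSpec(BaseModel):
    name: str
    protein_class: Literal["null", "environmental", "pleiotropic"]
    effect: float = 0.0
    genetic_effect: float = 0.0
    noise_sd: float = Field(default=0.5, gt=0)
    log_mean: float = 2.0
    missing_rate: float = Field(default=0.01, ge=0, le=1)

    @model_validator(mode="after")
    def _class_consistency(self):
        if self.protein_class == "null" and (self.effect != 0 or self.genetic_effect != 0):
            raise ValueError(f"null protein {self.name} must have zero effects")
        if self.protein_class == "environmental" and self.genetic_effect != 0:
            raise ValueError(
                f"environmental protein {self.name} must have zero genetic effect"
            )
        return self


def default_cytokine_panel() -> list[CytokineSpec]:
    """Fifteen-cytokine panel: nine well-detected analytes plus six whose
    detection limit sits one SD above their median, leaving them undetected
    in most samples (the study situation that forces their exclusion)."""
    detected = [
        ("MIP1a", 2.0, 0.2), ("IL6", 0.8, 0.5), ("RANTES", 7.5, 0.2),
        ("MIG", 4.5, 0.5), ("MCP1", 4.0, 0.2), ("Eotaxin", 3.5, 0.15),
        ("Psel", 9.0, 0.2), ("GDF15", 6.0, 0.5), ("BDNF", 7.0, 0.1),
    ]
    mostly_undetected = [
        ("IL2", 0.5, 0.1), ("TRAIL", 1.5, 0.1), ("GRO1a", 2.5, 0.1),
        ("IFNg", 1.0, 0.1), ("IL1b", 0.0, 0.1), ("PAI1", 5.0, 0.1),
    ]
    panel = []
    for name, mu, te in detected:
        panel.append(
            CytokineSpec(name=name, log_mean=mu, log_sd=0.6,
                         lod=float(np.exp(mu - 1.5 * 0.6)), trait_effect=te)
        )
    for name, mu, te in mostly_undetected:
        panel.append(
            CytokineSpec(name=name, log_mean=mu, log_sd=0.6,
                         lod=float(np.exp(mu + 1.0 * 0.6)), trait_effect=te)
        )
    return panel


def default_protein_panel() -> list[ProteinSpec]:
    """Sixty-six proteins: 20 null, 20 environmental, 20 pleiotropic, plus six
    high-missingness null proteins that the missingness filter should drop."""
    panel: list[ProteinSpec] = []
    for i in range(20):
        panel.append(ProteinSpec(name=f"NUL{i + 1:02d}", protein_class="null"))
    for i in range(20):
        sign = 1 if i % 2 == 0 else -1
        panel.append(
            ProteinSpec(
                name=f"ENV{i + 1:02d}", protein_class="environmental",
                effect=sign * (0.3 + 0.015 * i),
            )
        )
    for i in range(20):
        sign = 1 if i % 2 == 0 else -1
        panel.append(
            ProteinSpec(
                name=f"PLE{i + 1:02d}", protein_class="pleiotropic",
                effect=sign * (0.3 + 0.015 * i), genetic_effect=sign * 0.35,
            )
        )
    for i in range(6):
        panel.append(
            ProteinSpec(name=f"HIMISS{i + 1:02d}", protein_class="null",
                        missing_rate=0.30)
        )
    return panel


DEFAULT_METABOLITE_NAMES = [
    "XXL_VLDL_L", "S_HDL_L", "VLDL_D", "PUFA_by_FA", "Histidine", "Leucine",
    "Valine", "Albumin", "Glucose", "Lactate", "Isoleucine", "Phenylalanine",
    "Acetoacetate", "GlycA",
]
# signs follow the direction each analyte moves with poorer health in the
# mortality-score literature; magnitudes are synthetic
DEFAULT_METABOLITE_LOADINGS = [
    1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, -1.0, -1.0, -1.0, -1.0, -1.0, -1.0
]


class SimConfig(BaseModel):
    """All knobs of the generator. Defaults are the study-scale conditions:
    two population cohorts (middle-aged and older), a twin registry with
    726 MZ and 450 DZ pairs, trait heritability 0.4."""

    n_per_cohort: dict[str, int] = Field(
        default_factory=lambda: {"LLS": 2300, "RS": 2900}
    )
    age_ranges: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {"LLS": (45, 70), "RS": (60, 88), "NTR": (25, 48)}
    )
    n_mz_pairs: int = Field(default=726, ge=2)
    n_dz_pairs: int = Field(default=450, ge=2)
    h2_true: float = Field(default=0.4, ge=0, le=1)
    c2_true: float = Field(default=0.0, ge=0, le=1)
    n_metabolites: int = 14
    metabolite_names: list[str] = Field(
        default_factory=lambda: list(DEFAULT_METABOLITE_NAMES)
    )
    metabolite_loadings: list[float] = Field(
        default_factory=lambda: list(DEFAULT_METABOLITE_LOADINGS)
    )
    metabolite_log_sd: float = Field(default=0.05, gt=0)
    metabolite_log_mean: float = 1.0
    cytokine_panel: list[CytokineSpec] = Field(default_factory=default_cytokine_panel)
    protein_panel: list[ProteinSpec] = Field(default_factory=default_protein_panel)
    sex_fraction: float = Field(default=0.5, ge=0, le=1)
    trait_age_effect: float = 0.25  # trait SD per decade of age
    trait_sex_effect: float = 0.10
    covariate_effects: dict[str, float] = Field(
        default_factory=lambda: {
            "lymphocyte_pct": -3.0,  # percentage points per trait SD
            "monocyte_pct": 0.3,
            "bmi": 0.8,  # kg/m^2 per trait SD
        }
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.h2_true + self.c2_true > 1:
            raise ValueError("h2_true + c2_true must not exceed 1")
        if len(self.metabolite_loadings) != self.n_metabolites:
            raise ValueError(
                f"{len(self.metabolite_loadings)} loadings for "
                f"{self.n_metabolites} metabolites"
            )
        if len(self.metabolite_names) != self.n_metabolites:
            raise ValueError("metabolite_names length must equal n_metabolites")
        for label, n in self.n_per_cohort.items():
            if n <= 0:
                raise ValueError(f"non-positive size for cohort {label!r}")
        return self


@dataclass
class TruthRecord:
    """Ground truth kept aside for parameter-recovery tests: the latent trait,
    its additive-genetic component, and the planted per-feature effects."""

    latent_trait: pd.Series
    genetic_component: pd.Series
    protein_classes: pd.Series
    planted_effects: pd.Series

    def to_json(self, path: str | Path) -> None:
        payload = {
            "latent_trait": self.latent_trait.round(12).to_dict(),
            "genetic_component": self.genetic_component.round(12).to_dict(),
            "protein_classes": self.protein_classes.to_dict(),
            "planted_effects": self.planted_effects.round(12).to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ------------------------------------------------------------------- helpers
def _omics_layers(
    config: SimConfig,
    ids: pd.Index,
    trait: np.ndarray,
    genetic: np.ndarray,
    rng: np.random.Generator,
) -> tuple[FeatureMatrix, FeatureMatrix, FeatureMatrix]:
    n = len(ids)
    # metabolites: log-scale linear model, exponentiated so values stay > 0
    load = np.asarray(config.metabolite_loadings)
    met_log = (
        config.metabolite_log_mean
        + trait[:, None] * load[None, :]
        + rng.standard_normal((n, config.n_metabolites)) * config.metabolite_log_sd
    )
    metabolites = FeatureMatrix(
        pd.DataFrame(np.exp(met_log), index=ids, columns=config.metabolite_names),
        feature_meta=pd.DataFrame(
            {"platform": "nmr"}, index=config.metabolite_names
        ),
    )

    cyt_names = [c.name for c in config.cytokine_panel]
    cyt_log = np.empty((n, len(cyt_names)))
    for j, spec in enumerate(config.cytokine_panel):
        cyt_log[:, j] = (
            spec.log_mean
            + spec.trait_effect * trait
            + rng.standard_normal(n) * spec.log_sd
        )
    cytokines = FeatureMatrix(
        pd.DataFrame(np.exp(cyt_log), index=ids, columns=cyt_names),
        feature_meta=pd.DataFrame(
            {"platform": "luminex", "lod": [c.lod for c in config.cytokine_panel]},
            index=cyt_names,
        ),
    )

    prot_names = [p.name for p in config.protein_panel]
    prot_log = np.empty((n, len(prot_names)))
    for j, spec in enumerate(config.protein_panel):
        prot_log[:, j] = (
            spec.log_mean
            + spec.effect * trait
            + spec.genetic_effect * genetic
            + rng.standard_normal(n) * spec.noise_sd
        )
    proteins = FeatureMatrix(
        pd.DataFrame(np.exp(prot_log), index=ids, columns=prot_names),
        feature_meta=pd.DataFrame(
            {
                "platform": "ms_proteomics",
                "missing_rate": [p.missing_rate for p in config.protein_panel],
            },
            index=prot_names,
        ),
    )
    return metabolites, cytokines, proteins


def _covariates(
    config: SimConfig,
    ids: pd.Index,
    cohort: str,
    age: np.ndarray,
    sex: np.ndarray,
    trait: np.ndarray,
    rng: np.random.Generator,
    family_id: Sequence | None = None,
    zygosity: Sequence | None = None,
) -> pd.DataFrame:
    n = len(ids)
    eff = config.covariate_effects
    lymph = 31.0 + eff.get("lymphocyte_pct", 0.0) * trait + rng.standard_normal(n) * 5.0
    mono = 6.0 + eff.get("monocyte_pct", 0.0) * trait + rng.standard_normal(n) * 1.5
    bmi = 25.0 + eff.get("bmi", 0.0) * trait + rng.standard_normal(n) * 2.5
    p_lipid = 1.0 / (1.0 + np.exp(-(-2.5 + 0.03 * (age - 55) + 0.3 * trait)))
    p_bp = 1.0 / (1.0 + np.exp(-(-2.0 + 0.05 * (age - 55) + 0.3 * trait)))
    return pd.DataFrame(
        {
            "cohort": cohort,
            "family_id": family_id if family_id is not None else list(ids),
            "zygosity": zygosity if zygosity is not None else "",
            "age": age,
            "sex": sex.astype(int),  # 1 = female
            "bmi": bmi,
            "lymphocyte_pct": lymph,
            "monocyte_pct": mono,
            "lipid_med": (rng.random(n) < p_lipid).astype(int),
            "bp_med": (rng.random(n) < p_bp).astype(int),
        },
        index=ids,
    )


def _truth(
    config: SimConfig, ids: pd.Index, trait: np.ndarray, genetic: np.ndarray
) -> TruthRecord:
    classes = pd.Series(
        {p.name: p.protein_class for p in config.protein_panel}, name="protein_class"
    )
    planted = {}
    for name, loading in zip(config.metabolite_names, config.metabolite_loadings):
        planted[name] = loading
    for c in config.cytokine_panel:
        planted[c.name] = c.trait_effect
    for p in config.protein_panel:
        planted[p.name] = p.effect
    return TruthRecord(
        latent_trait=pd.Series(trait, index=ids, name="latent_trait"),
        genetic_component=pd.Series(genetic, index=ids, name="genetic_component"),
        protein_classes=classes,
        planted_effects=pd.Series(planted, name="planted_effect"),
    )


# ---------------------------------------------------------------- simulators
def simulate_population(
    config: SimConfig, cohort_label: str
) -> tuple[pd.DataFrame, dict[str, FeatureMatrix], TruthRecord]:
    """One population cohort of unrelated individuals.

    The latent trait is unit-variance ``a*A + sqrt(1-a^2)*R`` (A the additive
    genetic component, relevant for pleiotropic proteins) plus linear age and
    sex effects. Returns the sample table, a dict of the three omics layers
    (``metabolomics``, ``cytokines``, ``proteomics``) and the truth record.
    """
    if cohort_label not in config.n_per_cohort:
        raise ValueError(f"cohort {cohort_label!r} not named in config")
    n = config.n_per_cohort[cohort_label]
    rng = stage_rng(config.seed, "population", cohort_label)
    ids = pd.Index([f"{cohort_label}_{i + 1:05d}" for i in range(n)], name="sample_id")

    lo, hi = config.age_ranges.get(cohort_label, (40, 80))
    age = rng.uniform(lo, hi, n)
    sex = rng.random(n) < config.sex_fraction
    a = np.sqrt(config.h2_true)
    genetic = rng.standard_normal(n)
    core = a * genetic + np.sqrt(1 - a**2) * rng.standard_normal(n)
    trait = (
        core
        + config.trait_age_effect * (age - age.mean()) / 10.0
        + config.trait_sex_effect * (sex - 0.5)
    )

    layers = _omics_layers(config, ids, trait, genetic, rng)
    samples = _covariates(config, ids, cohort_label, age, sex, trait, rng)
    truth = _truth(config, ids, trait, genetic)
    matrices = dict(zip(("metabolomics", "cytokines", "proteomics"), layers))
    return samples, matrices, truth


def simulate_twin_registry(
    config: SimConfig, cohort_label: str = "NTR"
) -> tuple[pd.DataFrame, dict[str, FeatureMatrix], TruthRecord]:
    """Twin registry of complete MZ and DZ pairs under the ACE model.

    ``A`` is identical within MZ pairs and correlates 0.5 within DZ pairs;
    ``C`` is fully shared within a pair; ``E`` is individual. Co-twins share
    age and sex (same-sex pairs only).
    """
    rng = stage_rng(config.seed, "twins", cohort_label)
    n_mz, n_dz = config.n_mz_pairs, config.n_dz_pairs
    n_pairs = n_mz + n_dz
    zyg_pair = np.array(["MZ"] * n_mz + ["DZ"] * n_dz)

    a = np.sqrt(config.h2_true)
    c = np.sqrt(config.c2_true)
    e = np.sqrt(max(0.0, 1.0 - config.h2_true - config.c2_true))

    shared_a = rng.standard_normal(n_pairs)
    uniq_a = rng.standard_normal((n_pairs, 2))
    A = np.where(
        (zyg_pair == "MZ")[:, None],
        shared_a[:, None] * np.ones((1, 2)),
        np.sqrt(0.5) * shared_a[:, None] + np.sqrt(0.5) * uniq_a,
    )
    C = rng.standard_normal(n_pairs)[:, None] * np.ones((1, 2))
    E = rng.standard_normal((n_pairs, 2))
    core = a * A + c * C + e * E

    lo, hi = config.age_ranges.get(cohort_label, (25, 48))
    age_pair = rng.uniform(lo, hi, n_pairs)
    sex_pair = rng.random(n_pairs) < config.sex_fraction
    trait = (
        core
        + config.trait_age_effect * (age_pair[:, None] - age_pair.mean()) / 10.0
        + config.trait_sex_effect * (sex_pair[:, None] - 0.5)
    )

    fam = [f"{cohort_label}fam{i + 1:04d}" for i in range(n_pairs)]
    ids, fam_ids, zyg_ids, age_i, sex_i = [], [], [], [], []
    for i in range(n_pairs):
        for m, suffix in enumerate(("a", "b")):
            ids.append(f"{cohort_label}_{zyg_pair[i]}{i + 1:04d}_{suffix}")
            fam_ids.append(fam[i])
            zyg_ids.append(zyg_pair[i])
            age_i.append(age_pair[i])
            sex_i.append(sex_pair[i])
    index = pd.Index(ids, name="sample_id")
    trait_flat = trait.reshape(-1)
    genetic_flat = A.reshape(-1)

    layers = _omics_layers(config, index, trait_flat, genetic_flat, rng)
    samples = _covariates(
        config, index, cohort_label, np.array(age_i), np.array(sex_i, dtype=bool),
        trait_flat, rng, family_id=fam_ids, zygosity=zyg_ids,
    )
    truth = _truth(config, index, trait_flat, genetic_flat)
    matrices = dict(zip(("metabolomics", "cytokines", "proteomics"), layers))
    return samples, matrices, truth


# --------------------------------------------------------------- censor ops
def apply_detection_limit(
    matrix: FeatureMatrix, lods: Mapping[str, float] | pd.Series
) -> FeatureMatrix:
    """Mask values strictly below their feature's detection limit.

    The censored cells lose their value (NaN) and gain a below-LOD flag;
    values at or above the limit are untouched. The input is not modified.
    """
    lods = pd.Series(lods, dtype=float)
    extra = lods.index.difference(matrix.feature_names)
    missing_lods = matrix.feature_names.difference(lods.index)
    if len(extra) or len(missing_lods):
        bad = list(extra[:3]) + list(missing_lods[:3])
        raise ValueError(f"feature mismatch between matrix and lods: {bad}")
    if not np.all(np.isfinite(lods)):
        raise ValueError("detection limits must be finite")
    out = matrix.copy()
    lod_row = lods.reindex(matrix.feature_names)
    censored = out.values.lt(lod_row, axis=1) & out.values.notna()
    out.below_lod = out.below_lod | censored
    out.values = out.values.mask(censored)
    return out


def inject_missingness(
    matrix: FeatureMatrix, rate: float | Mapping[str, float] | pd.Series, seed: int
) -> FeatureMatrix:
    """Mask each observed cell missing-completely-at-random at its feature's
    rate; deterministic under ``seed``."""
    if np.isscalar(rate):
        rates = pd.Series(float(rate), index=matrix.feature_names)
    else:
        rates = pd.Series(rate, dtype=float).reindex(matrix.feature_names)
        if rates.isna().any():
            raise ValueError("missing rate for some features")
    if ((rates < 0) | (rates > 1)).any():
        raise ValueError("missingness rates must lie in [0, 1]")
    rng = stage_rng(seed, "inject_missingness")
    draw = rng.random(matrix.shape)
    hit = pd.DataFrame(
        draw < rates.to_numpy()[None, :],
        index=matrix.sample_ids,
        columns=matrix.feature_names,
    )
    out = matrix.copy()
    out.values = out.values.mask(hit & ~out.below_lod)
    return out
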