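"""Core data containers and their TSV/JSON serialisation.

The package moves three kinds of tabular objects between stages:

* a sample table — one row per participant, carrying cohort label, family id,
  zygosity and the clinical covariates used for matching and adjustment;
* a feature matrix — samples x features with two masks, one for missing
  entries and one for values reported below an assay's lower detection limit;
* a contrast design — the case/control membership produced by the selection
  stage, either matched population extremes or discordant twin pairs.

All on-disk formats are plain TSV (UTF-8, Unix newlines): missing values are
empty cells and below-LOD entries are flagged with a ``<LOD`` token in a
companion mask file, so censoring survives a round trip without inventing
substitute values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LOD_TOKEN = "<LOD"

#: columns a sample table may carry; only ``cohort`` is mandatory everywhere,
#: the rest are required by the stages that use them (matching, adjustment,
#: twin analyses).
SAMPLE_COLUMNS = (
    "cohort",
    "family_id",
    "zygosity",
    "age",
    "sex",
    "bmi",
    "lymphocyte_pct",
    "monocyte_pct",
    "lipid_med",
    "bp_med",
)


class FeatureMatrix:
    """Samples-by-features matrix with explicit missing and below-LOD masks.

    Parameters
    ----------
    values
        Float frame indexed by sample id with feature names as columns.
        ``NaN`` marks any unobserved cell (missing *or* censored).
    below_lod
        Boolean frame of the same shape; ``True`` where the assay reported
        the value under its lower detection limit. Such cells are also NaN
        in ``values``.
    feature_meta
        Optional per-feature metadata (e.g. ``platform``, ``lod``) indexed
        by feature name.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        below_lod: pd.DataFrame | None = None,
        feature_meta: pd.DataFrame | None = None,
    ):
        values = values.astype(float)
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise ValueError(f"duplicate feature name: {dup!r}")
        if below_lod is None:
            below_lod = pd.DataFrame(
                False, index=values.index, columns=values.columns
            )
        else:
            if not below_lod.index.equals(values.index) or not below_lod.columns.equals(
                values.columns
            ):
                below_lod = below_lod.reindex(
                    index=values.index, columns=values.columns, fill_value=False
                )
            below_lod = below_lod.astype(bool)
        if feature_meta is not None:
            unknown = feature_meta.index.difference(values.columns)
            if len(unknown):
                raise ValueError(
                    f"feature metadata references unknown feature: {unknown[0]!r}"
                )
            feature_meta = feature_meta.reindex(values.columns)
        self.values = values
        self.below_lod = below_lod
        self.feature_meta = feature_meta

    # ------------------------------------------------------------------ views
    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_names(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def observed(self) -> pd.DataFrame:
        """Boolean frame: cell holds an actual measurement."""
        return self.values.notna()

    @property
    def missing(self) -> pd.DataFrame:
        """Boolean frame: cell unobserved for reasons other than censoring."""
        return self.values.isna() & ~self.below_lod

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.copy(),
            self.below_lod.copy(),
            None if self.feature_meta is None else self.feature_meta.copy(),
        )

    def select_samples(self, ids: Sequence) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.loc[list(ids)],
            self.below_lod.loc[list(ids)],
            self.feature_meta,
        )

    def select_features(self, names: Sequence[str]) -> "FeatureMatrix":
        names = list(names)
        return FeatureMatrix(
            self.values[names],
            self.below_lod[names],
            None if self.feature_meta is None else self.feature_meta.loc[names],
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, p = self.shape
        return f"<FeatureMatrix {n} samples x {p} features>"

    # ------------------------------------------------------------------- I/O
    def write(self, path: str | Path) -> None:
        """Write values (and a companion ``.mask.tsv`` when any cell is
        censored) as TSV. Values keep 17 significant digits, which makes the
        write -> read round trip lossless for doubles."""
        path = Path(path)
        out = self.values.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", float_format="%.17g", na_rep="")
        if self.below_lod.to_numpy().any():
            mask = self.below_lod.replace({True: LOD_TOKEN, False: ""})
            mask.index.name = "sample_id"
            mask.to_csv(path.with_suffix(".mask.tsv"), sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        raw = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
        if raw.index.has_duplicates:
            dup = raw.index[raw.index.duplicated()][0]
            raise ValueError(f"duplicate sample id in {path.name}: {dup!r}")
        try:
            values = raw.apply(pd.to_numeric)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric cell in {path.name}: {exc}") from exc
        below = None
        mask_path = path.with_suffix(".mask.tsv")
        if mask_path.exists():
            mask = pd.read_csv(mask_path, sep="\t", index_col="sample_id", dtype=str)
            unknown = mask.columns.difference(values.columns)
            if len(unknown):
                raise ValueError(
                    f"mask file references unknown feature: {unknown[0]!r}"
                )
            below = mask.reindex(
                index=values.index, columns=values.columns
            ).eq(LOD_TOKEN)
            values = values.mask(below)
        return cls(values, below)


@dataclass
class ScoreCoefficients:
    """Weights projecting z-scaled log analytes onto a single score.

    ``transform_spec`` records the provenance of the expected input
    transform (log base, the add-one rule for zero-containing analytes,
    and the scope of z-scaling), so a score file can be audited.
    """

    analyte_names: list[str]
    weights: np.ndarray
    transform_spec: dict = field(
        default_factory=lambda: {
            "log_base": "e",
            "add_one_rule": "analytes containing any zero",
            "scaling_scope": "per_cohort",
        }
    )

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.analyte_names) != len(self.weights):
            raise ValueError(
                f"{len(self.analyte_names)} analyte names but "
                f"{len(self.weights)} weights"
            )
        if len(set(self.analyte_names)) != len(self.analyte_names):
            raise ValueError("analyte names must be unique")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreCoefficients":
        table = pd.read_csv(path, sep="\t")
        if not {"analyte", "weight"} <= set(table.columns):
            raise ValueError("coefficient table needs 'analyte' and 'weight' columns")
        return cls(list(table["analyte"]), table["weight"].to_numpy(float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"analyte": self.analyte_names, "weight": self.weights}
        ).to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class ContrastDesign:
    """Case/control membership, with either a matching map or pair structure.

    ``mode='population'``: ``matching_map`` maps each case to the controls
    admissible for it (same sex, age within tolerance). ``mode='twin'``:
    ``pair_map`` maps a pair id to ``(high_id, low_id, abs_score_difference)``
    and the higher-scoring co-twin is the case.
    """

    mode: str
    case_ids: list
    control_ids: list
    matching_map: dict = field(default_factory=dict)
    pair_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("population", "twin"):
            raise ValueError(f"unknown design mode {self.mode!r}")
        overlap = set(self.case_ids) & set(self.control_ids)
        if overlap:
            raise ValueError(f"case/control sets overlap: {sorted(overlap)[:3]}")
        if self.mode == "population" and len(self.case_ids) != len(self.control_ids):
            raise ValueError(
                "population design requires equal case and control counts "
                f"({len(self.case_ids)} vs {len(self.control_ids)})"
            )

    @property
    def all_ids(self) -> list:
        return list(self.case_ids) + list(self.control_ids)

    def status(self, sample_ids: Iterable) -> pd.Series:
        """0/1 case indicator over ``sample_ids`` (all must be in the design)."""
        cases = set(self.case_ids)
        controls = set(self.control_ids)
        out = {}
        for sid in sample_ids:
            if sid in cases:
                out[sid] = 1
            elif sid in controls:
                out[sid] = 0
            else:
                raise KeyError(f"sample {sid!r} not covered by the design")
        return pd.Series(out, dtype=int)

    def pair_id_of(self) -> pd.Series:
        """Twin mode: sample id -> pair id."""
        if self.mode != "twin":
            raise ValueError("pair structure only exists in twin mode")
        out = {}
        for pid, (hi, lo, _) in self.pair_map.items():
            out[hi] = pid
            out[lo] = pid
        return pd.Series(out)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        if self.mode == "twin":
            for pid, (hi, lo, diff) in sorted(self.pair_map.items()):
                rows.append({"sample_id": hi, "role": "case", "stratum": pid})
                rows.append({"sample_id": lo, "role": "control", "stratum": pid})
        else:
            for cid in self.case_ids:
                rows.append({"sample_id": cid, "role": "case", "stratum": ""})
            for cid in self.control_ids:
                rows.append({"sample_id": cid, "role": "control", "stratum": ""})
        return pd.DataFrame(rows, columns=["sample_id", "role", "stratum"])

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        meta = {
            "mode": self.mode,
            "matching_map": {str(k): [str(v) for v in vs] for k, vs in self.matching_map.items()},
            "pair_map": {
                str(k): {"high": str(hi), "low": str(lo), "abs_score_difference": diff}
                for k, (hi, lo, diff) in self.pair_map.items()
            },
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


# ---------------------------------------------------------------- sample I/O
def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="sample_id")
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    return table


# public aliases used by the pipeline module
read_matrix = FeatureMatrix.read


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    matrix.write(path)
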