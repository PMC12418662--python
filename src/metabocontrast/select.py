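"""Extreme-score case/control selection and discordant-twin-pair extraction.

Population cohorts: cases are the top scorers on the age-independent score;
controls are admitted greedily in ascending score order, each needing at
least one case of identical sex within the age tolerance — a nested
case-control design matched on age and sex. Twin registry: complete
monozygotic pairs are ranked by the absolute within-pair score difference
and the most discordant pairs are taken, the higher-scoring co-twin being
the case. All orderings break ties by sample/pair id so selections are
reproducible.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .containers import ContrastDesign

SCORE_COLUMN = "age_residual_score"


def _score_series(scores: pd.DataFrame) -> pd.Series:
    col = SCORE_COLUMN if SCORE_COLUMN in scores.columns else "raw_score"
    return scores[col]


def select_extreme_cases(scores: pd.DataFrame, n_cases: int) -> list:
    """Ids of the ``n_cases`` samples with the largest age-independent score
    (descending score, ties broken by ascending sample id)."""
    if n_cases <= 0:
        raise ValueError("n_cases must be positive")
    s = _score_series(scores)
    if n_cases > len(s):
        raise ValueError(f"n_cases={n_cases} exceeds population size {len(s)}")
    order = sorted(s.index, key=lambda sid: (-s[sid], str(sid)))
    return order[:n_cases]


def select_matched_controls(
    scores: pd.DataFrame,
    cases: list,
    covars: pd.DataFrame,
    n_controls: int | None = None,
    age_tolerance: float = 2.5,
) -> ContrastDesign:
    """Greedy matched-control selection.

    Candidates (non-cases) are visited in ascending score order; one is
    admitted iff some case shares its sex and differs in age by at most
    ``age_tolerance`` years. Stops once ``n_controls`` are admitted. The
    matching map records, per case, every admitted control that qualified
    for it.
    """
    if age_tolerance < 0:
        raise ValueError("age_tolerance must be non-negative")
    if n_controls is None:
        n_controls = len(cases)
    s = _score_series(scores)
    case_set = set(cases)
    case_info = [(cid, covars.at[cid, "sex"], covars.at[cid, "age"]) for cid in cases]

    candidates = sorted(
        (sid for sid in s.index if sid not in case_set),
        key=lambda sid: (s[sid], str(sid)),
    )
    controls: list = []
    matching: dict = {cid: [] for cid in cases}
    for sid in candidates:
        if len(controls) >= n_controls:
            break
        sex, age = covars.at[sid, "sex"], covars.at[sid, "age"]
        hits = [
            cid
            for cid, csex, cage in case_info
            if csex == sex and abs(cage - age) <= age_tolerance
        ]
        if hits:
            controls.append(sid)
            for cid in hits:
                matching[cid].append(sid)
    if len(controls) < n_controls:
        unmatched = sorted(
            {
                (covars.at[cid, "sex"], round(covars.at[cid, "age"], 1))
                for cid in cases
                if not matching[cid]
            }
        )
        raise ValueError(
            f"only {len(controls)} admissible controls found "
            f"(needed {n_controls}); case strata without any match "
            f"(sex, age): {unmatched}"
        )
    return ContrastDesign(
        mode="population",
        case_ids=list(cases),
        control_ids=controls,
        matching_map=matching,
    )


def select_extremes_design(
    scores: pd.DataFrame,
    covars: pd.DataFrame,
    n_cases: int = 25,
    age_tolerance: float = 2.5,
) -> ContrastDesign:
    """Convenience wrapper: top-score cases plus matched controls."""
    cases = select_extreme_cases(scores, n_cases)
    return select_matched_controls(
        scores, cases, covars, n_controls=n_cases, age_tolerance=age_tolerance
    )


def select_discordant_pairs(
    scores: pd.DataFrame, covars: pd.DataFrame, n_pairs: int = 25
) -> ContrastDesign:
    """The ``n_pairs`` complete MZ pairs with the largest absolute within-pair
    score difference; within each pair the higher scorer is the case.

    Pairs with a member lacking a score are excluded with a warning. Ties in
    the absolute difference are broken by ascending pair (family) id; within
    a tied pair, by sample id.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    s = _score_series(scores)
    mz = covars[covars["zygosity"] == "MZ"]
    pairs = []
    for fam, members in mz.groupby("family_id").groups.items():
        members = list(members)
        scored = [m for m in members if m in s.index and pd.notna(s.get(m))]
        if len(members) != 2 or len(scored) != 2:
            warnings.warn(
                f"MZ pair {fam!r} incomplete ({len(scored)} scored members); excluded"
            )
            continue
        a, b = sorted(scored, key=str)
        hi, lo = (a, b) if s[a] >= s[b] else (b, a)
        pairs.append((fam, hi, lo, abs(s[a] - s[b])))
    if n_pairs > len(pairs):
        raise ValueError(
            f"n_pairs={n_pairs} exceeds the {len(pairs)} available complete MZ pairs"
        )
    pairs.sort(key=lambda rec: (-rec[3], str(rec[0])))
    chosen = pairs[:n_pairs]
    return ContrastDesign(
        mode="twin",
        case_ids=[hi for _, hi, _, _ in chosen],
        control_ids=[lo for _, _, lo, _ in chosen],
        pair_map={fam: (hi, lo, diff) for fam, hi, lo, diff in chosen},
    )
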