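import math

import numpy as np
import pandas as pd
import pytest

from metabocontrast.containers import ContrastDesign
from metabocontrast.prep import (
    detectability_table,
    filter_missing,
    filter_undetected,
    fisher_exact_2x2,
    mask_outliers,
    nipals_impute,
    prep_cytokines,
    prep_transform,
)
from metabocontrast.simulate import SimConfig, apply_detection_limit, simulate_population
from conftest import make_matrix


def exact_fisher_oracle(table):
    """Independent two-sided Fisher p: enumerate all tables with the observed
    margins, summing hypergeometric point probabilities <= the observed one
    (exact integer arithmetic until the final division)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def point(k):  # P(X = k) * C(n, c1), integer
        return math.comb(r1, k) * math.comb(r2, c1 - k)

    denom = math.comb(n, c1)
    obs = point(a)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = point(k)
        if pk <= obs:
            total += pk
    return total / denom


class TestFisherExact:
    def test_balanced_table_is_null(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_extreme_table(self):
        expected = 2 / math.comb(20, 10)
        assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(
            expected, rel=1e-7
        )

    def test_small_table_vs_enumeration(self):
        table = [[3, 1], [1, 3]]
        assert fisher_exact_2x2(table) == pytest.approx(
            exact_fisher_oracle(table), rel=1e-10
        )

    @pytest.mark.parametrize("table", [[[4, 2], [1, 5]], [[0, 7], [3, 2]]])
    def test_symmetry_under_row_and_column_swap(self, table):
        p = fisher_exact_2x2(table)
        assert fisher_exact_2x2(table[::-1]) == pytest.approx(p, rel=1e-12)
        swapped = [row[::-1] for row in table]
        assert fisher_exact_2x2(swapped) == pytest.approx(p, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -2], [3, 4]])


class TestDetectability:
    def design6(self):
        return ContrastDesign(
            "population", ["s1", "s2", "s3"], ["s4", "s5", "s6"]
        )

    def test_hand_counted_table(self):
        mask = [[True], [False], [False], [True], [True], [False]]
        mat = make_matrix(np.ones((6, 1)), below_lod=mask)
        res = detectability_table(mat, self.design6())
        assert res.table("f1").tolist() == [[2, 1], [1, 2]]
        assert (res.fdr_adjusted_p >= res.fisher_p - 1e-15).all()

    def test_no_censoring_gives_zero_undetected(self):
        mat = make_matrix(np.ones((6, 2)))
        res = detectability_table(mat, self.design6())
        assert (res.counts[["case_undetected", "control_undetected"]] == 0).all().all()
        assert (res.fisher_p == 1.0).all()

    def test_full_censoring_gives_zero_detected(self):
        mat = make_matrix(np.ones((6, 1)), below_lod=[[True]] * 6)
        res = detectability_table(mat, self.design6())
        assert (res.counts[["case_detected", "control_detected"]] == 0).all().all()

    def test_sample_outside_design_rejected(self):
        mat = make_matrix(np.ones((7, 1)))
        with pytest.raises(KeyError):
            detectability_table(mat, self.design6())


class TestFilters:
    def test_undetected_strictly_greater_semantics(self):
        n = 100
        mask66 = [[True]] * 66 + [[False]] * 34
        mask65 = [[True]] * 65 + [[False]] * 35
        removed, rep = filter_undetected(make_matrix(np.ones((n, 1)), below_lod=mask66))
        assert removed.shape[1] == 0 and rep.excluded_features[0][0] == "f1"
        retained, _ = filter_undetected(make_matrix(np.ones((n, 1)), below_lod=mask65))
        assert retained.shape[1] == 1  # exactly 65% kept
        full, _ = filter_undetected(make_matrix(np.ones((n, 1))))
        assert full.shape[1] == 1

    def test_missing_strictly_greater_semantics(self):
        vals = np.ones((100, 1))
        m6 = vals.copy(); m6[:6, 0] = np.nan
        m5 = vals.copy(); m5[:5, 0] = np.nan
        assert filter_missing(make_matrix(m6))[0].shape[1] == 0
        assert filter_missing(make_matrix(m5))[0].shape[1] == 1  # exactly 5% kept
        assert filter_missing(make_matrix(vals))[0].shape[1] == 1

    def test_absolute_count_mode(self):
        vals = np.ones((50, 1)); vals[:3, 0] = np.nan
        kept, _ = filter_missing(make_matrix(vals), max_missing_count=3)
        assert kept.shape[1] == 1
        dropped, _ = filter_missing(make_matrix(vals), max_missing_count=2)
        assert dropped.shape[1] == 0

    def test_threshold_range_validated(self):
        with pytest.raises(ValueError):
            filter_undetected(make_matrix(np.ones((3, 1))), 1.2)
        with pytest.raises(ValueError):
            filter_missing(make_matrix(np.ones((3, 1))), -0.1)


class TestOutlierMask:
    def test_single_pass_moments_keep_moderate_extreme(self):
        # mean 20, sd ~44.7: |100 - 20| = 80 < 5 sd -> retained
        mat = make_matrix(np.array([0.0, 0.0, 0.0, 0.0, 100.0])[:, None])
        out, rep = mask_outliers(mat, k_sd=5.0)
        assert out.values.notna().all().all()
        assert rep.outlier_cells == []

    def test_gross_outlier_masked_exactly_once(self):
        rng = np.random.default_rng(30)
        vals = rng.standard_normal(1001)
        vals[500] = 1e6
        out, rep = mask_outliers(make_matrix(vals[:, None]), k_sd=5.0)
        assert len(rep.outlier_cells) == 1
        assert rep.outlier_cells[0] == ("s501", "f1")
        assert int(out.values.isna().sum().sum()) == 1

    def test_exactly_k_sd_retained(self):
        # strictly-greater boundary: |x - mean| == k sd stays
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        mu, sd = vals.mean(), vals.std(ddof=1)
        k = abs(vals[-1] - mu) / sd
        out, rep = mask_outliers(make_matrix(vals[:, None]), k_sd=k)
        assert out.values.notna().all().all() and rep.outlier_cells == []

    def test_too_few_observations_warns_and_skips(self):
        vals = np.array([[1.0], [np.nan], [np.nan], [np.nan]])
        with pytest.warns(UserWarning, match="skipped"):
            out, _ = mask_outliers(make_matrix(vals), k_sd=5.0)
        assert out.values.iloc[0, 0] == 1.0


class TestNipals:
    def test_complete_matrix_returned_unchanged(self):
        mat = make_matrix(np.random.default_rng(0).normal(size=(10, 4)))
        out, rep = nipals_impute(mat, n_components=2)
        pd.testing.assert_frame_equal(out.values, mat.values)
        assert rep.imputed_cells == []

    def test_rank_one_completion_is_exact(self):
        rng = np.random.default_rng(31)
        u = rng.normal(size=60)
        v = rng.normal(size=12)
        X = np.outer(u, v)
        holes = rng.random(X.shape) < 0.05
        Xm = X.copy()
        Xm[holes] = np.nan
        out, rep = nipals_impute(make_matrix(Xm), n_components=1, tol=1e-12,
                                 max_iter=2000)
        rel = np.abs(out.values.to_numpy()[holes] - X[holes]) / (
            np.abs(X[holes]) + 1e-300
        )
        assert rel.max() < 1e-6
        assert len(rep.imputed_cells) == int(holes.sum())

    def test_observed_cells_never_altered(self):
        rng = np.random.default_rng(32)
        X = rng.normal(size=(30, 8))
        holes = rng.random(X.shape) < 0.1
        Xm = X.copy()
        Xm[holes] = np.nan
        out, _ = nipals_impute(make_matrix(Xm), n_components=3)
        obs = ~holes
        assert (out.values.to_numpy()[obs] == X[obs]).all()

    def test_matches_em_svd_oracle_on_low_rank_matrix(self):
        """Independent oracle: EM with full SVD reconstruction (fill holes,
        iterate rank-k SVD refits) agrees with NIPALS on an exactly rank-2
        matrix with a single hole."""
        rng = np.random.default_rng(33)
        X = (np.outer(rng.normal(size=6), rng.normal(size=5))
             + np.outer(rng.normal(size=6), rng.normal(size=5)))
        Xm = X.copy()
        Xm[1, 2] = np.nan

        # EM-SVD oracle
        filled = Xm.copy()
        col_mean = np.nanmean(Xm, axis=0)
        filled[1, 2] = col_mean[2]
        for _ in range(5000):
            mu = filled.mean(axis=0)
            U, s, Vt = np.linalg.svd(filled - mu, full_matrices=False)
            recon = (U[:, :2] * s[:2]) @ Vt[:2] + mu
            if abs(recon[1, 2] - filled[1, 2]) < 1e-12:
                break
            filled[1, 2] = recon[1, 2]

        out, _ = nipals_impute(make_matrix(Xm), n_components=2, tol=1e-12,
                               max_iter=5000)
        assert out.values.iloc[1, 2] == pytest.approx(filled[1, 2], abs=1e-4)
        assert out.values.iloc[1, 2] == pytest.approx(X[1, 2], abs=1e-4)

    def test_all_missing_feature_rejected(self):
        vals = np.ones((5, 2))
        vals[:, 1] = np.nan
        with pytest.raises(ValueError, match="no observed values"):
            nipals_impute(make_matrix(vals), n_components=1)

    def test_component_budget_validated(self):
        vals = np.ones((4, 3)) + np.eye(4, 3)
        vals[0, 0] = np.nan
        with pytest.raises(ValueError, match="n_components"):
            nipals_impute(make_matrix(vals), n_components=3)


class TestPrepTransform:
    def test_log_then_z_hand_example(self):
        mat = make_matrix(np.array([1.0, np.e, np.e**2])[:, None])
        out = prep_transform(mat, pd.Series("A", index=mat.sample_ids))
        assert np.allclose(out.values["f1"], [-1.0, 0.0, 1.0])

    def test_cohort_location_shift_removed(self):
        base = np.exp(np.random.default_rng(34).normal(size=12))
        mat = make_matrix(np.concatenate([base, base * 50.0])[:, None])
        labels = pd.Series(["A"] * 12 + ["B"] * 12, index=mat.sample_ids)
        out = prep_transform(mat, labels)
        a = out.values["f1"].iloc[:12].to_numpy()
        b = out.values["f1"].iloc[12:].to_numpy()
        assert np.allclose(a, b, atol=1e-10)

    def test_zero_containing_analyte_routed_through_log1p(self):
        mat = make_matrix(np.array([0.0, np.e - 1.0, np.e**2 - 1.0])[:, None])
        out = prep_transform(mat, pd.Series("A", index=mat.sample_ids))
        z = (np.array([0.0, 1.0, 2.0]) - 1.0) / 1.0
        assert np.allclose(out.values["f1"], z)


def test_cytokine_pipeline_excludes_exactly_the_high_lod_panel():
    """Generator scenario: six cytokines carry detection limits above most of
    their distribution; the undetected-fraction filter must remove exactly
    those six of the fifteen."""
    cfg = SimConfig(n_per_cohort={"LLS": 300}, seed=41)
    samples, mats, _ = simulate_population(cfg, "LLS")
    cyto = apply_detection_limit(
        mats["cytokines"], mats["cytokines"].feature_meta["lod"]
    )
    ids = list(cyto.sample_ids)
    design = ContrastDesign("population", ids[:150], ids[150:])
    prepped, detect, report = prep_cytokines(cyto, design, samples["cohort"])
    excluded = {f for f, _ in report.excluded_features}
    assert excluded == {"IL2", "TRAIL", "GRO1a", "IFNg", "IL1b", "PAI1"}
    assert prepped.shape[1] == 9
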