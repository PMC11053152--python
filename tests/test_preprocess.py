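"""Preprocessing chain: CV, filtering, imputation, ComBat, cleanup, merging."""

import numpy as np
import pandas as pd
import pytest

from pptc_protrisk import preprocess as pp
from pptc_protrisk.containers import PipelineOrderError
from pptc_protrisk.synthetic import generate_cohort, inject_missingness

from conftest import matrix_from_values, small_config


class TestComputeCV:
    def test_constant_protein_has_zero_cv(self):
        m = matrix_from_values(np.full((3, 4), 5.0))
        cv = pp.compute_cv(m, m.sample_ids)
        assert (cv == 0).all()

    def test_hand_computed_two_point_cv(self):
        # values {1, 3}: sample sd = sqrt(2), mean = 2 -> CV = sqrt(2)/2
        m = matrix_from_values(np.array([[1.0, 3.0]]))
        cv = pp.compute_cv(m, m.sample_ids)
        assert cv.iloc[0] == pytest.approx(np.sqrt(2) / 2, abs=1e-12)

    def test_all_missing_protein_excluded_from_median(self):
        vals = np.array([[1.0, 3.0], [np.nan, np.nan]])
        m = matrix_from_values(vals)
        cv = pp.compute_cv(m, m.sample_ids)
        assert np.isnan(cv.iloc[1])
        assert cv.median() == pytest.approx(np.sqrt(2) / 2)

    def test_empty_subset_rejected(self):
        m = matrix_from_values(np.ones((2, 3)))
        with pytest.raises(ValueError):
            pp.compute_cv(m, [])

    def test_qc_report_covers_pools_and_replicates(self, small_cohort):
        matrix, _, _ = small_cohort
        rep = pp.qc_report(matrix)
        assert rep.replicate_cv.shape[1] == 4
        assert 0 < rep.median_pooled_cv < 0.2
        assert rep.na_rate.between(0, 1).all()


class TestFilterByMissingness:
    def test_strictly_above_threshold_removed(self):
        # NA rates 0.90, 0.85, 0.10 on 20 samples; 0.85 is kept (strict >)
        vals = np.ones((3, 20))
        vals[0, :18] = np.nan
        vals[1, :17] = np.nan
        vals[2, :2] = np.nan
        m = matrix_from_values(vals)
        kept = pp.filter_by_missingness(m, 0.85)
        assert list(kept.protein_ids) == ["P0001", "P0002"]

    def test_threshold_one_is_identity(self, small_cohort):
        matrix, _, _ = small_cohort
        assert pp.filter_by_missingness(matrix, 1.0).values.shape == matrix.values.shape

    def test_order_preserved(self, small_cohort):
        matrix, _, _ = small_cohort
        kept = pp.filter_by_missingness(matrix, 0.5)
        original = [p for p in matrix.protein_ids if p in set(kept.protein_ids)]
        assert list(kept.protein_ids) == original


class TestImputeSequential:
    def test_complete_matrix_unchanged(self):
        m = matrix_from_values(np.random.default_rng(0).normal(size=(20, 10)))
        out = pp.impute_sequential(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_rank_one_matrix_recovered_exactly(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=30)
        v = rng.normal(size=25)
        full = np.outer(u, v) + 20.0
        mask = rng.random(full.shape) < 0.05
        vals = full.copy()
        vals[mask] = np.nan
        # keep at least one complete anchor row
        vals[0] = full[0]
        out = pp.impute_sequential(matrix_from_values(vals))
        assert np.allclose(out.values.to_numpy(), full, atol=1e-6)

    def test_beats_median_imputation_on_mcar_mask(self, clean_cohort):
        matrix, _, _ = clean_cohort
        masked, records = inject_missingness(matrix, 0.0, 0.1, seed=9)
        truth = matrix.values
        errs = {}
        for name in ("sequential", "median"):
            imp = pp.IMPUTERS[name](masked).values
            diffs = [
                imp.at[r["protein"], r["sample"]] - truth.at[r["protein"], r["sample"]]
                for _, r in records.iterrows()
            ]
            errs[name] = float(np.sqrt(np.mean(np.square(diffs))))
        assert errs["sequential"] < errs["median"]

    def test_observed_entries_untouched(self, small_cohort):
        matrix, _, _ = small_cohort
        out = pp.impute_sequential(matrix)
        obs = matrix.values.notna().to_numpy()
        assert np.array_equal(out.values.to_numpy()[obs],
                              matrix.values.to_numpy()[obs])

    def test_all_missing_row_rejected(self):
        vals = np.ones((3, 4))
        vals[1] = np.nan
        with pytest.raises(pp.DataError, match="P0001"):
            pp.impute_sequential(matrix_from_values(vals))


class TestReplaceNonpositive:
    def test_hand_examples(self):
        m = matrix_from_values(np.array([[-1.0, 4.0, 8.0], [0.0, 0.5, 2.0]]),
                               scale="linear")
        out = pp.replace_nonpositive(m)
        assert list(out.values.iloc[0]) == [2.0, 4.0, 8.0]
        assert list(out.values.iloc[1]) == [0.25, 0.5, 2.0]

    def test_all_positive_unchanged_and_idempotent(self):
        m = matrix_from_values(np.array([[-1.0, 4.0, 8.0]]), scale="linear")
        once = pp.replace_nonpositive(m)
        twice = pp.replace_nonpositive(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_no_positive_value_errors(self):
        m = matrix_from_values(np.array([[-1.0, 0.0, -3.0]]), scale="linear")
        with pytest.raises(pp.DataError, match="P0000"):
            pp.replace_nonpositive(m)

    def test_requires_linear_scale(self):
        m = matrix_from_values(np.ones((2, 3)), scale="log2")
        with pytest.raises(ValueError):
            pp.replace_nonpositive(m)


class TestCorrectBatch:
    def test_single_batch_identity(self):
        m = matrix_from_values(np.random.default_rng(0).normal(20, 1, (10, 8)))
        out = pp.correct_batch(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_additive_shift_removed_in_noise_free_case(self):
        rng = np.random.default_rng(1)
        base = rng.normal(20, 2, (30, 1)) * np.ones((1, 20))
        shift = rng.normal(0, 1, (30, 1))
        vals = base.copy()
        vals[:, 10:] += shift
        # tiny jitter so per-batch variances are defined
        vals += rng.normal(0, 1e-4, vals.shape)
        m = matrix_from_values(vals, batches=[1] * 10 + [2] * 10)
        out = pp.correct_batch(m)
        b1 = out.values.iloc[:, :10].mean(axis=1)
        b2 = out.values.iloc[:, 10:].mean(axis=1)
        assert np.allclose(b1, b2, atol=1e-4)

    def test_batch_variance_collapses_on_synthetic_cohort(self, small_cohort):
        matrix, _, _ = small_cohort
        complete = pp.impute_sequential(pp.filter_by_missingness(matrix, 0.85))
        before = pp.batch_r2(complete).mean()
        corrected = pp.correct_batch(complete)
        after = pp.batch_r2(corrected).mean()
        assert before > 0.1
        assert after < 0.01

    def test_global_means_approximately_preserved(self, small_cohort):
        matrix, _, _ = small_cohort
        complete = pp.impute_sequential(pp.filter_by_missingness(matrix, 0.85))
        corrected = pp.correct_batch(complete)
        drift = (corrected.values.mean(axis=1) - complete.values.mean(axis=1)).abs()
        assert drift.max() < 0.05

    def test_incomplete_matrix_rejected(self, small_cohort):
        matrix, _, _ = small_cohort
        with pytest.raises(pp.DataError):
            pp.correct_batch(matrix)

    def test_small_batch_rejected(self):
        m = matrix_from_values(np.random.default_rng(0).normal(size=(5, 5)),
                               batches=[1, 1, 1, 1, 2])
        with pytest.raises(pp.DataError):
            pp.correct_batch(m)


class TestMergeReplicates:
    def test_pair_mean_and_pool_removal(self, small_cohort):
        matrix, _, _ = small_cohort
        merged = pp.merge_replicates(matrix)
        links = matrix.meta["replicate_of"].dropna()
        rep, orig = next(iter(links.items()))
        expected = matrix.values[[orig, rep]].mean(axis=1, skipna=True)
        pd.testing.assert_series_equal(
            merged.values[orig], expected, check_names=False
        )
        assert "POOL" not in set(merged.meta["group"])
        assert merged.values.shape[1] == 90  # 30 + 40 + 20 biological samples

    def test_study_layout_merges_240_to_234(self):
        cfg = small_config(n_pm=85, n_pb=83, n_am=66, n_replicate_pairs=6,
                           n_batches=16, n_proteins=40)
        matrix, _, _ = generate_cohort(cfg)
        merged = pp.merge_replicates(matrix)
        assert merged.values.shape[1] == 234

    def test_no_replicates_is_identity_and_idempotent(self):
        m = matrix_from_values(np.random.default_rng(0).normal(size=(4, 6)))
        once = pp.merge_replicates(m)
        twice = pp.merge_replicates(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_dangling_link_rejected(self, small_cohort):
        matrix, _, _ = small_cohort
        broken = matrix.copy()
        links = broken.meta["replicate_of"].dropna()
        orig = next(iter(links.values))
        broken.values = broken.values.drop(columns=orig)
        broken.meta = broken.meta.drop(index=orig)
        with pytest.raises(pp.DataError):
            pp.merge_replicates(broken)


class TestPipelineOrdering:
    def test_history_tracks_stage_order(self, small_cohort):
        matrix, _, _ = small_cohort
        m = pp.filter_by_missingness(matrix, 0.85)
        m = pp.impute_sequential(m)
        m = pp.correct_batch(m)
        assert m.history[-3:] == ["filter", "impute", "combat"]

    def test_out_of_order_invocation_rejected(self, small_cohort):
        matrix, _, _ = small_cohort
        with pytest.raises(PipelineOrderError):
            matrix.require_history("impute")

    def test_identifiers_preserved_through_chain(self, small_cohort):
        matrix, _, _ = small_cohort
        m = pp.correct_batch(
            pp.impute_sequential(pp.filter_by_missingness(matrix, 0.85))
        )
        assert list(m.sample_ids) == list(matrix.sample_ids)
        assert set(m.protein_ids) <= set(matrix.protein_ids)
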