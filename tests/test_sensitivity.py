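"""CV, within-dataset ranks, and rank-mean sensitive values."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exprsens import (
    NumericError,
    PipelineError,
    SensitivityConfig,
    build_sensitivity_table,
    compute_cv,
    compute_sv,
    floor_and_log,
    rank_within_dataset,
)

from _oracles import cv_oracle, rank_oracle, sv_oracle
from conftest import make_dataset


def _gene_level(values, **kw):
    return make_dataset(values, log_transformed=True, **kw)


class TestCV:
    def test_constant_gene_has_zero_cv(self):
        cv = compute_cv(_gene_level([[4.0, 4.0, 4.0]]))
        assert cv.iloc[0] == 0.0

    def test_hand_computed_two_sample_case(self):
        cv = compute_cv(_gene_level([[3.0, 5.0]]))
        assert cv.iloc[0] == pytest.approx(math.sqrt(2) / 4, abs=1e-12)

    def test_matches_two_pass_oracle_elementwise(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(3, 14, (50, 9))
        cv = compute_cv(_gene_level(vals))
        for i in range(vals.shape[0]):
            assert cv.iloc[i] == pytest.approx(cv_oracle(list(vals[i])), abs=1e-10)

    def test_non_positive_mean_is_a_numeric_error(self):
        ds = _gene_level([[1.0, -3.0]], probes=["gBad"])
        with pytest.raises(NumericError, match="gBad"):
            compute_cv(ds)

    def test_single_sample_rejected(self):
        with pytest.raises(PipelineError, match="2 samples"):
            compute_cv(_gene_level([[4.0]]))

    def test_raw_scale_option_backtransforms(self):
        vals = np.array([[3.0, 5.0, 4.0]])
        cv_log = compute_cv(_gene_level(vals))
        cv_raw = compute_cv(_gene_level(vals), SensitivityConfig(cv_scale="raw"))
        raw = 2.0 ** vals[0]
        assert cv_raw.iloc[0] == pytest.approx(cv_oracle(list(raw)), abs=1e-12)
        assert cv_raw.iloc[0] != pytest.approx(cv_log.iloc[0], abs=1e-6)


class TestRanks:
    def test_strict_ordering(self):
        ranks = rank_within_dataset(pd.Series([0.1, 0.3, 0.2]))
        assert list(ranks) == [1.0, 3.0, 2.0]

    def test_ties_receive_average_rank(self):
        ranks = rank_within_dataset(pd.Series([0.2, 0.2]))
        assert list(ranks) == [1.5, 1.5]

    def test_empty_vector_rejected(self):
        with pytest.raises(PipelineError):
            rank_within_dataset(pd.Series([], dtype=float))

    def test_matches_sort_then_assign_oracle_with_planted_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            vals = np.round(rng.uniform(0, 1, 40), 2)  # rounding plants ties
            ranks = rank_within_dataset(pd.Series(vals))
            expected = rank_oracle(list(vals))
            np.testing.assert_allclose(ranks.to_numpy(), expected, atol=1e-12)

    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=30))
    def test_rank_sum_invariant(self, vals):
        n = len(vals)
        ranks = rank_within_dataset(pd.Series(vals))
        assert ranks.sum() == pytest.approx(n * (n + 1) / 2, abs=1e-9)


class TestSV:
    @staticmethod
    def _table(rank_rows: dict[str, list[float | None]], ds_ids=None):
        genes = sorted(rank_rows)
        m = len(next(iter(rank_rows.values())))
        ds_ids = ds_ids or [f"D{j + 1}" for j in range(m)]
        ranks = pd.DataFrame(
            [[np.nan if v is None else v for v in rank_rows[g]] for g in genes],
            index=genes, columns=ds_ids, dtype=float,
        )
        return ranks

    def test_single_dataset_sv_equals_its_ranks(self):
        ranks = self._table({"a": [2.0], "b": [1.0], "c": [3.0]})
        table = compute_sv(ranks, ranks)
        assert table.sv.to_dict() == {"b": 1.0, "a": 2.0, "c": 3.0}
        assert list(table.sv.index) == ["b", "a", "c"]  # ascending SV

    def test_mean_of_two_ranks(self):
        ranks = self._table({"a": [3.0, 5.0]})
        assert compute_sv(ranks, ranks).sv["a"] == 4.0

    def test_matches_loop_oracle_on_simulated_ranks(self):
        rng = np.random.default_rng(5)
        rank_rows = {
            f"g{i}": [float(r) for r in rng.integers(1, 100, 10)]
            for i in range(60)
        }
        ranks = self._table(rank_rows)
        table = compute_sv(ranks, ranks)
        expected = sv_oracle({g: list(v) for g, v in rank_rows.items()})
        for gene, sv in expected.items():
            assert table.sv[gene] == pytest.approx(sv, abs=1e-10)

    def test_low_coverage_genes_excluded_and_divided_by_own_m(self):
        ranks = self._table({
            "full": [1.0, 2.0, 3.0, 4.0],
            "half": [5.0, 6.0, None, None],
            "rare": [7.0, None, None, None],
        })
        table = compute_sv(ranks, ranks, SensitivityConfig(min_coverage_fraction=0.5))
        assert table.sv["full"] == 2.5
        assert table.sv["half"] == 5.5  # mean over its own 2 datasets
        assert "rare" not in table.sv.index
        assert table.excluded == ["rare"]
        assert table.coverage["rare"] == 1

    def test_no_datasets_is_a_pipeline_error(self):
        empty = pd.DataFrame(index=["a"], columns=[], dtype=float)
        with pytest.raises(PipelineError):
            compute_sv(empty, empty)


class TestInvariances:
    def test_sample_permutation_leaves_cv_ranks_sv_identical(self, tiny_collection):
        datasets, pmap, _ = tiny_collection
        from exprsens import preprocess_collection
        gene_level = preprocess_collection(datasets, pmap)
        table = build_sensitivity_table(gene_level)
        rng = np.random.default_rng(6)
        shuffled = []
        for ds in gene_level:
            cols = list(rng.permutation(ds.sample_ids))
            shuffled.append(
                make_dataset(ds.values[cols].to_numpy(),
                             probes=list(ds.values.index), samples=cols,
                             dataset_id=ds.dataset_id, log_transformed=True)
            )
        table_p = build_sensitivity_table(shuffled)
        pd.testing.assert_series_equal(table.sv, table_p.sv)
        pd.testing.assert_frame_equal(table.cv, table_p.cv)

    def test_dataset_reordering_leaves_sv_identical(self, tiny_collection):
        datasets, pmap, _ = tiny_collection
        from exprsens import preprocess_collection
        gene_level = preprocess_collection(datasets, pmap)
        table = build_sensitivity_table(gene_level)
        table_r = build_sensitivity_table(list(reversed(gene_level)))
        pd.testing.assert_series_equal(table.sv, table_r.sv)

    def test_raw_mode_cv_ranks_invariant_to_positive_scaling(self):
        """CV = SD/mean is scale-free, so raw-mode ranks are exactly stable."""
        rng = np.random.default_rng(7)
        raw = rng.uniform(50, 5000, (80, 10))  # floor-free by construction
        cfg = SensitivityConfig(cv_scale="raw")
        for c in (2.0, 10.0):
            a = floor_and_log(make_dataset(raw))
            b = floor_and_log(make_dataset(c * raw))
            ra = rank_within_dataset(compute_cv(a, cfg), cfg)
            rb = rank_within_dataset(compute_cv(b, cfg), cfg)
            np.testing.assert_allclose(ra.to_numpy(), rb.to_numpy(), atol=1e-9)

    def test_log_mode_cv_ranks_stable_under_positive_scaling(self):
        """Log-mode CV shifts with the mean; ranks stay highly concordant."""
        from scipy.stats import spearmanr
        rng = np.random.default_rng(8)
        base = rng.normal(8, 1.5, 80).clip(5, None)
        sd = 0.25 * np.exp(rng.normal(0, 0.3, 80))
        raw = 2.0 ** rng.normal(base[:, None], sd[:, None], (80, 12))
        for c in (2.0, 10.0):
            a = floor_and_log(make_dataset(raw))
            b = floor_and_log(make_dataset(c * raw))
            ra = rank_within_dataset(compute_cv(a))
            rb = rank_within_dataset(compute_cv(b))
            rho = spearmanr(ra, rb).statistic
            assert rho > 0.95

    def test_planted_sensitive_mean_sv_exceeds_planted_robust(self, tiny_collection):
        datasets, pmap, truth = tiny_collection
        from exprsens import run_pipeline
        table = run_pipeline(datasets, pmap).table
        sv = table.sv
        mean_sens = sv[sorted(truth.planted_sensitive)].mean()
        mean_rob = sv[sorted(truth.planted_robust)].mean()
        assert mean_sens > mean_rob
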