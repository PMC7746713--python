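import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ceranet.expression import (
    CountPanel,
    TissueScoreTable,
    coexpression_score,
    cpm,
    filter_low_expression,
    median_of_ratios_normalize,
    srpbm,
    tissue_ecdf_scores,
)
from ceranet.io import ExpressionPanel


def make_counts(mat, features=None, samples=None, totals=None, feature_class="gene"):
    mat = np.asarray(mat)
    features = features or [f"f{i}" for i in range(mat.shape[0])]
    samples = samples or [f"s{i}" for i in range(mat.shape[1])]
    df = pd.DataFrame(mat, index=features, columns=samples)
    tot = pd.Series(totals, index=samples) if totals is not None else None
    return CountPanel(counts=df, feature_class=feature_class, total_mapped_reads=tot)


class TestMedianOfRatios:
    def test_identical_samples_unchanged(self):
        panel = median_of_ratios_normalize(make_counts([[4, 4], [10, 10], [7, 7]]))
        assert np.allclose(panel.values.to_numpy(), [[4, 4], [10, 10], [7, 7]])

    def test_doubled_sample_rescaled_to_match(self):
        panel = median_of_ratios_normalize(make_counts([[4, 8], [10, 20], [7, 14]]))
        got = panel.values.to_numpy()
        assert np.allclose(got[:, 0], got[:, 1])

    def test_toy_panel_matches_hand_formula(self):
        mat = np.array([[10, 20, 30], [5, 5, 5], [100, 50, 25], [1, 2, 4]])
        # independent hand computation of size factors
        geo = np.exp(np.log(mat).mean(axis=1))
        sf = np.median(mat / geo[:, None], axis=0)
        panel = median_of_ratios_normalize(make_counts(mat))
        assert np.allclose(panel.values.to_numpy(), mat / sf)

    def test_zero_row_excluded_from_size_factors(self):
        mat = np.array([[4, 8], [0, 3], [10, 20]])
        panel = median_of_ratios_normalize(make_counts(mat))
        ref = np.array([[4, 8], [10, 20]])
        geo = np.exp(np.log(ref).mean(axis=1))
        sf = np.median(ref / geo[:, None], axis=0)
        assert np.allclose(panel.values.to_numpy(), mat / sf)

    def test_no_all_positive_feature_is_error(self):
        with pytest.raises(ValueError, match="CPM"):
            median_of_ratios_normalize(make_counts([[0, 1], [1, 0]]))

    def test_single_sample_is_error(self):
        with pytest.raises(ValueError, match="2 samples"):
            median_of_ratios_normalize(make_counts([[1], [2]]))


class TestCPMAndSRPBM:
    def test_cpm_forced_values(self):
        panel = cpm(make_counts([[1], [3]]))
        assert np.allclose(panel.values.to_numpy().ravel(), [250_000, 750_000])

    def test_cpm_columns_sum_to_million(self):
        rng = np.random.default_rng(3)
        panel = cpm(make_counts(rng.integers(0, 100, size=(20, 4)) + 1))
        assert np.allclose(panel.values.sum(axis=0), 1e6)

    def test_cpm_zero_column_is_error(self):
        with pytest.raises(ValueError, match="zero total"):
            cpm(make_counts([[0], [0]]))

    def test_srpbm_formula(self):
        panel = srpbm(make_counts([[1], [0]], totals=[1e9]))
        assert panel.values.iloc[0, 0] == 1.0
        assert panel.values.iloc[1, 0] == 0.0

    def test_srpbm_toy_matches_hand_arithmetic(self):
        panel = srpbm(make_counts([[3, 5], [7, 2]], totals=[2e8, 5e8]))
        expected = np.array([[3 / 2e8, 5 / 5e8], [7 / 2e8, 2 / 5e8]]) * 1e9
        assert np.allclose(panel.values.to_numpy(), expected)

    def test_srpbm_requires_totals(self):
        with pytest.raises(ValueError, match="total mapped reads"):
            srpbm(make_counts([[1]]))

    def test_missing_total_for_sample_is_error(self):
        df = pd.DataFrame([[1, 2]], index=["f"], columns=["s0", "s1"])
        with pytest.raises(ValueError, match="missing total"):
            CountPanel(counts=df, feature_class="circRNA",
                       total_mapped_reads=pd.Series({"s0": 1e9}))


class TestFilterLowExpression:
    def test_total_count_boundary(self):
        counts = make_counts([[9, 0], [10, 0]])
        norm = ExpressionPanel(
            values=pd.DataFrame([[100.0, 100.0], [100.0, 100.0]],
                                index=["f0", "f1"], columns=["s0", "s1"]),
            feature_class="gene",
        )
        assert filter_low_expression(counts, norm) == ["f1"]

    def test_mean_norm_boundary_inclusive(self):
        counts = make_counts([[50, 50], [50, 50]])
        norm = ExpressionPanel(
            values=pd.DataFrame([[10.0, 10.0], [9.9, 9.9]],
                                index=["f0", "f1"], columns=["s0", "s1"]),
            feature_class="gene",
        )
        assert filter_low_expression(counts, norm) == ["f0"]

    def test_random_fixture_equals_brute_force(self):
        rng = np.random.default_rng(5)
        mat = rng.integers(0, 30, size=(50, 3))
        counts = make_counts(mat)
        norm_vals = pd.DataFrame(rng.lognormal(2, 1, size=(50, 3)),
                                 index=counts.counts.index, columns=counts.counts.columns)
        norm = ExpressionPanel(values=norm_vals, feature_class="gene")
        expected = [
            f for f in counts.counts.index
            if mat[counts.counts.index.get_loc(f)].sum() >= 10
            and norm_vals.loc[f].mean() >= 10
        ]
        assert filter_low_expression(counts, norm) == expected

    def test_mismatched_features_is_error(self):
        counts = make_counts([[1, 1]])
        norm = ExpressionPanel(values=pd.DataFrame([[1.0, 1.0]], index=["other"],
                                                   columns=["s0", "s1"]),
                               feature_class="gene")
        with pytest.raises(ValueError, match="different feature sets"):
            filter_low_expression(counts, norm)


class TestTissueECDF:
    @staticmethod
    def scores_for(values, tissue="t"):
        panel = ExpressionPanel(
            values=pd.DataFrame({tissue: values},
                                index=[f"f{i}" for i in range(len(values))]),
            feature_class="gene",
        )
        table = tissue_ecdf_scores(panel)
        return table.scores.set_index("feature_id")["score"]

    def test_single_expressed_feature_scores_one(self):
        s = self.scores_for([5.0, 0.0])
        assert list(s.index) == ["f0"] and s["f0"] == 1.0

    def test_distinct_values_forced_by_definition(self):
        s = self.scores_for([1.0, 2.0, 3.0])
        assert np.allclose(s[["f0", "f1", "f2"]], [1 / 3, 2 / 3, 1.0])

    def test_ties_share_upper_score(self):
        s = self.scores_for([2.0, 2.0, 5.0])
        assert np.allclose(s[["f0", "f1", "f2"]], [2 / 3, 2 / 3, 1.0])

    def test_zeros_excluded_per_tissue(self, panel_3x2):
        table = tissue_ecdf_scores(panel_3x2)
        tb = table.scores[table.scores.tissue_id == "tB"]
        assert set(tb.feature_id) == {"f2"}
        assert tb.score.iloc[0] == 1.0

    def test_empty_tissue_omitted_with_warning(self, caplog):
        panel = ExpressionPanel(
            values=pd.DataFrame({"t0": [1.0], "t1": [0.0]}, index=["f"]),
            feature_class="gene",
        )
        with caplog.at_level("WARNING"):
            table = tissue_ecdf_scores(panel)
        assert table.tissue_ids == ["t0"]
        assert "no expressed" in caplog.text

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1e6, allow_nan=False), min_size=1, max_size=30))
    def test_scores_in_unit_interval_and_monotone(self, values):
        if not any(v > 0 for v in values):
            values = values + [1.0]
        s = self.scores_for(values)
        assert ((s > 0) & (s <= 1)).all()
        # non-decreasing in expression: brute-force pairwise check
        expressed = {f"f{i}": v for i, v in enumerate(values) if v > 0}
        for a, va in expressed.items():
            for b, vb in expressed.items():
                if va <= vb:
                    assert s[a] <= s[b]

    def test_raising_expression_never_lowers_score(self):
        base = [1.0, 4.0, 2.0, 8.0]
        s0 = self.scores_for(base)
        bumped = list(base)
        bumped[2] = 5.0
        s1 = self.scores_for(bumped)
        assert s1["f2"] >= s0["f2"]


def table_from(scores: dict[tuple[str, str], float]) -> TissueScoreTable:
    rows = [(f, t, v) for (f, t), v in scores.items()]
    return TissueScoreTable(scores=pd.DataFrame(rows, columns=["feature_id", "tissue_id", "score"]))


class TestCoexpression:
    def test_no_shared_tissue_scores_zero(self):
        circ = table_from({("c", "tA"): 0.9})
        mir = table_from({("m", "tB"): 0.8})
        table = coexpression_score(circ, mir)
        assert table.edges.S_exp.iloc[0] == 0.0

    def test_min_within_tissue(self):
        circ = table_from({("c", "tA"): 0.9})
        mir = table_from({("m", "tA"): 0.4})
        assert coexpression_score(circ, mir).edges.S_exp.iloc[0] == pytest.approx(0.4)

    def test_max_of_mins_across_tissues(self):
        circ = table_from({("c", "tA"): 0.9, ("c", "tB"): 0.6})
        mir = table_from({("m", "tA"): 0.4, ("m", "tB"): 0.5})
        assert coexpression_score(circ, mir).edges.S_exp.iloc[0] == pytest.approx(0.5)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(7)
        circ = table_from({(f"c{i}", f"t{j}"): rng.uniform(0.1, 1)
                           for i in range(3) for j in range(3) if rng.random() > 0.3})
        mir = table_from({(f"m{i}", f"t{j}"): rng.uniform(0.1, 1)
                          for i in range(4) for j in range(3) if rng.random() > 0.3})
        ab = coexpression_score(circ, mir).edges
        ba = coexpression_score(mir, circ).edges
        lut = {(r.target_id, r.source_id): r.S_exp for r in ba.itertuples()}
        for r in ab.itertuples():
            assert lut[(r.source_id, r.target_id)] == pytest.approx(r.S_exp)

    def test_score_one_iff_shared_tied_maximum(self, small_bundle):
        from ceranet.expression import tissue_ecdf_scores

        circ_t = tissue_ecdf_scores(small_bundle.circ_expression)
        mir_t = tissue_ecdf_scores(small_bundle.mir_expression)
        edges = coexpression_score(circ_t, mir_t).edges
        cmat, mmat = circ_t.pivot(), mir_t.pivot()
        tissues = [t for t in cmat.columns if t in mmat.columns]
        for r in edges.itertuples():
            both_max = any(
                cmat.loc[r.source_id, t] == 1.0 and mmat.loc[r.target_id, t] == 1.0
                for t in tissues
            )
            assert (r.S_exp == 1.0) == both_max
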