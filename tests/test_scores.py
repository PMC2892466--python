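import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from bimodalgene.exceptions import (
    DegenerateInputError,
    EmptyInputError,
    InsufficientDataError,
)
from bimodalgene.scores import (
    MAD_SCALE,
    RANK_COLUMNS,
    SCORE_COLUMNS,
    bimodality_index,
    grouping_from_outliers,
    kurtosis,
    likelihood_ratio,
    outlier_sum,
    score_all,
    vrs,
    wvrs,
)


class TestVrs:
    def test_perfect_split(self):
        assert vrs([0, 0, 10, 10]) == 0.0

    def test_simple_example(self):
        assert vrs([1, 2, 3, 4]) == pytest.approx(0.2)

    def test_uniform_grid_limit(self):
        # splitting a uniform in half leaves each half a quarter of the variance
        assert vrs(np.linspace(0, 1, 2001)) == pytest.approx(0.25, abs=0.005)

    def test_bounds(self, rng):
        for _ in range(20):
            v = vrs(rng.normal(size=30))
            assert 0.0 <= v <= 1.0


class TestWvrs:
    def test_simple_example(self):
        assert wvrs([1, 2, 3, 4]) == pytest.approx(0.3)

    def test_singleton_cluster_scores_zero(self):
        assert wvrs([0, 0, 0, 100]) == 0.0
        assert wvrs([0, 0, 10, 10]) == 0.0

    def test_can_exceed_one(self):
        # a tiny cluster with large internal variance dominates the average
        x = np.concatenate([np.zeros(50), [50.0, 80.0]])
        assert wvrs(x) > 1.0


class TestKurtosis:
    def test_gaussian_calibration(self):
        r = np.random.default_rng(0)
        means = [kurtosis(r.normal(size=5000)) for _ in range(200)]
        assert abs(np.mean(means)) < 0.05

    def test_symmetric_two_point_limit(self):
        x = np.tile([-1.0, 1.0], 10000)
        assert kurtosis(x) == pytest.approx(-2.0, abs=0.01)

    def test_single_outlier_positive(self):
        x = np.concatenate([np.random.default_rng(1).normal(size=199), [50.0]])
        assert kurtosis(x) > 0

    def test_matches_scipy_unbiased_estimator(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(5, 200))
            assert kurtosis(x) == pytest.approx(
                st.kurtosis(x, fisher=True, bias=False), abs=1e-12
            )

    def test_minimum_size(self):
        with pytest.raises(InsufficientDataError):
            kurtosis([1.0, 2.0, 3.0])


class TestLikelihoodRatio:
    def test_null_calibration(self):
        r = np.random.default_rng(0)
        lrs = np.array([likelihood_ratio(r.normal(size=200)) for _ in range(40)])
        assert np.all(lrs >= -1e-9)
        assert np.median(lrs) < 3
        assert np.max(lrs) < 15

    def test_separated_mixture_is_huge(self):
        r = np.random.default_rng(2)
        x = np.concatenate([r.normal(0, 1, 100), r.normal(6, 1, 100)])
        assert likelihood_ratio(x) > 50


class TestBimodalityIndex:
    def test_cutoff_algebra(self):
        # pi = 0.5, delta = 2.2 gives BI = sqrt(0.25) * 2.2 = 1.1
        r = np.random.default_rng(3)
        member = r.random(50000) < 0.5
        x = r.normal(0, 1, 50000) + 2.2 * member
        assert bimodality_index(x) == pytest.approx(1.1, abs=0.05)

    def test_plugin_estimate(self):
        r = np.random.default_rng(1)
        vals = []
        for _ in range(10):
            member = r.random(500) < 0.3
            vals.append(bimodality_index(r.normal(0, 1, 500) + 3 * member))
        target = np.sqrt(0.3 * 0.7) * 3  # ~1.374
        assert np.mean(vals) == pytest.approx(target, abs=0.15)

    def test_nonnegative(self, rng):
        for _ in range(10):
            assert bimodality_index(rng.normal(size=40)) >= 0


class TestOutlierSum:
    def test_tight_sample_has_no_outliers(self):
        res = outlier_sum([1, 2, 3, 4, 5])
        assert res.statistic == 0.0
        assert not res.outlier_mask.any()

    def test_single_extreme_value(self):
        res = outlier_sum([1, 2, 3, 4, 5, 100])
        z100 = (100 - 3.5) / (1.5 * MAD_SCALE)
        assert res.statistic == pytest.approx(z100)
        assert res.side == "positive"
        assert res.outlier_mask.sum() == 1
        assert res.outlier_mask[-1]

    def test_mirror_symmetry(self, rng):
        x = np.concatenate([rng.normal(size=30), [9.0, 11.0]])
        pos = outlier_sum(x)
        neg = outlier_sum(-x)
        assert abs(pos.statistic) == pytest.approx(abs(neg.statistic))
        assert {pos.side, neg.side} == {"positive", "negative"}

    def test_statistic_is_sum_over_mask(self, rng):
        for _ in range(20):
            x = rng.standard_t(2, size=50)
            res = outlier_sum(x)
            if res.side == "positive":
                assert res.statistic == pytest.approx(
                    res.standardized[res.outlier_mask].sum()
                )
            assert (res.statistic == 0.0) == (not res.outlier_mask.any())

    def test_mad_zero_falls_back_then_raises(self):
        # MAD is 0 but the mean absolute deviation is not: still works
        res = outlier_sum([0, 0, 0, 0, 0, 7.0])
        assert res.outlier_mask.sum() == 1
        with pytest.raises(DegenerateInputError):
            outlier_sum([1, 1, 1, 1])

    def test_literal_fence_variant_differs_on_low_outliers(self):
        # the conventions agree on the high fence (q75 + IQR = IQR + q75) but
        # the literal low fence IQR - q25 is positive, flagging a different set
        x = np.concatenate([np.random.default_rng(0).normal(size=40), [-8.0]])
        std = outlier_sum(x, fence="standard")
        lit = outlier_sum(x, fence="literal")
        assert std.outlier_mask.sum() != lit.outlier_mask.sum()


class TestGroupingFromOutliers:
    def test_outlier_group_sizes(self):
        g = grouping_from_outliers(outlier_sum([1, 2, 3, 4, 5, 100]))
        assert g.sizes == (5, 1)

    def test_no_outliers_single_group(self):
        g = grouping_from_outliers(outlier_sum([1, 2, 3, 4, 5]))
        assert g.degenerate
        assert g.sizes[0] == 5

    def test_negative_side_outliers_are_low_group(self):
        g = grouping_from_outliers(outlier_sum([-100, 1, 2, 3, 4, 5]))
        assert g.sizes == (1, 5)
        assert g.labels[0] == 1


class TestInvariances:
    @pytest.mark.parametrize("score", [vrs, wvrs, kurtosis, bimodality_index,
                                       lambda x: outlier_sum(x).score])
    def test_shift_and_scale_invariance(self, score, rng):
        x = np.concatenate([rng.normal(0, 1, 40), rng.normal(5, 1, 20)])
        base = score(x)
        assert score(x + 7.0) == pytest.approx(base, rel=1e-6, abs=1e-8)
        assert score(2.5 * x) == pytest.approx(base, rel=1e-6, abs=1e-8)

    def test_log_lr_shift_invariance(self, rng):
        x = np.concatenate([rng.normal(0, 1, 40), rng.normal(5, 1, 20)])
        base = likelihood_ratio(x)
        assert likelihood_ratio(x + 3.0) == pytest.approx(base, rel=1e-3, abs=0.05)


class TestScoreAll:
    def test_planted_balanced_genes_rank_top_by_bi(self):
        from bimodalgene.synthetic import CohortSpec, simulate_expression

        spec = CohortSpec(n_genes=500, n_samples=150, frac_balanced=0.05,
                          frac_unbalanced=0.0, frac_outlier=0.0, frac_heavy=0.0,
                          n_prognostic=0, seed=9)
        matrix, truth = simulate_expression(spec)
        table = score_all(matrix)
        planted = truth.gene_class[truth.gene_class == "balanced_bimodal"].index
        assert table.loc[planted, "rank_bi"].median() <= 50

    def test_constant_gene_gets_missing_scores_and_worst_rank(self, small_cohort):
        _, matrix, _, _ = small_cohort
        mat = matrix.iloc[:30].copy()
        mat.iloc[0] = 5.0
        table = score_all(mat)
        assert table.iloc[0][SCORE_COLUMNS].isna().all()
        for rank_col in RANK_COLUMNS:
            assert table.iloc[0][rank_col] == mat.shape[0]

    def test_single_gene_matrix(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 8.0]], index=["g"],
                           columns=list("abcde"))
        table = score_all(mat)
        assert table.shape[0] == 1
        assert all(table.iloc[0][rc] == 1 for rc in RANK_COLUMNS)

    def test_empty_matrix_raises(self):
        with pytest.raises(EmptyInputError):
            score_all(pd.DataFrame())

    def test_ranks_are_permutations(self, small_cohort):
        _, matrix, _, _ = small_cohort
        table = score_all(matrix.iloc[:80])
        for rank_col in RANK_COLUMNS:
            assert sorted(table[rank_col]) == list(range(1, 81))

    def test_shape_to_score_mapping(self, small_cohort):
        """Planted shapes surface on their matching ranked lists (AUC > 0.9)."""
        from sklearn.metrics import roc_auc_score

        _, matrix, _, truth = small_cohort
        table = score_all(matrix)
        cls = truth.gene_class
        null = cls == "unimodal"

        def auc(rank_col, planted_mask):
            keep = planted_mask | null
            # small ranks = stronger: invert so AUC > 0.5 means planted on top
            return roc_auc_score(planted_mask[keep], -table.loc[keep, rank_col])

        balanced = cls == "balanced_bimodal"
        outlier = cls == "single_outlier"
        for rank_col in ("rank_dip", "rank_kurtosis_neg", "rank_bi"):
            assert auc(rank_col, balanced) > 0.9, rank_col
        for rank_col in ("rank_wvrs", "rank_kurtosis_pos", "rank_outlier_sum", "rank_log_lr"):
            assert auc(rank_col, outlier) > 0.9, rank_col

    def test_outlier_sum_among_log_lr_closest_partners(self):
        # the log LR and the outlier sum are both driven by tail weight, so in
        # a genome with heavy-tailed and outlier genes the outlier sum sits
        # among the closest rank-correlation partners of the log LR
        from bimodalgene.synthetic import CohortSpec, simulate_expression

        spec = CohortSpec(n_genes=600, n_samples=150, frac_balanced=0.02,
                          frac_unbalanced=0.02, frac_outlier=0.1, frac_heavy=0.1,
                          n_prognostic=0, seed=31)
        matrix, _ = simulate_expression(spec)
        table = score_all(matrix)
        sp = table[SCORE_COLUMNS].corr(method="spearman")
        partners = sp["log_lr"].drop("log_lr").abs().sort_values(ascending=False)
        assert "outlier_sum" in partners.index[:2]
        assert partners["outlier_sum"] > 0.3
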