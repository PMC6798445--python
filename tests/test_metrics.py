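import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from netimpute import (
    ExpressionMatrix,
    ValidationError,
    adjusted_mutual_information,
    adjusted_rand,
    de_auc,
    de_calling_table,
    distribution_compare,
    fowlkes_mallows,
    gapdh_normalize,
    gini,
    gini_agreement,
    silhouette,
    truth_de_labels,
)
from _oracles import ami_direct, ari_pairs, bh_stepup, fmi_pairs, gini_pairwise, ks_scan


def _series(labels):
    return pd.Series(list(labels), index=[f"c{i}" for i in range(len(labels))])


class TestClusteringAgreement:
    def test_identical_partitions_score_one(self):
        a = _series("AABBBCC")
        assert adjusted_rand(a, a) == pytest.approx(1.0)
        assert adjusted_mutual_information(a, a) == pytest.approx(1.0)
        assert fowlkes_mallows(a, a) == pytest.approx(1.0)

    def test_singletons_vs_one_cluster_not_rewarded(self):
        a = _series("ABCDEF")
        b = _series("XXXXXX")
        assert adjusted_rand(a, b) <= 0.0 + 1e-12

    def test_mismatched_cell_sets_rejected(self):
        a = _series("AB")
        b = pd.Series(["A", "B"], index=["c0", "zz"])
        with pytest.raises(ValidationError):
            adjusted_rand(a, b)

    @settings(deadline=None, max_examples=120)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_match_pair_counting_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        a = [int(x) for x in rng.integers(0, 3, size=n)]
        b = [int(x) for x in rng.integers(0, 3, size=n)]
        sa, sb = _series(a), _series(b)
        assert adjusted_rand(sa, sb) == pytest.approx(ari_pairs(a, b), abs=1e-10)
        assert fowlkes_mallows(sa, sb) == pytest.approx(fmi_pairs(a, b), abs=1e-10)
        assert adjusted_mutual_information(sa, sb) == pytest.approx(
            ami_direct(a, b), abs=1e-8
        )

    def test_ami_near_zero_for_independent_labels(self):
        values = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = _series(rng.integers(0, 5, size=2000))
            b = _series(rng.integers(0, 5, size=2000))
            values.append(adjusted_mutual_information(a, b))
        assert abs(np.mean(values)) < 0.05


class TestSilhouette:
    def test_separated_blobs_score_high(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(20, 0.1, (30, 2))])
        labels = _series([0] * 30 + [1] * 30)
        assert silhouette(X, labels) > 0.9

    def test_random_labels_on_one_blob_near_zero(self, rng):
        X = rng.normal(0, 1.0, (200, 2))
        labels = _series(rng.integers(0, 2, size=200))
        assert abs(silhouette(X, labels)) < 0.1

    def test_four_point_hand_example(self):
        # two pairs on a line: (0), (1) in A and (10), (11) in B
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = _series([0, 0, 1, 1])
        # per point: a=1, b=mean(10,11)=10.5 -> (10.5-1)/10.5, symmetric for all
        by_hand = np.mean(
            [(10.5 - 1) / 10.5, (9.5 - 1) / 9.5, (9.5 - 1) / 9.5, (10.5 - 1) / 10.5]
        )
        assert silhouette(X, labels) == pytest.approx(by_hand)

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValidationError):
            silhouette(rng.random((5, 2)), _series([1] * 5))


class TestBhAdjustment:
    def test_printed_example(self):
        assert bh_stepup([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @settings(deadline=None, max_examples=100)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_statsmodels_matches_stepup_oracle(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 11)))
        adj = multipletests(p, method="fdr_bh")[1]
        assert adj == pytest.approx(np.array(bh_stepup(p)), abs=1e-12)


class TestDeAuc:
    def test_truth_fed_as_scores_gives_one(self, small_sim):
        matrix, truth = small_sim
        is_de = truth_de_labels(truth)
        # degenerate upper bound: score the genes by their own truth
        auc = roc_auc_score(is_de.to_numpy(), is_de.to_numpy().astype(float))
        assert auc == 1.0

    def test_recovers_de_genes_on_simulation(self, small_sim):
        matrix, truth = small_sim
        auc = de_auc(matrix, truth.group_labels, truth, top_n=50)
        assert auc > 0.7

    def test_calling_table_one_record_per_group_gene(self, small_sim):
        matrix, truth = small_sim
        table = de_calling_table(matrix, truth.group_labels, top_n=50)
        assert set(table.columns) == {"group", "gene", "padj", "calling_prob"}
        assert table["calling_prob"].between(0, 1).all()
        assert (table.groupby("group").size() <= 50).all()
        assert not table.duplicated(["group", "gene"]).any()

    def test_per_gene_truth_pools_unique_genes_with_max_probability(self, small_sim):
        from netimpute import truth_de_labels

        matrix, truth = small_sim
        table = de_calling_table(matrix, truth.group_labels, top_n=50)
        per_gene = table.groupby("gene")["calling_prob"].max()
        is_de = truth_de_labels(truth)
        if is_de[per_gene.index].nunique() == 2:
            auc = de_auc(matrix, truth.group_labels, is_de, top_n=50)
            assert 0.0 <= auc <= 1.0

    def test_shuffled_truth_gives_half(self, small_sim):
        matrix, truth = small_sim
        table = de_calling_table(matrix, truth.group_labels, top_n=50)
        scores = table["calling_prob"].to_numpy()
        aucs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            y = rng.permutation(np.arange(len(scores)) < len(scores) // 2)
            aucs.append(roc_auc_score(y, scores))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_tiny_group_rejected(self, small_sim):
        matrix, truth = small_sim
        groups = truth.group_labels.copy()
        groups.iloc[:] = "big"
        groups.iloc[0] = "solo"
        with pytest.raises(ValidationError):
            de_auc(matrix, groups, truth)


class TestGapdhNormalize:
    def _matrix_with_housekeeping(self, hk_values, rng):
        n = len(hk_values)
        values = np.column_stack([np.asarray(hk_values, float), rng.poisson(5, n) + 1.0])
        return ExpressionMatrix(values, gene_ids=["GAPDH", "other"])

    def test_percentile_trim_retains_80_of_100(self, rng):
        m = self._matrix_with_housekeeping(np.arange(1.0, 101.0), rng)
        out = gapdh_normalize(m, "GAPDH")
        assert out.n_cells == 80

    def test_housekeeping_equalised_to_retained_mean(self, rng):
        m = self._matrix_with_housekeeping(rng.uniform(1, 10, 50), rng)
        out = gapdh_normalize(m, "GAPDH")
        hk = out.values[:, 0]
        np.testing.assert_allclose(hk, hk.mean(), rtol=1e-12)

    def test_constant_housekeeping_changes_nothing(self, rng):
        m = self._matrix_with_housekeeping(np.full(30, 4.0), rng)
        out = gapdh_normalize(m, "GAPDH")
        assert out.n_cells == 30
        np.testing.assert_array_equal(out.values, m.values)

    def test_absent_gene_rejected(self, rng):
        m = self._matrix_with_housekeeping(np.full(10, 4.0), rng)
        with pytest.raises(ValidationError):
            gapdh_normalize(m, "ACTB")


class TestGini:
    def test_all_equal_is_zero(self):
        assert gini(np.full(9, 3.0)) == pytest.approx(0.0)

    def test_single_holder_example(self):
        assert gini(np.array([1.0, 0.0, 0.0, 0.0])) == pytest.approx(0.75)

    def test_scale_invariance(self, rng):
        x = rng.random(20)
        assert gini(x * 7.3) == pytest.approx(gini(x))

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            gini(np.zeros(5))

    @settings(deadline=None, max_examples=100)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(int(rng.integers(1, 11))) * 10
        assert gini(x) == pytest.approx(gini_pairwise(x), abs=1e-10)

    def test_pigou_dalton_transfer_increases_gini(self, rng):
        # moving mass from a poorer to a richer coordinate raises inequality
        for _ in range(20):
            x = rng.random(6) + 0.5
            lo, hi = np.argmin(x), np.argmax(x)
            if lo == hi:
                continue
            y = x.copy()
            delta = x[lo] * 0.5
            y[lo] -= delta
            y[hi] += delta
            assert gini(y) > gini(x)


class TestDistributionCompare:
    def test_identical_distributions(self, rng):
        v = rng.poisson(8, 100).astype(float) + 1.0
        comp = distribution_compare({"g": v}, {"g": v.copy()})
        assert comp.ks_statistic["g"] == 0.0
        assert comp.corr["g"] == pytest.approx(1.0)
        assert comp.mse["g"] == pytest.approx(0.0)
        assert comp.efficiency_factors["g"] == pytest.approx(1.0)

    def test_efficiency_rescaling_matches_means(self, rng):
        ref = rng.poisson(10, 80).astype(float) + 1.0
        met = ref * 0.25
        comp = distribution_compare({"g": ref}, {"g": met})
        assert comp.efficiency_factors["g"] == pytest.approx(4.0)
        assert comp.ks_statistic["g"] == 0.0  # rescaled copy is identical

    def test_ks_matches_ecdf_scan_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, int(rng.integers(5, 11)))
            b = rng.normal(0.8, 1, int(rng.integers(5, 11)))
            comp = distribution_compare(
                {"g": a - a.min() + 0.1}, {"g": b - b.min() + 0.1}
            )
            ref = a - a.min() + 0.1
            met = b - b.min() + 0.1
            met = met * (ref.mean() / met.mean())
            assert comp.ks_statistic["g"] == pytest.approx(ks_scan(ref, met), abs=1e-12)

    def test_zero_mean_method_gene_skipped(self, rng):
        comp = distribution_compare(
            {"g": rng.random(10) + 1}, {"g": np.zeros(10)}
        )
        assert comp.skipped == ["g"]
        assert "g" not in comp.ks_statistic.index

    def test_gini_agreement_on_matching_distributions(self, rng):
        ref = {f"g{i}": rng.gamma(2.0 + i, 1.0, 200) for i in range(5)}
        comp = distribution_compare(ref, {k: v.copy() for k, v in ref.items()})
        corr, mse = gini_agreement(comp)
        assert corr == pytest.approx(1.0)
        assert mse == pytest.approx(0.0, abs=1e-12)
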