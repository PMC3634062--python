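import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from crossatlas import (ExpressionError, SyntheticConfig, collapse_replicates,
                        cluster_tissues, cross_platform_correlations,
                        generate_truth, pca_tissues, replicate_correlations,
                        simulate_microarray, top_expressed_genes)
from crossatlas.transforms import transform_log2_floor

from conftest import make_matrix


def pearson(x, y):
    """Direct textbook formula, the independent oracle for correlations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())


class TestReplicateCorrelations:
    def test_identical_replicates_give_unit_correlation(self):
        rng = np.random.default_rng(0)
        col = rng.lognormal(1, 1, 20)
        m = make_matrix(np.column_stack([col, col, col]), replicates=3)
        rep = replicate_correlations(m)
        assert rep.mean_r == pytest.approx(1.0)
        assert rep.fraction_above[0.95] == 1.0

    def test_sign_flipped_deviations_give_minus_one(self):
        base = np.array([4.0, 8.0, 16.0, 32.0])
        logb = np.log2(base)
        flipped = 2 ** (logb.mean() - (logb - logb.mean()))
        m = make_matrix(np.column_stack([base, flipped]), replicates=2)
        rep = replicate_correlations(m)
        assert rep.mean_r == pytest.approx(-1.0)

    def test_pairwise_values_match_direct_formula(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(2, 1, (4, 3))
        m = make_matrix(vals, replicates=3)
        rep = replicate_correlations(m)
        logged = np.log2(np.clip(vals, 1, None))
        assert len(rep.pairwise) == 3
        for _, row in rep.pairwise.iterrows():
            want = pearson(logged[:, row.rep_i - 1], logged[:, row.rep_j - 1])
            assert row.r == pytest.approx(want)


class TestCrossPlatformCorrelations:
    def test_scaled_copy_gives_unit_correlation(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(2, 1, (10, 3))
        a = make_matrix(vals, units="log2")
        b = make_matrix(2 * vals, platform="microarray", units="log2")
        rep = cross_platform_correlations(a, b)
        assert np.allclose(rep.per_tissue_r, 1.0)

    def test_independent_noise_correlation_near_zero(self):
        rng = np.random.default_rng(3)
        n = 2000
        a = make_matrix(rng.normal(0, 1, (n, 2)), units="log2")
        b = make_matrix(rng.normal(0, 1, (n, 2)), platform="microarray",
                        units="log2")
        rep = cross_platform_correlations(a, b)
        assert np.abs(rep.per_tissue_r).max() < 3 / np.sqrt(n)

    def test_toy_table_matches_direct_formula(self):
        va = np.array([[1.0], [4.0], [16.0], [64.0]])
        vb = np.array([[2.0], [3.0], [50.0], [40.0]])
        a = make_matrix(va)
        b = make_matrix(vb, platform="microarray")
        rep = cross_platform_correlations(a, b)
        want = pearson(np.log2(va[:, 0]), np.log2(vb[:, 0]))
        assert rep.per_tissue_r.iloc[0] == pytest.approx(want)

    def test_too_few_genes_rejected(self):
        a = make_matrix([[1.0], [2.0]])
        b = make_matrix([[1.0], [2.0]], platform="microarray")
        with pytest.raises(ExpressionError):
            cross_platform_correlations(a, b)


class TestClusterTissues:
    def test_identical_tissues_merge_first_at_zero(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        z = rng.normal(0, 1, 30)
        m = make_matrix(np.column_stack([x, x, y, z]), units="log2",
                        tissues=["t1", "t2", "t3", "t4"])
        dend = cluster_tissues(m)
        left, right, h = dend.merges[0]
        assert {left[0], right[0]} == {"t1", "t2"}
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_three_leaf_hand_agglomeration(self):
        # build columns with pairwise correlation distances ~ {0.1, 0.4, 0.5};
        # complete linkage: first merge at the minimum, final height at the
        # maximum of the cross distances
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 500)
        def with_target_r(r):
            noise = rng.normal(0, 1, 500)
            v = r * base + np.sqrt(1 - r * r) * noise
            return v
        a = base
        b = with_target_r(0.9)
        c = rng.normal(0, 1, 500)
        m = make_matrix(np.column_stack([a, b, c]), units="log2",
                        tissues=["a", "b", "c"])
        dend = cluster_tissues(m)
        (l1, r1, h1), (l2, r2, h2) = dend.merges
        assert {l1[0], r1[0]} == {"a", "b"}
        D = 1 - np.corrcoef(m.values.to_numpy().T)
        assert h1 == pytest.approx(D[0, 1])
        assert h2 == pytest.approx(max(D[0, 2], D[1, 2]))

    def test_matches_scipy_complete_linkage_heights(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 1, (40, 6))
        m = make_matrix(vals, units="log2")
        dend = cluster_tissues(m)
        D = 1 - np.corrcoef(vals.T)
        np.fill_diagonal(D, 0.0)
        Z = hierarchy.linkage(squareform(D, checks=False), method="complete")
        np.testing.assert_allclose(sorted(dend.heights), sorted(Z[:, 2]),
                                   atol=1e-12)

    def test_recovers_synthetic_tissue_groups(self):
        groups = (tuple(range(9)), tuple(range(9, 18)))
        cfg = SyntheticConfig(seed=21, n_genes=200, n_modules=10,
                              module_size_range=(20, 20), tissue_groups=groups,
                              noise_sd=0.0, frac_saturated=0,
                              frac_low_expressed=0, paralog_fraction=0)
        truth = generate_truth(cfg)
        m = transform_log2_floor(collapse_replicates(simulate_microarray(truth, cfg)))
        cut = cluster_tissues(m).cut(2)
        want = {frozenset(truth.tissue_ids[i] for i in g) for g in groups}
        assert set(cut) == want

    def test_constant_tissue_column_rejected(self):
        m = make_matrix([[1.0, 1.0], [2.0, 1.0]], units="log2",
                        tissues=["ok", "flat"])
        with pytest.raises(ExpressionError, match="flat"):
            cluster_tissues(m)

    def test_newick_output_parses(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.normal(0, 1, (30, 4)), units="log2")
        nwk = cluster_tissues(m).to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 3


class TestPcaTissues:
    def test_duplicate_tissue_columns_coincide(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, (50, 3))
        vals = np.column_stack([x, x[:, 0]])
        m = make_matrix(vals, units="log2", tissues=["a", "b", "c", "a2"])
        ordn = pca_tissues(m, k=10, seed=0)
        np.testing.assert_allclose(ordn.coordinates.loc["a"],
                                   ordn.coordinates.loc["a2"], atol=1e-8)

    def test_explained_variance_sorted_and_sums_to_one(self):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.normal(0, 1, (80, 6)), units="log2")
        ordn = pca_tissues(m, k=20, seed=0)
        ev = ordn.explained_variance_ratio
        assert np.all(np.diff(ev) <= 1e-12)
        assert ev.sum() == pytest.approx(1.0, abs=1e-9)

    def test_k_reduced_with_warning(self):
        rng = np.random.default_rng(10)
        m = make_matrix(rng.normal(0, 1, (5, 4)), units="log2")
        with pytest.warns(UserWarning):
            ordn = pca_tissues(m, k=50, seed=0)
        assert ordn.k_used == 5

    def test_pc1_separates_synthetic_groups(self):
        groups = (tuple(range(9)), tuple(range(9, 18)))
        cfg = SyntheticConfig(seed=22, n_genes=200, n_modules=10,
                              module_size_range=(20, 20), tissue_groups=groups,
                              noise_sd=0.0, frac_saturated=0,
                              frac_low_expressed=0, paralog_fraction=0)
        truth = generate_truth(cfg)
        m = transform_log2_floor(collapse_replicates(simulate_microarray(truth, cfg)))
        ordn = pca_tissues(m, k=50, seed=0)
        pc1 = ordn.coordinates["PC1"]
        a = pc1[[truth.tissue_ids[i] for i in groups[0]]]
        b = pc1[[truth.tissue_ids[i] for i in groups[1]]]
        assert a.max() < b.min() or b.max() < a.min()


class TestTopExpressedGenes:
    def test_argmax_for_n_equal_one(self):
        m = make_matrix([[1.0], [9.0], [3.0]], genes=["a", "b", "c"])
        top = top_expressed_genes(m, n=1)
        assert top.gene.tolist() == ["b"]

    def test_ties_broken_by_gene_id(self):
        m = make_matrix([[5.0], [5.0], [1.0]], genes=["zed", "abc", "mid"])
        top = top_expressed_genes(m, n=2)
        assert top.gene.tolist() == ["abc", "zed"]

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(11)
        vals = rng.integers(0, 5, (5, 2)).astype(float)
        m = make_matrix(vals)
        top = top_expressed_genes(m, n=5)
        for tissue in m.tissue_ids:
            got = top[top.tissue == tissue].gene.tolist()
            want = [g for g, _ in sorted(
                zip(m.gene_ids, m.values[tissue]),
                key=lambda kv: (-kv[1], kv[0]))]
            assert got == want

    def test_oversized_n_warns(self):
        m = make_matrix([[1.0]], genes=["a"])
        with pytest.warns(UserWarning):
            top = top_expressed_genes(m, n=10)
        assert len(top) == 1
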