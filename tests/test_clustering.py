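"""Correlation features, k-means recovery, binomial marker test, t-SNE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from scgpcr.clustering import (AUTO, ClusterParams, binomial_two_sided_p,
                               cluster_marker_genes, correlation_features,
                               kmeans_cluster, normalize_cells, tsne_embed)
from scgpcr.expression import ExpressionMatrix, lod_transform
from scgpcr.simulate import default_panel, simulate_clustered


def _expr(vals):
    arr = np.asarray(vals, dtype=float)
    return ExpressionMatrix(pd.DataFrame(
        arr, index=[f"c{i}" for i in range(arr.shape[0])],
        columns=[f"g{j}" for j in range(arr.shape[1])]))


@pytest.fixture(scope="module")
def planted():
    """Two well-separated subpopulations with known membership."""
    m, truth = simulate_clustered(sizes=(40, 40), n_diff=25, seed=21)
    e = lod_transform(m).subset_genes(default_panel().gpcrs())
    return e, truth


class TestNormalizeCells:
    def test_common_total_is_median(self):
        e = _expr([[60.0, 40.0], [150.0, 50.0]])
        norm = normalize_cells(e)
        totals = norm.values.sum(axis=1)
        assert np.allclose(totals, 150.0)  # median of {100, 200}

    def test_identity_when_totals_equal(self):
        e = _expr([[2.0, 3.0], [1.0, 4.0]])
        norm = normalize_cells(e)
        pd.testing.assert_frame_equal(norm.values, e.values)

    def test_all_zero_cell_dropped(self, caplog):
        import logging
        e = _expr([[1.0, 1.0], [0.0, 0.0], [2.0, 2.0]])
        with caplog.at_level(logging.WARNING, logger="scgpcr.clustering"):
            norm = normalize_cells(e)
        assert norm.n_cells == 2
        assert "all-zero" in caplog.text

    def test_zeros_preserved(self):
        e = _expr([[0.0, 10.0], [5.0, 5.0], [0.0, 30.0]])
        norm = normalize_cells(e)
        assert (norm.values.to_numpy() == 0).sum() == 2


class TestCorrelationFeatures:
    def test_duplicated_cell_correlation_one(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 100, 10)
        e = _expr([base, base, rng.uniform(0, 100, 10)])
        feats = correlation_features(e)
        assert feats.iloc[0, 1] == pytest.approx(1.0)

    def test_matches_bruteforce_pearson(self):
        """Feature matrix equals the definitional pairwise Pearson formula."""
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 50, size=(10, 12))
        e = _expr(vals)
        feats = correlation_features(e, log=False)
        x = vals
        n = x.shape[1]
        for i in range(10):
            for j in range(10):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                sx = x[i].std(ddof=1)
                sy = x[j].std(ddof=1)
                expected = (xi * xj).sum() / (sx * sy * (n - 1))
                assert feats.iloc[i, j] == pytest.approx(expected, abs=1e-10)

    def test_constant_profile_zeroed(self, caplog):
        import logging
        vals = np.vstack([np.full(6, 3.0), np.arange(6.0), np.arange(6.0)[::-1]])
        with caplog.at_level(logging.WARNING, logger="scgpcr.clustering"):
            feats = correlation_features(_expr(vals), log=False)
        assert feats.iloc[0, 1] == 0.0
        assert feats.iloc[0, 0] == 1.0

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            correlation_features(_expr([[1, 2], [3, 4]]))


class TestKMeans:
    def test_planted_two_populations_recovered(self, planted):
        e, truth = planted
        feats = correlation_features(e)
        res = kmeans_cluster(feats, ClusterParams(k=2, seed=4))
        ari = adjusted_rand_score(truth.cell_labels.values, res.labels.values)
        assert ari >= 0.95

    def test_determinism(self, planted):
        e, _ = planted
        feats = correlation_features(e)
        a = kmeans_cluster(feats, ClusterParams(k=3, seed=9))
        b = kmeans_cluster(feats, ClusterParams(k=3, seed=9))
        assert a.labels.equals(b.labels)

    def test_identical_cells_degenerate(self, caplog):
        import logging
        e = _expr(np.ones((6, 5)))
        feats = correlation_features(e)
        with caplog.at_level(logging.WARNING, logger="scgpcr.clustering"):
            res = kmeans_cluster(feats, ClusterParams(k=AUTO, seed=0))
        assert res.degenerate
        assert set(res.labels) == {1}

    def test_auto_k_finds_planted_count(self, planted):
        e, truth = planted
        feats = correlation_features(e)
        res = kmeans_cluster(feats, ClusterParams(k=AUTO, k_max=6, seed=2))
        assert res.k == truth.cell_labels.nunique()

    def test_k_exceeding_cells_rejected(self):
        e = _expr(np.random.default_rng(0).uniform(size=(5, 4)))
        feats = correlation_features(e)
        with pytest.raises(ValueError):
            kmeans_cluster(feats, ClusterParams(k=7))

    def test_cell_order_permutation_invariance(self, planted):
        e, _ = planted
        rng = np.random.default_rng(8)
        perm = rng.permutation(e.values.index)
        e_perm = ExpressionMatrix(e.values.loc[perm], e.lod_ct)
        a = kmeans_cluster(correlation_features(e), ClusterParams(k=2, seed=3))
        b = kmeans_cluster(correlation_features(e_perm), ClusterParams(k=2, seed=3))
        joined = pd.concat([a.labels.rename("a"), b.labels.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == pytest.approx(1.0)


class TestBinomialMarkerTest:
    def test_small_instance_matches_enumeration(self):
        """p for (N=10, pi=0.2, n=6) equals exact pmf enumeration."""
        N, pi, n = 10, 0.2, 6
        pmf = np.array([stats.binom.pmf(k, N, pi) for k in range(N + 1)])
        lower = pmf[:n + 1].sum()
        upper = pmf[n:].sum()
        expected = min(1.0, 2.0 * min(lower, upper))
        assert binomial_two_sided_p(n, N, pi) == pytest.approx(expected, rel=1e-12)

    def test_enumeration_grid(self):
        """Exactness over all (N <= 12, n, pi) on a pi grid."""
        for N in range(1, 13):
            pmf_cache = {}
            for pi in (0.05, 0.2, 0.5, 0.8):
                pmf = np.array([stats.binom.pmf(k, N, pi) for k in range(N + 1)])
                for n in range(N + 1):
                    expected = min(1.0, 2.0 * min(pmf[:n + 1].sum(), pmf[n:].sum()))
                    assert binomial_two_sided_p(n, N, pi) == pytest.approx(
                        expected, rel=1e-10), (N, pi, n)

    def test_null_gene_near_one(self):
        rng = np.random.default_rng(12)
        vals = rng.poisson(20, size=(200, 10)).astype(float)
        e = _expr(vals)
        labels = pd.Series([1] * 100 + [2] * 100, index=e.values.index)
        mk = cluster_marker_genes(e, labels)
        null = mk[mk.gene == "g0"]
        assert (null.fold_change > 0.8).all() and (null.fold_change < 1.2).all()

    def test_planted_upregulated_gene_significant(self, planted):
        e, truth = planted
        labels = pd.Series(
            pd.factorize(truth.cell_labels)[0] + 1, index=e.values.index)
        mk = cluster_marker_genes(e, labels, ClusterParams(k=2))
        pop1_genes = truth.diff_genes["pop1"]
        cluster1 = int(labels[truth.cell_labels == "pop1"].iloc[0])
        sub = mk[(mk.cluster == cluster1) & mk.gene.isin(pop1_genes)]
        assert (sub.significant & (sub.fold_change > 1.5)).mean() >= 0.8

    def test_globally_undetected_gene_excluded(self):
        vals = np.ones((6, 3))
        vals[:, 2] = 0.0
        e = _expr(vals)
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=e.values.index)
        mk = cluster_marker_genes(e, labels)
        assert "g2" not in set(mk.gene)

    def test_fold_change_conservation(self):
        """Size-weighted cluster means average to the global mean."""
        rng = np.random.default_rng(7)
        e = _expr(rng.uniform(0, 30, size=(50, 6)))
        labels = pd.Series(rng.integers(1, 4, 50), index=e.values.index)
        mk = cluster_marker_genes(e, labels)
        sizes = labels.value_counts()
        for g in e.gene_ids:
            sub = mk[mk.gene == g].set_index("cluster")
            weighted = sum(sizes[c] * sub.loc[c, "mean_cluster"]
                           for c in sub.index) / sizes.sum()
            assert weighted == pytest.approx(sub["mean_all"].iloc[0], rel=1e-9)

    def test_null_calibration_small_cluster_share(self):
        """p<0.05 rate on Poisson nulls with random labels, 10,000 tests.

        Clusters are kept a small share of all cells so the finite-total
        conditioning does not dominate; the discrete two-sided test stays
        slightly conservative."""
        rng = np.random.default_rng(5)
        n_cells, n_clusters, n_genes = 400, 20, 500
        lam = np.exp(rng.uniform(np.log(2), np.log(100), n_genes))
        vals = rng.poisson(lam, size=(n_cells, n_genes)).astype(float)
        e = _expr(vals)
        labels = pd.Series(rng.permutation(np.repeat(np.arange(1, n_clusters + 1),
                                                     n_cells // n_clusters)),
                           index=e.values.index)
        mk = cluster_marker_genes(e, labels)
        assert len(mk) == 10_000
        rate = float((mk.p_value < 0.05).mean())
        assert 0.03 <= rate <= 0.07


class TestTsne:
    def test_planted_separation_positive_silhouette(self, planted):
        from sklearn.metrics import silhouette_score
        e, truth = planted
        feats = correlation_features(e)
        xy = tsne_embed(feats, ClusterParams(k=2, tsne_seed=1))
        score = silhouette_score(xy.to_numpy(), truth.cell_labels.values)
        assert score > 0

    def test_determinism(self, planted):
        e, _ = planted
        feats = correlation_features(e)
        a = tsne_embed(feats, ClusterParams(k=2, tsne_seed=5))
        b = tsne_embed(feats, ClusterParams(k=2, tsne_seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_minimal_input(self):
        e = _expr(np.random.default_rng(1).uniform(size=(4, 6)))
        feats = correlation_features(e)
        xy = tsne_embed(feats, ClusterParams(k=2, tsne_perplexity=1.0))
        assert xy.shape == (4, 2)

    def test_perplexity_bound(self):
        e = _expr(np.random.default_rng(1).uniform(size=(5, 6)))
        feats = correlation_features(e)
        with pytest.raises(ValueError):
            tsne_embed(feats, ClusterParams(k=2, tsne_perplexity=5.0))
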