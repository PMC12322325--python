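"""QC, normalization, HVGs, PCA, exact kNN, Louvain, annotation."""

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score, silhouette_score

from oligoscore.params import PipelineParams
from oligoscore.preprocess import (Embedding, KnnGraph, NormMatrix,
                                   PreprocessError, annotate_clusters,
                                   build_knn, cluster_louvain, normalize_log,
                                   qc_filter, qc_metrics, run_pca, select_hvgs)
from oligoscore.benchmarks import qc_fixture_10cells
from oligoscore.simulate import MAJOR_MARKERS

from conftest import make_counts, make_norm


# --------------------------------------------------------------------------
# QC


class TestQC:
    def test_planted_fixture_keeps_exactly_the_qualifying_cells(self):
        counts, kept_ids = qc_fixture_10cells()
        filtered, report = qc_filter(counts)
        assert list(filtered.cell_ids) == kept_ids
        assert report["n_kept"] == 6 and report["n_input"] == 10

    def test_zero_count_cell_removed(self):
        m = make_counts(np.column_stack([np.zeros(300), np.ones(300)]))
        filtered, _ = qc_filter(m)
        assert list(filtered.cell_ids) == ["c1"]

    def test_idempotent(self, query):
        counts, _, _, _ = query
        once, _ = qc_filter(counts)
        twice, _ = qc_filter(once)
        assert list(once.cell_ids) == list(twice.cell_ids)

    def test_all_removed_is_an_error(self):
        m = make_counts(np.ones((10, 3)))  # 10 detected genes < 200
        with pytest.raises(PreprocessError, match="every cell"):
            qc_filter(m)

    def test_zero_total_mito_fraction_defined_as_zero(self):
        m = make_counts(np.column_stack([np.zeros(20), np.ones(20)]),
                        gene_ids=["MT-ND1"] + [f"G{i}" for i in range(19)])
        qc = qc_metrics(m)
        assert qc.loc[0, "mito_frac"] == 0.0


# --------------------------------------------------------------------------
# Normalization


class TestNormalize:
    def test_stated_formula(self):
        # cell with 4 total counts, gene count 1, s = 10000 -> ln(1 + 2500)
        m = make_counts([[1], [3]])
        nm = normalize_log(m)
        assert np.isclose(nm.values[0, 0], np.log(1 + 2500.0))
        # zero count stays exactly zero
        m2 = make_counts([[0, 1], [4, 3]])
        assert normalize_log(m2).values[0, 0] == 0.0

    def test_scale_invariance_per_cell(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(2.0, size=(50, 4))
        base[0] += 1  # ensure nonzero libsize
        doubled = base.copy()
        doubled[:, 2] *= 2
        a = normalize_log(make_counts(base)).values.toarray()
        b = normalize_log(make_counts(doubled)).values.toarray()
        np.testing.assert_allclose(a[:, 2], b[:, 2], rtol=1e-12)

    def test_zero_libsize_rejected(self):
        m = make_counts([[0, 1], [0, 1]])
        with pytest.raises(PreprocessError, match="zero total"):
            normalize_log(m)

    def test_gene_reordering_equivariance(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(1.0, size=(30, 5)) + (np.arange(30) == 0)[:, None]
        m = make_counts(base)
        nm = normalize_log(m).values.toarray()
        perm = rng.permutation(30)
        m2 = make_counts(base[perm], gene_ids=[f"G{i}" for i in perm])
        nm2 = normalize_log(m2).values.toarray()
        np.testing.assert_allclose(nm2, nm[perm])


# --------------------------------------------------------------------------
# HVG selection


class TestHVGs:
    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(2)
        data = rng.normal(1.0, 0.5, size=(20, 100)).clip(0)
        data[0] = 1.0  # constant gene
        nm = make_norm(data)
        hv = select_hvgs(nm, 19)
        assert "G0" not in hv.genes

    def test_planted_bimodal_outranks_matched_unimodal(self):
        rng = np.random.default_rng(3)
        n_cells = 400
        data = rng.normal(1.0, 0.2, size=(40, n_cells)).clip(0)
        # same mean ~1.0, very different variance
        data[0] = np.where(rng.random(n_cells) < 0.5, 0.0, 2.0)  # bimodal
        nm = make_norm(data)
        hv = select_hvgs(nm, 40)
        assert hv.genes.index("G0") < hv.genes.index("G1")

    def test_identity_when_n_equals_genes(self, ref_norm):
        hv = select_hvgs(ref_norm, ref_norm.n_genes)
        assert sorted(hv.genes) == sorted(map(str, ref_norm.gene_ids))

    def test_too_many_requested(self, ref_norm):
        with pytest.raises(PreprocessError):
            select_hvgs(ref_norm, ref_norm.n_genes + 1)


# --------------------------------------------------------------------------
# PCA


class TestPCA:
    def test_rank_deficient_errors_by_default(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(2, 50))
        data = (rng.normal(size=(30, 2)) @ base).T  # 50 cells x 30 genes, rank 2
        nm = make_norm(data.T - data.T.min())
        with pytest.raises(PreprocessError, match="rank"):
            run_pca(nm, [f"G{i}" for i in range(30)], 30, scale=False)
        emb = run_pca(nm, [f"G{i}" for i in range(30)], 30, scale=False,
                      allow_truncate=True)
        assert emb.coords.shape[1] <= 3

    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.2, size=(50, 20))
        b = rng.normal(3, 0.2, size=(50, 20))
        data = np.vstack([a, b]).T
        nm = make_norm(data - data.min())
        emb = run_pca(nm, [f"G{i}" for i in range(20)], 5)
        labels = np.array([0] * 50 + [1] * 50)
        assert silhouette_score(emb.coords[:, :1], labels) > 0.5

    def test_explained_variance_fractions(self, ref_norm):
        hv = select_hvgs(ref_norm, 500)
        emb = run_pca(ref_norm, hv, 30)
        frac = emb.explained_var_frac
        assert frac.sum() <= 1.0 + 1e-9
        assert np.all(np.diff(frac) <= 1e-12)

    def test_too_many_components(self):
        nm = make_norm(np.ones((5, 4)) + np.eye(5, 4))
        with pytest.raises(PreprocessError, match="n_pcs"):
            run_pca(nm, [f"G{i}" for i in range(5)], 6)


# --------------------------------------------------------------------------
# kNN graph


class TestKnn:
    def test_collinear_tie_rule(self):
        emb = Embedding(np.array([[0.0], [1.0], [2.0]]), np.array([1.0]),
                        np.array(["a", "b", "c"], dtype=object))
        g = build_knn(emb, 1)
        assert g.neighbors.ravel().tolist() == [1, 0, 1]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 5))
        emb = Embedding(X, np.ones(5), np.array([f"c{i}" for i in range(200)], dtype=object))
        g = build_knn(emb, 10)
        d = cdist(X, X)
        np.fill_diagonal(d, np.inf)
        expected = np.argsort(d, axis=1, kind="stable")[:, :10]
        np.testing.assert_array_equal(g.neighbors, expected)

    def test_no_self_edges_and_symmetry(self):
        rng = np.random.default_rng(7)
        emb = Embedding(rng.normal(size=(50, 3)), np.ones(3),
                        np.array([f"c{i}" for i in range(50)], dtype=object))
        g = build_knn(emb, 5)
        assert g.adjacency.diagonal().sum() == 0
        assert (g.adjacency != g.adjacency.T).nnz == 0
        assert np.diff(g.adjacency.indptr).min() >= 5

    def test_k_bounds(self):
        emb = Embedding(np.zeros((3, 2)), np.ones(2),
                        np.array(["a", "b", "c"], dtype=object))
        with pytest.raises(PreprocessError):
            build_knn(emb, 3)


# --------------------------------------------------------------------------
# Louvain


def graph_from_nx(G):
    adj = sp.csr_matrix(nx.to_scipy_sparse_array(G) != 0)
    n = adj.shape[0]
    return KnnGraph(neighbors=np.zeros((n, 0), dtype=np.int64), adjacency=adj,
                    cell_ids=np.asarray([f"c{i}" for i in range(n)], dtype=object))


class TestLouvain:
    def test_two_disconnected_cliques(self):
        G = nx.disjoint_union(nx.complete_graph(20), nx.complete_graph(20))
        cl = cluster_louvain(graph_from_nx(G), resolution=1.0, seed=0)
        assert cl.n_clusters == 2
        assert len(set(cl.labels[:20])) == 1 and len(set(cl.labels[20:])) == 1

    def test_planted_partition_recovered(self):
        G = nx.planted_partition_graph(4, 50, 0.3, 0.01, seed=8)
        truth = np.repeat(np.arange(4), 50)
        cl = cluster_louvain(graph_from_nx(G), resolution=0.5, seed=0)
        assert adjusted_rand_score(truth, cl.labels) >= 0.9

    def test_tiny_resolution_gives_single_cluster(self):
        G = nx.erdos_renyi_graph(60, 0.15, seed=9)
        cl = cluster_louvain(graph_from_nx(G), resolution=1e-4, seed=0)
        assert cl.n_clusters == 1

    def test_empty_graph_rejected(self):
        g = KnnGraph(np.zeros((0, 0), dtype=np.int64),
                     sp.csr_matrix((0, 0)), np.array([], dtype=object))
        with pytest.raises(PreprocessError, match="empty"):
            cluster_louvain(g, 1.0, 0)

    def test_deterministic_under_seed(self):
        G = nx.planted_partition_graph(3, 40, 0.3, 0.02, seed=10)
        a = cluster_louvain(graph_from_nx(G), 0.5, seed=4)
        b = cluster_louvain(graph_from_nx(G), 0.5, seed=4)
        np.testing.assert_array_equal(a.labels, b.labels)


# --------------------------------------------------------------------------
# Annotation


class TestAnnotate:
    def test_forced_single_marker_cluster(self):
        from oligoscore.preprocess import Clustering
        data = np.zeros((4, 40))
        data[0, :20] = 3.0  # PLP1 high in cluster 0
        data[1, :20] = 3.0  # MBP high in cluster 0
        data[2, 20:] = 3.0  # P2RY12 high in cluster 1
        nm = make_norm(data, gene_ids=["PLP1", "MBP", "P2RY12", "GFAP"])
        cl = Clustering(labels=np.repeat([0, 1], 20), resolution=0.5, modularity=0.0)
        out = annotate_clusters(nm, cl, {"OL": ["PLP1", "MBP"], "MG": ["P2RY12"]})
        assert out == {0: "OL", 1: "MG"}

    def test_single_cluster_single_type(self):
        from oligoscore.preprocess import Clustering
        nm = make_norm(np.ones((2, 10)) + np.arange(10), gene_ids=["PLP1", "X"])
        cl = Clustering(labels=np.zeros(10, dtype=int), resolution=0.5, modularity=0.0)
        assert annotate_clusters(nm, cl, {"OL": ["PLP1"]}) == {0: "OL"}

    def test_all_markers_missing_rejected(self, ref_norm):
        from oligoscore.preprocess import Clustering
        cl = Clustering(labels=np.zeros(ref_norm.n_cells, dtype=int),
                        resolution=0.5, modularity=0.0)
        with pytest.raises(PreprocessError, match="marker"):
            annotate_clusters(ref_norm, cl, {"XX": ["NOT_A_GENE"]})

    def test_recovery_on_synthetic_query(self, query_norm):
        """>= 90% of clusters get their majority true major type."""
        nm, meta = query_norm
        hv = select_hvgs(nm, min(2000, nm.n_genes))
        emb = run_pca(nm, hv, 30)
        g = build_knn(emb, 15)
        cl = cluster_louvain(g, 0.5, seed=0)
        annot = annotate_clusters(nm, cl, MAJOR_MARKERS)
        truth = meta["cell_type"].to_numpy()
        ok = 0
        for c in range(cl.n_clusters):
            members = truth[cl.labels == c]
            vals, cnt = np.unique(members, return_counts=True)
            if annot[c] == vals[np.argmax(cnt)]:
                ok += 1
        assert ok / cl.n_clusters >= 0.9
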