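"""Prototype scorer: training, penalty sweep, scoring, wheel projection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oligoscore.params import PipelineParams
from oligoscore.preprocess import NormMatrix
from oligoscore.prototype import (PrototypeResults, PrototypeScorer,
                                  ScoringError, assign_and_tabulate,
                                  wheel_coordinates)

from conftest import make_norm


def subset_norm(nm, mask):
    idx = np.nonzero(mask)[0]
    return NormMatrix(nm.values[:, idx], nm.gene_ids, nm.cell_ids[idx])


@pytest.fixture(scope="module")
def two_class(ref_norm, reference):
    """Pre-OPC vs MOL: disjoint marker supports by construction."""
    _, table, _ = reference
    y = table["subtype"].to_numpy()
    mask = np.isin(y, ["Pre-OPC", "MOL"])
    return subset_norm(ref_norm, mask), y[mask]


class TestTraining:
    def test_separable_two_class_accuracy(self, two_class):
        nm, y = two_class
        res = PrototypeScorer(nm, y).fit(seed=0)
        at = res.sweep.loc[res.sweep["lam"] == res.lambda_].iloc[0]
        assert at["cv_accuracy"] >= 0.99

    def test_shuffled_labels_score_at_chance(self, two_class):
        nm, y = two_class
        rng = np.random.default_rng(0)
        res = PrototypeScorer(nm, rng.permutation(y)).fit(
            lambda_grid=np.array([1.0]), seed=0)
        acc = res.sweep["cv_accuracy"].iloc[0]
        sd = res.sweep["ci_halfwidth"].iloc[0] / 1.96 * np.sqrt(5)
        assert abs(acc - 0.5) <= max(3 * sd, 0.12)

    def test_weight_norm_strictly_decreases_with_penalty(self, two_class):
        nm, y = two_class
        res = PrototypeScorer(nm, y).fit(seed=0)
        w = res.sweep.sort_values("lam")["sum_abs_weight"].to_numpy()
        assert np.all(np.diff(w) < 0)

    def test_train_loglik_non_increasing_with_penalty(self, two_class):
        nm, y = two_class
        res = PrototypeScorer(nm, y).fit(seed=0)
        ll = res.sweep.sort_values("lam")["train_loglik"].to_numpy()
        assert np.all(np.diff(ll) <= 1e-9)

    def test_small_class_rejected(self, ref_norm, reference):
        _, table, _ = reference
        y = table["subtype"].to_numpy().copy()
        y[:695] = "A"  # leaves 5 cells in the last class
        with pytest.raises(ScoringError, match="below"):
            PrototypeScorer(ref_norm, y)

    def test_lambda_star_in_grid(self, trained):
        assert trained.lambda_ in set(trained.sweep["lam"])


class TestScoring:
    def test_rows_sum_to_one_and_threshold_unique(self, query_ol_scores):
        scores, _ = query_ol_scores
        sums = scores.scores.sum(axis=1).to_numpy()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert (scores.scores.to_numpy() >= scores.tau).sum(axis=1).max() <= 1

    def test_training_cell_scores_its_own_class(self, trained, ref_norm, reference):
        _, table, _ = reference
        y = table["subtype"].to_numpy()
        pre = subset_norm(ref_norm, y == "Pre-OPC")
        st = trained.score(pre)
        assert (st.assigned == "Pre-OPC").mean() >= 0.9
        assert st.scores["Pre-OPC"].median() >= 0.70

    def test_all_zero_cells_score_identically(self, trained):
        nm = make_norm(np.zeros((len(trained.genes), 3)), gene_ids=list(trained.genes))
        st = trained.score(nm)
        assert (st.scores.iloc[0] == st.scores.iloc[1]).all()
        assert (st.scores.iloc[0] == st.scores.iloc[2]).all()

    def test_uniform_model_gives_uniform_unassigned(self):
        K, G = 7, 10
        res = PrototypeResults(
            classes=[f"C{k}" for k in range(K)], genes=[f"G{j}" for j in range(G)],
            W=np.zeros((K, G)), b=np.zeros(K), feature_mean=np.zeros(G),
            feature_sd=np.ones(G), lambda_=1.0,
            sweep=pd.DataFrame({"lam": [1.0], "cv_accuracy": [1 / K]}),
        )
        nm = make_norm(np.random.default_rng(0).random((G, 5)),
                       gene_ids=[f"G{j}" for j in range(G)])
        st = res.score(nm)
        np.testing.assert_allclose(st.scores.to_numpy(), 1 / K)
        assert (st.assigned == "unassigned").all()

    def test_invariant_to_query_gene_order(self, trained, ref_norm):
        rng = np.random.default_rng(1)
        perm = rng.permutation(ref_norm.n_genes)
        nm_perm = NormMatrix(ref_norm.values[perm], ref_norm.gene_ids[perm],
                             ref_norm.cell_ids)
        a = trained.score(ref_norm).scores
        b = trained.score(nm_perm).scores
        pd.testing.assert_frame_equal(a, b)

    def test_mostly_missing_genes_rejected(self, trained):
        few = trained.genes[: len(trained.genes) // 3]
        nm = make_norm(np.ones((len(few), 4)), gene_ids=list(few))
        with pytest.raises(ScoringError, match="missing"):
            trained.score(nm)

    def test_model_json_round_trip(self, trained, ref_norm, tmp_path):
        p = trained.to_json(tmp_path / "model.json")
        back = PrototypeResults.from_json(p)
        a = trained.score(ref_norm).scores
        b = back.score(ref_norm).scores
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)


@pytest.fixture(scope="module")
def planted_toy():
    rng = np.random.default_rng(2)
    n_per, n_inf, n_noise = 40, 10, 490
    X = rng.normal(1.0, 1.0, size=(n_inf + n_noise, 2 * n_per)).clip(0)
    X[:n_inf, :n_per] += 2.0  # informative genes mark class A
    genes = [f"INF{i}" for i in range(n_inf)] + [f"N{i}" for i in range(n_noise)]
    y = np.array(["A"] * n_per + ["B"] * n_per, dtype=object)
    return make_norm(X, gene_ids=genes), y


class TestReduceGenes:
    def test_identity_when_keeping_all_genes(self, planted_toy):
        nm, y = planted_toy
        full = PrototypeScorer(nm, y).fit(lambda_grid=np.array([1.0]), seed=0)
        same = full.reduce_genes(len(full.genes), seed=0)
        assert same.genes == full.genes
        np.testing.assert_allclose(same.W, full.W, atol=1e-4)

    def test_planted_features_recovered(self, planted_toy):
        nm, y = planted_toy
        full = PrototypeScorer(nm, y).fit(lambda_grid=np.array([1.0]), seed=0)
        red = full.reduce_genes(20, seed=0)
        recovered = sum(g.startswith("INF") for g in red.genes)
        assert recovered >= 8

    def test_beats_random_gene_subset(self, planted_toy):
        nm, y = planted_toy
        full = PrototypeScorer(nm, y).fit(lambda_grid=np.array([1.0]), seed=0)
        red = full.reduce_genes(20, seed=0)
        rng = np.random.default_rng(3)
        rand_genes = list(rng.choice(full.genes, size=20, replace=False))
        rand = PrototypeScorer(nm, y, genes=rand_genes).fit(
            lambda_grid=np.array([1.0]), seed=0)
        assert red.sweep["cv_accuracy"].iloc[0] >= rand.sweep["cv_accuracy"].iloc[0]

    def test_top_n_bounds(self, planted_toy):
        nm, y = planted_toy
        full = PrototypeScorer(nm, y).fit(lambda_grid=np.array([1.0]), seed=0)
        with pytest.raises(ScoringError):
            full.reduce_genes(1)
        with pytest.raises(ScoringError):
            full.reduce_genes(len(full.genes) + 1)


class TestTabulate:
    def test_fractions_sum_to_one_per_region(self, query_ol_scores):
        scores, meta = query_ol_scores
        tab = assign_and_tabulate(scores, meta)
        sums = tab.groupby("region")["fraction"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0)

    def test_planted_absence_recovered(self, query_ol_scores):
        scores, meta = query_ol_scores
        tab = assign_and_tabulate(scores, meta)
        core = tab[tab["region"].isin(["CA", "CI"])
                   & tab["label"].isin(["Pre-OPC", "NFOL"])]
        assert core["fraction"].sum() <= 0.01

    def test_cell_mismatch_rejected(self, query_ol_scores):
        scores, meta = query_ol_scores
        with pytest.raises(ScoringError, match="match"):
            assign_and_tabulate(scores, meta.iloc[:10])

    def test_single_region_single_row_group(self, trained, ref_norm, reference):
        _, table, _ = reference
        st = trained.score(ref_norm)
        tab = assign_and_tabulate(st, table)
        assert set(tab["region"]) == {"Control"}


class TestWheel:
    def test_one_hot_maps_to_vertex_and_uniform_to_origin(self, query_ol_scores):
        scores, _ = query_ol_scores
        wc = wheel_coordinates(scores)
        K = len(scores.classes)
        # synthetic rows: one-hot and uniform
        from oligoscore.prototype import SimilarityScoreTable
        rows = np.vstack([np.eye(K)[0], np.full(K, 1.0 / K)])
        st = SimilarityScoreTable(
            scores=pd.DataFrame(rows, index=["onehot", "uniform"],
                                columns=scores.classes),
            assigned=pd.Series(["x", "y"], index=["onehot", "uniform"]),
            tau=0.7,
        )
        wc2 = wheel_coordinates(st)
        np.testing.assert_allclose(wc2.points.loc["onehot"].to_numpy(),
                                   wc2.vertices.iloc[0].to_numpy(), atol=1e-12)
        np.testing.assert_allclose(wc2.points.loc["uniform"].to_numpy(), 0.0,
                                   atol=1e-12)
        # all real cells stay inside the unit disk (hull of the vertices)
        assert (np.linalg.norm(wc.points.to_numpy(), axis=1) <= 1 + 1e-9).all()

    def test_half_half_on_adjacent_vertices_is_midpoint(self):
        from oligoscore.prototype import SimilarityScoreTable
        classes = ["A", "B", "C", "D"]
        row = np.array([[0.5, 0.5, 0.0, 0.0]])
        st = SimilarityScoreTable(
            scores=pd.DataFrame(row, index=["c"], columns=classes),
            assigned=pd.Series(["unassigned"], index=["c"]), tau=0.7)
        wc = wheel_coordinates(st)
        mid = (wc.vertices.loc["A"].to_numpy() + wc.vertices.loc["B"].to_numpy()) / 2
        np.testing.assert_allclose(wc.points.loc["c"].to_numpy(), mid, atol=1e-12)

    def test_needs_three_classes(self):
        from oligoscore.prototype import SimilarityScoreTable
        st = SimilarityScoreTable(
            scores=pd.DataFrame([[0.5, 0.5]], index=["c"], columns=["A", "B"]),
            assigned=pd.Series(["unassigned"], index=["c"]), tau=0.7)
        with pytest.raises(ScoringError, match="3"):
            wheel_coordinates(st)

    def test_rows_must_sum_to_one(self):
        from oligoscore.prototype import SimilarityScoreTable
        st = SimilarityScoreTable(
            scores=pd.DataFrame([[0.5, 0.2, 0.1]], index=["c"],
                                columns=["A", "B", "C"]),
            assigned=pd.Series(["unassigned"], index=["c"]), tau=0.7)
        with pytest.raises(ScoringError, match="sum"):
            wheel_coordinates(st)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.001, 1.0), min_size=3, max_size=9))
    def test_any_stochastic_row_stays_in_hull(self, raw):
        from oligoscore.prototype import SimilarityScoreTable
        s = np.asarray(raw) / np.sum(raw)
        classes = [f"C{i}" for i in range(len(s))]
        table = SimilarityScoreTable(
            scores=pd.DataFrame([s], index=["c"], columns=classes),
            assigned=pd.Series(["unassigned"], index=["c"]), tau=0.7)
        wc = wheel_coordinates(table)
        assert np.linalg.norm(wc.points.loc["c"].to_numpy()) <= 1 + 1e-9
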