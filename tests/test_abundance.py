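"""Neighborhood differential abundance: sampling, Fisher testing, summaries."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oligoscore.abundance import (AbundanceError, NeighborhoodDA,
                                  NeighborhoodSet, filter_replicates,
                                  sample_neighborhoods, summarize_da)
from oligoscore.abundance import test_da as run_da_test
from oligoscore.params import PipelineParams
from oligoscore.preprocess import Embedding, NormMatrix, build_knn, run_pca, select_hvgs


# --------------------------------------------------------------------------
# replicate filter


class TestFilterReplicates:
    def _table(self):
        rows = []
        for grp, n_samples in (("A", 2), ("B", 3), ("C", 5)):
            for s in range(n_samples):
                rows.append({"cell_id": f"{grp}{s}", "sample_id": f"s{grp}{s}",
                             "region": "Control", "condition": "control",
                             "cell_type": grp})
        return pd.DataFrame(rows)

    def test_underreplicated_group_dropped(self):
        out = filter_replicates(self._table(), "cell_type")
        assert set(out["cell_type"]) == {"B", "C"}

    def test_min_one_is_identity(self):
        p = PipelineParams(min_replicates=1)
        out = filter_replicates(self._table(), "cell_type", p)
        assert len(out) == len(self._table())

    def test_everything_dropped_is_an_error(self):
        p = PipelineParams(min_replicates=10)
        with pytest.raises(AbundanceError):
            filter_replicates(self._table(), "cell_type", p)


# --------------------------------------------------------------------------
# neighborhood sampling


def small_graph(n=40, seed=0, k=3):
    rng = np.random.default_rng(seed)
    emb = Embedding(rng.normal(size=(n, 3)), np.ones(3),
                    np.asarray([f"c{i}" for i in range(n)], dtype=object))
    return emb, build_knn(emb, k)


class TestSampleNeighborhoods:
    def test_exhaustive_on_tiny_graph(self):
        emb, g = small_graph(5, k=2)
        nset = sample_neighborhoods(g, emb, prop=1.0, seed=0)
        assert len(nset.members) <= 5
        for i, mem in zip(nset.index_cells, nset.members):
            deg = g.adjacency.indptr[i + 1] - g.adjacency.indptr[i]
            assert len(mem) == deg + 1 and i in mem

    def test_deterministic(self):
        emb, g = small_graph()
        a = sample_neighborhoods(g, emb, prop=0.3, seed=5)
        b = sample_neighborhoods(g, emb, prop=0.3, seed=5)
        assert [m.tolist() for m in a.members] == [m.tolist() for m in b.members]

    def test_refinement_moves_to_neighborhood_centroid(self):
        """With prop = 1 every cell is drawn, so the refined index set is
        exactly {argmin over members of distance to the draw's neighborhood
        mean}, computable without touching the RNG."""
        emb, g = small_graph(30, seed=3, k=4)
        nset = sample_neighborhoods(g, emb, prop=1.0, seed=1)
        expected = set()
        for j in range(30):
            members = np.concatenate([[j], g.graph_neighbors(j)])
            center = emb.coords[members].mean(axis=0)
            d2 = ((emb.coords[members] - center) ** 2).sum(axis=1)
            expected.add(int(members[np.lexsort((members, d2))[0]]))
        assert set(nset.index_cells.tolist()) == expected
        # refinement never increases the distance to the neighborhood mean
        for j in range(30):
            members = np.concatenate([[j], g.graph_neighbors(j)])
            center = emb.coords[members].mean(axis=0)
            d_orig = ((emb.coords[j] - center) ** 2).sum()
            d_best = ((emb.coords[members] - center) ** 2).sum(axis=1).min()
            assert d_best <= d_orig + 1e-12

    def test_count_conservation(self, query_norm):
        nm, meta = query_norm
        hv = select_hvgs(nm, 500)
        emb = run_pca(nm, hv, 10)
        g = build_knn(emb, 15)
        nset = sample_neighborhoods(g, emb, meta, prop=0.05, seed=2)
        sizes = np.asarray([len(m) for m in nset.members])
        np.testing.assert_array_equal(nset.sample_counts.sum(axis=1).to_numpy(), sizes)

    def test_prop_bounds(self):
        emb, g = small_graph(5, k=2)
        with pytest.raises(AbundanceError):
            sample_neighborhoods(g, emb, prop=0.0, seed=0)
        with pytest.raises(AbundanceError):
            sample_neighborhoods(g, emb, prop=0.05, seed=0)


# --------------------------------------------------------------------------
# Fisher DA


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p via exact hypergeometric enumeration (rationals)."""
    n1, row1, N = a + b, a + c, a + b + c + d

    def pmf(k):
        return (Fraction(math.comb(row1, k) * math.comb(N - row1, n1 - k),
                         math.comb(N, n1)))

    lo, hi = max(0, n1 - (N - row1)), min(row1, n1)
    p_obs = pmf(a)
    total = sum(pmf(k) for k in range(lo, hi + 1)
                if pmf(k) <= p_obs * (1 + Fraction(1, 10**7)))
    return float(total)


def make_nset(members_list, cell_ids):
    return NeighborhoodSet(
        index_cells=np.asarray([m[0] for m in members_list]),
        members=[np.asarray(m) for m in members_list],
        sample_counts=pd.DataFrame(index=range(len(members_list))),
        cell_ids=np.asarray(cell_ids, dtype=object),
    )


def balanced_table(n=100):
    return pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "sample_id": [f"s{i % 4}" for i in range(n)],
        "region": ["Control"] * (n // 2) + ["CA"] * (n // 2),
        "condition": ["control"] * (n // 2) + ["MS"] * (n // 2),
        "subtype": ["X"] * n,
    })


class TestTestDA:
    def test_null_neighborhood_flat(self):
        table = balanced_table()
        nset = make_nset([list(range(45, 55))], table["cell_id"])  # 5 + 5 split
        out = run_da_test(nset, table, condition_key="region",
                      level_a="CA", level_b="Control")
        assert out["p_value"].iloc[0] == 1.0
        assert abs(out["log2fc"].iloc[0]) < 0.01

    def test_condition_swap_negates_lfc_preserves_p(self):
        rng = np.random.default_rng(0)
        table = balanced_table()
        nset = make_nset([sorted(rng.choice(100, 12, replace=False)),
                          sorted(rng.choice(100, 20, replace=False))],
                         table["cell_id"])
        a = run_da_test(nset, table, "region", "CA", "Control")
        b = run_da_test(nset, table, "region", "Control", "CA")
        np.testing.assert_allclose(a["log2fc"].to_numpy(), -b["log2fc"].to_numpy(),
                                   atol=1e-12)
        np.testing.assert_array_equal(a["p_value"].to_numpy(), b["p_value"].to_numpy())

    @pytest.mark.parametrize("tbl", [
        (3, 7, 17, 13), (0, 10, 20, 10), (8, 2, 12, 18), (5, 5, 15, 15),
        (1, 1, 24, 24), (12, 3, 8, 17),
    ])
    def test_matches_factorial_oracle(self, tbl):
        a, b, c, d = tbl
        ours = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        assert np.isclose(ours, fisher_two_sided_oracle(a, b, c, d), atol=1e-10)

    def test_single_condition_rejected(self):
        table = balanced_table()
        table["region"] = "CA"
        table["condition"] = "MS"
        nset = make_nset([[0, 1, 2]], table["cell_id"])
        with pytest.raises(AbundanceError):
            run_da_test(nset, table, "region", "CA", "Control")

    def test_majority_annotation(self):
        table = balanced_table()
        table.loc[:59, "subtype"] = "Y"
        nset = make_nset([list(range(10))], table["cell_id"])
        out = run_da_test(nset, table, "region", "CA", "Control")
        assert out["majority_label"].iloc[0] == "Y"


# --------------------------------------------------------------------------
# end-to-end DA on the synthetic query


@pytest.fixture(scope="module")
def da_inputs(query_norm):
    nm, meta = query_norm
    sel = meta["region"].isin(["CA", "Control"]).to_numpy()
    idx = np.nonzero(sel)[0]
    sub = NormMatrix(nm.values[:, idx], nm.gene_ids, nm.cell_ids[idx])
    hv = select_hvgs(sub, min(2000, sub.n_genes))
    emb = run_pca(sub, hv, 30)
    g = build_knn(emb, 15)
    return emb, g, meta[sel].reset_index(drop=True)


class TestDAOnQuery:
    def test_planted_effects_point_the_right_way(self, da_inputs):
        emb, g, meta = da_inputs
        res = NeighborhoodDA(emb, g, meta).fit(
            condition_key="region", level_a="CA", level_b="Control", seed=0)
        summ = res.summarize().set_index("majority_label")
        # inflamed microglia are ~10-fold enriched in CA, Pre-OPC/NFOL absent
        assert summ.loc["MG_inflamed", "mean_log2fc"] > 1.0
        for depleted in ("Pre-OPC", "NFOL"):
            if depleted in summ.index:
                assert summ.loc[depleted, "mean_log2fc"] < -1.0
        assert summ.loc["MG_inflamed", "flagged_fraction"] > 0.2

    def test_permuted_labels_are_calibrated(self, da_inputs):
        emb, g, meta = da_inputs
        rates = []
        for s in range(3):
            rng = np.random.default_rng(s)
            perm = meta.copy()
            perm["region"] = rng.permutation(perm["region"].to_numpy())
            res = NeighborhoodDA(emb, g, perm).fit(
                condition_key="region", level_a="CA", level_b="Control",
                seed=100 + s)
            rates.append(float((res.table["fdr"] < 0.05).mean()))
        assert np.mean(rates) < 0.05

    def test_summaries(self, da_inputs):
        emb, g, meta = da_inputs
        res = NeighborhoodDA(emb, g, meta).fit(
            condition_key="region", level_a="CA", level_b="Control", seed=0)
        one = summarize_da(res.table.iloc[:1])
        assert len(one) == 1
        full = res.summarize()
        assert set(full["majority_label"]) <= set(meta["subtype"])
        assert "neighborhoods" in res.summary()
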