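"""Recovery and calibration benchmarks run on freshly simulated data.

Every function here regenerates its inputs from a seed and runs the
package end to end on them, returning measured quantities: held-out
recall of the prototype scorer, threshold semantics on a withheld class,
region-composition recovery, permutation-test calibration and planted
ligand-receptor recovery, module-score calibration, neighborhood
differential-abundance calibration and power, and exact-oracle agreement
for the small-sample statistics.  Both the test suite and the acceptance
script are thin wrappers around these routines.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .abundance import NeighborhoodDA
from .communication import LigandReceptorAnalysis, permutation_test
from .deg import wilcoxon_deg
from .io import CountMatrix
from .modulescore import score_module
from .params import PipelineParams
from .preprocess import (NormMatrix, build_knn, normalize_log, qc_filter,
                         run_pca, select_hvgs)
from .prototype import PrototypeScorer
from .simulate import (INFLAMMATORY_PROGRAM, MT_GENES, SimConfig,
                       generate_lr_patterns, generate_ms_query,
                       generate_reference_atlas, make_null_lr_table)


def _sub_seed(seed: int, key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(key,)).generate_state(1)[0]
               % (2**31))


def _subset(nm: NormMatrix, mask: np.ndarray) -> NormMatrix:
    idx = np.nonzero(mask)[0]
    return NormMatrix(nm.values[:, idx], nm.gene_ids, nm.cell_ids[idx])


def _query_norm(cfg: SimConfig, plant_lr: bool = False):
    counts, table, truth = generate_ms_query(cfg)
    lr_table = None
    if plant_lr:
        lr_table, counts, truth = generate_lr_patterns(cfg, counts, table, truth)
    filtered, _ = qc_filter(counts)
    nm = normalize_log(filtered)
    meta = table[table["cell_id"].isin(set(filtered.cell_ids))].reset_index(drop=True)
    return nm, meta, truth, lr_table


# --------------------------------------------------------------------------
# Prototype scorer


def heldout_recall(seed: int, test_size: float = 0.3) -> dict:
    """Per-class recall on a stratified held-out split of the reference."""
    cfg = SimConfig(seed=seed)
    counts, table, _ = generate_reference_atlas(cfg)
    nm = normalize_log(counts)
    y = table["subtype"].to_numpy()
    idx_tr, idx_te = train_test_split(np.arange(nm.n_cells), test_size=test_size,
                                      stratify=y, random_state=_sub_seed(seed, 1))
    idx_tr, idx_te = np.sort(idx_tr), np.sort(idx_te)
    model = PrototypeScorer(_subset(nm, np.isin(np.arange(nm.n_cells), idx_tr)),
                            y[idx_tr]).fit(seed=_sub_seed(seed, 2))
    scores = model.score(_subset(nm, np.isin(np.arange(nm.n_cells), idx_te)))
    pred = scores.scores.idxmax(axis=1).to_numpy()
    y_te = y[idx_te]
    recall = {c: float((pred[y_te == c] == c).mean()) for c in np.unique(y_te)}
    pooled_mask = np.isin(y_te, ["COP", "NFOL"])
    recall["COP+NFOL"] = float(np.isin(pred[pooled_mask], ["COP", "NFOL"]).mean())
    solo = [v for c, v in recall.items() if c not in ("COP", "NFOL", "COP+NFOL")]
    return {"per_class": recall, "min_recall": min(solo + [recall["COP+NFOL"]]),
            "n_test": int(len(y_te))}


def threshold_semantics(seed: int, withheld: str = "MOL") -> dict:
    """Row-stochasticity, threshold uniqueness, and withheld-class rejection."""
    cfg = SimConfig(seed=seed)
    counts, table, _ = generate_reference_atlas(cfg)
    nm = normalize_log(counts)
    y = table["subtype"].to_numpy()
    keep = y != withheld
    model = PrototypeScorer(_subset(nm, keep), y[keep]).fit(seed=_sub_seed(seed, 3))
    scores = model.score(_subset(nm, ~keep))
    mat = scores.scores.to_numpy()
    return {
        "row_sum_max_abs_dev": float(np.abs(mat.sum(axis=1) - 1.0).max()),
        "max_classes_at_tau": int((mat >= scores.tau).sum(axis=1).max()),
        "unassigned_rate": float((scores.assigned == "unassigned").mean()),
        "n_cells": int(mat.shape[0]),
    }


def composition_recovery(seed: int) -> dict:
    """Assigned Pre-OPC + NFOL fraction per region vs the planted truth.

    Fractions are computed among threshold-passing (assigned) OL-lineage
    cells, matching how subtype matches are extracted for composition
    figures; the planted value is the true fraction among the same scored
    population.
    """
    cfg = SimConfig(seed=seed)
    ref_counts, ref_table, _ = generate_reference_atlas(cfg)
    model = PrototypeScorer(normalize_log(ref_counts),
                            ref_table["subtype"].to_numpy()).fit(seed=_sub_seed(seed, 4))
    nm, meta, _, _ = _query_norm(cfg)
    ol = meta["cell_type"].isin(["OPC", "OL"]).to_numpy()
    scores = model.score(_subset(nm, ol))
    df = pd.DataFrame({
        "region": meta.loc[ol, "region"].to_numpy(),
        "assigned": scores.assigned.to_numpy(),
        "true": meta.loc[ol, "subtype"].to_numpy(),
    })
    out = {}
    for region in ("Control", "NAWM", "CA", "CA_edge", "CI", "CI_edge"):
        sub = df[df["region"] == region]
        ass = sub[sub["assigned"] != "unassigned"]
        out[region] = {
            "assigned_fraction": float(ass["assigned"].isin(["Pre-OPC", "NFOL"]).mean()),
            "planted_fraction": float(sub["true"].isin(["Pre-OPC", "NFOL"]).mean()),
            "n": int(len(sub)),
        }
    return out


# --------------------------------------------------------------------------
# Ligand-receptor permutation test


def lr_type1_calibration(seed: int, n_seeds: int = 5) -> dict:
    """Fraction of tested null hypotheses with p < 0.05.

    The null shuffles cell-type labels within each region (the data carry
    no label-linked pattern for the tested filler-gene pairs), pooling
    across seeds and regions.
    """
    hits = total = 0
    for i in range(n_seeds):
        s = _sub_seed(seed, 10 + i)
        cfg = SimConfig(seed=s)
        nm, meta, _, _ = _query_norm(cfg)
        rng = np.random.default_rng(_sub_seed(s, 1))
        meta = meta.copy()
        for region in meta["region"].unique():
            m = (meta["region"] == region).to_numpy()
            meta.loc[m, "cell_type"] = rng.permutation(meta.loc[m, "cell_type"].to_numpy())
        res = LigandReceptorAnalysis(nm, meta, make_null_lr_table(nm.gene_ids, 8)).fit(
            seed=_sub_seed(s, 2), regions=["Control", "NAWM"])
        tested = res.table[res.table["tested"]]
        hits += int((tested["p_value"] < 0.05).sum())
        total += len(tested)
    return {"rate": hits / total, "n_tests": total}


def lr_exact_oracle_gap(seed: int) -> dict:
    """|Monte-Carlo p - exhaustive-enumeration p| on a 6-cell 2-type toy."""
    rng = np.random.default_rng(seed)
    vals = rng.random((2, 6)) + 0.5
    nm = NormMatrix(sp.csr_matrix(vals), np.asarray(["L", "R"], dtype=object),
                    np.asarray([f"c{i}" for i in range(6)], dtype=object))
    meta = pd.DataFrame({"cell_id": [f"c{i}" for i in range(6)], "sample_id": "s1",
                         "region": "Control", "condition": "control",
                         "cell_type": ["S"] * 3 + ["T"] * 3})
    lr = pd.DataFrame({"pair_id": ["P"], "ligand_gene": ["L"], "receptor_gene": ["R"]})
    res = permutation_test(nm, meta, lr, params=PipelineParams(n_perm=1000),
                           seed=_sub_seed(seed, 1))
    p_mc = float(res.table.set_index(["sender", "receiver"]).loc[("S", "T"), "p_value"])
    obs = 0.5 * (vals[0, :3].mean() + vals[1, 3:].mean())
    stats_all = [
        0.5 * (vals[0, list(s_cells)].mean()
               + vals[1, [i for i in range(6) if i not in s_cells]].mean())
        for s_cells in combinations(range(6), 3)
    ]
    p_exact = float(np.mean(np.asarray(stats_all) >= obs - 1e-12))
    return {"p_mc": p_mc, "p_exact": p_exact, "abs_gap": abs(p_mc - p_exact)}


def lr_planted_recovery(seed: int, n_seeds: int = 5) -> dict:
    """Planted SIRPA-CD47 / CD74-MIF on-off recovery across seeds."""
    tallies = {"sirpa_nawm_sig": 0, "sirpa_ca_nonsig": 0,
               "cd74_ca_sig": 0, "cd74_nawm_nonsig": 0}
    for i in range(n_seeds):
        s = _sub_seed(seed, 20 + i)
        cfg = SimConfig(seed=s)
        nm, meta, _, lr_table = _query_norm(cfg, plant_lr=True)
        res = LigandReceptorAnalysis(nm, meta, lr_table).fit(
            seed=_sub_seed(s, 1), regions=["NAWM", "CA"])
        t = res.table.set_index(["region", "pair_id", "sender", "receiver"])
        tallies["sirpa_nawm_sig"] += bool(t.loc[("NAWM", "SIRPA-CD47", "MG", "OL"),
                                                "significant"])
        tallies["sirpa_ca_nonsig"] += not t.loc[("CA", "SIRPA-CD47", "MG", "OL"),
                                                "significant"]
        tallies["cd74_ca_sig"] += bool(t.loc[("CA", "CD74-MIF", "OL", "MG"),
                                             "significant"])
        tallies["cd74_nawm_nonsig"] += not t.loc[("NAWM", "CD74-MIF", "OL", "MG"),
                                                 "significant"]
    tallies["n_seeds"] = n_seeds
    return tallies


# --------------------------------------------------------------------------
# Module scoring


def module_score_calibration(seed: int, n_draws: int = 100, set_size: int = 30) -> dict:
    """Null random-set score means plus planted inflamed-microglia AUC."""
    cfg = SimConfig(seed=seed)
    nm, meta, _, _ = _query_norm(cfg)
    fillers = [str(g) for g in nm.gene_ids if str(g).startswith("GENE")]
    rng = np.random.default_rng(_sub_seed(seed, 1))
    means = [
        float(score_module(nm, list(rng.choice(fillers, set_size, replace=False)),
                           seed=_sub_seed(seed, 100 + i)).scores.mean())
        for i in range(n_draws)
    ]
    msv = score_module(nm, INFLAMMATORY_PROGRAM, seed=_sub_seed(seed, 2))
    mg = meta[meta["cell_type"] == "MG"]
    auc = float(roc_auc_score((mg["subtype"] == "MG_inflamed").to_numpy(),
                              msv.scores[mg["cell_id"]].to_numpy()))
    return {"max_abs_null_mean": float(np.max(np.abs(means))),
            "mean_null_mean": float(np.mean(means)),
            "inflamed_auc": auc, "n_draws": n_draws}


# --------------------------------------------------------------------------
# Differential abundance


def _embed(nm: NormMatrix, params: PipelineParams):
    hv = select_hvgs(nm, min(params.n_hvg_cluster, nm.n_genes))
    emb = run_pca(nm, hv, min(params.n_pcs, len(hv.genes) - 1))
    return emb, build_knn(emb, params.knn_k)


def da_null_calibration(seed: int, n_perm_seeds: int = 20) -> dict:
    """Flagged fraction at FDR 0.05 under permuted condition labels."""
    params = PipelineParams()
    cfg = SimConfig(seed=seed)
    nm, meta, _, _ = _query_norm(cfg)
    sel = meta["region"].isin(["CA", "Control"]).to_numpy()
    sub_nm = _subset(nm, sel)
    emb, graph = _embed(sub_nm, params)
    sub_meta = meta[sel].reset_index(drop=True)
    rates = []
    for i in range(n_perm_seeds):
        rng = np.random.default_rng(_sub_seed(seed, 200 + i))
        perm = sub_meta.copy()
        perm["region"] = rng.permutation(perm["region"].to_numpy())
        res = NeighborhoodDA(emb, graph, perm, params).fit(
            condition_key="region", level_a="CA", level_b="Control",
            seed=_sub_seed(seed, 300 + i))
        rates.append(float((res.table["fdr"] < 0.05).mean()))
    return {"mean_flag_rate": float(np.mean(rates)), "n_seeds": n_perm_seeds}


def da_power_3fold(seed: int, n_seeds: int = 5) -> dict:
    """Power on an exactly 3-fold planted enrichment of one state.

    Two regions; microglia (one homeostatic state) at 45% vs 15% of cells
    with every other subtype scaled proportionally; neighborhoods whose
    majority label is the enriched state are scored at FDR 0.10.
    """
    params = PipelineParams()
    comp = {
        "Control": {"Pre-OPC": 0.15, "Late-OPC": 0.15, "NFOL": 0.15, "MOL": 0.25,
                    "MG": 0.15, "AST": 0.15},
        "NAWM": {"Pre-OPC": 0.10, "Late-OPC": 0.10, "NFOL": 0.10, "MOL": 0.20,
                 "MG": 0.45, "AST": 0.05},
    }
    flagged = total = 0
    for i in range(n_seeds):
        s = _sub_seed(seed, 400 + i)
        cfg = SimConfig(seed=s, regions=("Control", "NAWM"), region_composition=comp,
                        inflamed_frac={"Control": 0.0, "NAWM": 0.0},
                        cells_per_sample=250)
        nm, meta, _, _ = _query_norm(cfg)
        emb, graph = _embed(nm, params)
        res = NeighborhoodDA(emb, graph, meta, params).fit(
            condition_key="region", level_a="NAWM", level_b="Control",
            seed=_sub_seed(s, 1))
        mg = res.table[res.table["majority_label"] == "MG_homeostatic"]
        flagged += int((mg["fdr"] < 0.10).sum())
        total += len(mg)
    return {"power": flagged / total, "n_neighborhoods": total, "n_seeds": n_seeds}


# --------------------------------------------------------------------------
# Exact oracles


def wilcoxon_enumeration_gap(seed: int, n_genes: int = 10) -> dict:
    """Max |p - enumeration| for 4-vs-4 tie-free groups."""
    rng = np.random.default_rng(seed)
    vals = rng.random((n_genes, 8)) + 0.1
    nm = NormMatrix(sp.csr_matrix(vals),
                    np.asarray([f"G{i}" for i in range(n_genes)], dtype=object),
                    np.asarray([f"c{i}" for i in range(8)], dtype=object))
    out = wilcoxon_deg(nm, [f"c{i}" for i in range(4)],
                       [f"c{i}" for i in range(4, 8)]).set_index("gene")
    gaps = []
    for g in range(n_genes):
        a, b = vals[g, :4], vals[g, 4:]
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        u_obs = ranks[:4].sum() - 10
        us = np.asarray([ranks[list(c)].sum() - 10 for c in combinations(range(8), 4)])
        p_enum = min(1.0, 2 * min(float(np.mean(us <= u_obs)),
                                  float(np.mean(us >= u_obs))))
        gaps.append(abs(float(out.loc[f"G{g}", "p_value"]) - p_enum))
    return {"max_abs_gap": float(np.max(gaps)), "n_genes": n_genes}


def hypergeom_worked_example() -> dict:
    """ORA p for N=10, K=4, n=3, k=2; exact value 1/3."""
    from .deg import enrich_hypergeom
    from .io import GeneSetCollection
    universe = [f"G{i}" for i in range(10)]
    out = enrich_hypergeom(["G0", "G1", "G9"], universe,
                           GeneSetCollection({"S": universe[:4]}))
    return {"p": float(out["p_value"].iloc[0]), "exact": 1 / 3}


def fisher_oracle_gap(seed: int, n_tables: int = 30, max_n: int = 50) -> dict:
    """Max |Fisher p - factorial enumeration| over random tables, N <= 50."""

    def oracle(a, b, c, d):
        n1, row1, N = a + b, a + c, a + b + c + d

        def pmf(k):
            return Fraction(math.comb(row1, k) * math.comb(N - row1, n1 - k),
                            math.comb(N, n1))

        lo, hi = max(0, n1 - (N - row1)), min(row1, n1)
        p_obs = pmf(a)
        return float(sum(pmf(k) for k in range(lo, hi + 1)
                         if pmf(k) <= p_obs * (1 + Fraction(1, 10**7))))

    rng = np.random.default_rng(seed)
    gaps = []
    for _ in range(n_tables):
        N = int(rng.integers(8, max_n + 1))
        a = int(rng.integers(0, N + 1))
        b = int(rng.integers(0, N - a + 1))
        c = int(rng.integers(0, N - a - b + 1))
        d = N - a - b - c
        ours = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        gaps.append(abs(ours - oracle(a, b, c, d)))
    return {"max_abs_gap": float(np.max(gaps)), "n_tables": n_tables}


# --------------------------------------------------------------------------
# QC worked fixture


def qc_fixture_10cells():
    """10 cells with planted detected-gene counts and mito fractions;
    exactly 6 satisfy 200 <= genes <= 6000 (inclusive) and mito < 5%."""
    n_genes = 6200
    genes = MT_GENES + [f"G{i:05d}" for i in range(n_genes - len(MT_GENES))]
    plan = [
        (199, 1),    # 200 detected, mito 1/200        -> kept
        (5999, 1),   # 6000 detected (boundary)        -> kept
        (499, 26),   # mito 26/525 = 0.0495            -> kept
        (3000, 0),   # no mito at all                  -> kept
        (249, 7),    # mito 7/256 = 0.027              -> kept
        (999, 20),   # mito 20/1019 = 0.0196           -> kept
        (150, 0),    # 150 detected < 200              -> removed
        (6050, 0),   # 6050 detected > 6000            -> removed
        (475, 25),   # mito 25/500 = 0.05 exactly      -> removed (strict <)
        (450, 50),   # mito 0.10                       -> removed
    ]
    rows, cols, vals = [], [], []
    for c, (n_reg, mt) in enumerate(plan):
        rows.extend(range(len(MT_GENES), len(MT_GENES) + n_reg))
        cols.extend([c] * n_reg)
        vals.extend([1] * n_reg)
        if mt:
            rows.append(0)
            cols.append(c)
            vals.append(mt)
    m = sp.csr_matrix((vals, (rows, cols)), shape=(n_genes, 10), dtype=np.int64)
    counts = CountMatrix(m, np.asarray(genes, dtype=object),
                         np.asarray([f"cell{i}" for i in range(10)], dtype=object))
    return counts, [f"cell{i}" for i in range(6)]


def qc_fixture_result() -> dict:
    counts, expected = qc_fixture_10cells()
    filtered, report = qc_filter(counts)
    return {"retained": list(map(str, filtered.cell_ids)), "expected": expected,
            "n_retained": int(report["n_kept"])}


# --------------------------------------------------------------------------
# Pipeline determinism


def runall_determinism(seed: int, base_dir) -> dict:
    """Run the full pipeline twice with one seed; compare output bytes."""
    import hashlib
    from pathlib import Path

    from .pipeline import run_all

    base = Path(base_dir)
    digests = []
    for tag in ("a", "b"):
        out = base / f"run_{tag}"
        run_all(seed=seed, out_dir=out)
        files = sorted(p for p in out.rglob("*")
                       if p.is_file() and p.name not in ("manifest.json", "run.log"))
        digests.append({str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
                        for p in files})
    identical = digests[0] == digests[1]
    return {"identical": bool(identical), "n_files": len(digests[0])}
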