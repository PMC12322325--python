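"""End-to-end orchestration of the synthetic study.

``run_all`` executes simulate -> QC -> normalize -> cluster/annotate ->
train -> score -> module-score -> differential abundance -> cell
communication -> DEG/ORA with one config and one seed, writing plain TSV
outputs, a machine-readable summary, and a manifest with per-stage wall
times and SHA-256 checksums.  A single global seed fans out to per-stage
seeds through a fixed spawn schedule, so any stage can be re-run in
isolation and two runs with the same seed produce byte-identical outputs
(timestamps live only in the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance, communication, deg, modulescore, prototype
from . import preprocess as pp
from .io import (GeneSetCollection, write_cell_table, write_counts, write_gmt,
                 write_lr_table)
from .params import PipelineParams, load_params
from .simulate import (INFLAMMATORY_PROGRAM, MAJOR_MARKERS, SUBTYPE_MARKERS,
                       SimConfig, generate_lr_patterns, generate_ms_query,
                       generate_reference_atlas)

logger = logging.getLogger("oligoscore")

STAGES = ("simulate", "qc", "normalize", "cluster", "train", "score",
          "module_score", "da", "cellcomm", "deg")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2^31."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


def setup_logging(out_dir: Path | None = None, level: str = "INFO") -> None:
    logger.setLevel(level)
    logger.handlers.clear()
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    if out_dir is not None:
        fh = logging.FileHandler(out_dir / "run.log", mode="w")
        fh.setFormatter(fmt)
        logger.addHandler(fh)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path


def run_all(
    config_path: str | Path | None = None,
    seed: int | None = None,
    out_dir: str | Path = "oligoscore_run",
    sim_config: SimConfig | None = None,
) -> dict:
    """Run the full synthetic study; returns the manifest dict."""
    params = load_params(config_path)
    if seed is not None:
        params.seed = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    setup_logging(out)
    manifest: dict = {"params": dataclasses.asdict(params), "seed": params.seed,
                      "stages": {}, "outputs": {}}
    t_all = time.time()

    def record(stage: str, t0: float, paths: dict[str, Path]) -> None:
        manifest["stages"][stage] = {"wall_time_s": round(time.time() - t0, 3)}
        for key, p in paths.items():
            manifest["outputs"][f"{stage}/{key}"] = {
                "path": str(p), "sha256": _sha256(Path(p))
            }

    # ---- simulate ----------------------------------------------------------
    t0 = time.time()
    cfg = sim_config or SimConfig(seed=stage_seed(params.seed, "simulate"))
    ref_counts, ref_table, ref_truth = generate_reference_atlas(cfg)
    q_counts, q_table, q_truth = generate_ms_query(cfg)
    lr_table, q_counts, q_truth = generate_lr_patterns(cfg, q_counts, q_table, q_truth)
    sim_dir = out / "simulated"
    ref_paths = write_counts(ref_counts, sim_dir / "reference")
    q_paths = write_counts(q_counts, sim_dir / "query")
    paths = {
        "ref_mtx": ref_paths["mtx"], "query_mtx": q_paths["mtx"],
        "ref_meta": write_cell_table(ref_table, sim_dir / "reference_meta.tsv"),
        "query_meta": write_cell_table(q_table, sim_dir / "query_meta.tsv"),
        "truth_cells": _write_tsv(q_truth.cells, sim_dir / "truth_cells.tsv"),
        "truth_composition": _write_tsv(q_truth.composition, sim_dir / "truth_composition.tsv"),
        "truth_interactions": _write_tsv(q_truth.interactions, sim_dir / "truth_interactions.tsv"),
        "lr_table": write_lr_table(lr_table, sim_dir / "lr_pairs.tsv"),
    }
    cfg_path = sim_dir / "sim_config.yaml"
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["regions"] = list(cfg_dict["regions"])
    for pat in cfg_dict["lr_patterns"]:
        pat["on_regions"] = list(pat["on_regions"])
    cfg_path.write_text(yaml.safe_dump(cfg_dict, sort_keys=True))
    paths["sim_config"] = cfg_path
    record("simulate", t0, paths)

    # ---- QC + normalize ----------------------------------------------------
    t0 = time.time()
    q_filt, qc_report = pp.qc_filter(q_counts, params)
    keep = set(q_filt.cell_ids)
    q_table_f = q_table[q_table["cell_id"].isin(keep)].reset_index(drop=True)
    (out / "qc_report.json").write_text(json.dumps(qc_report, indent=2))
    record("qc", t0, {"report": out / "qc_report.json"})

    t0 = time.time()
    ref_norm = pp.normalize_log(ref_counts, params)
    q_norm = pp.normalize_log(q_filt, params)
    record("normalize", t0, {})

    # ---- cluster + annotate ------------------------------------------------
    t0 = time.time()
    hvgs = pp.select_hvgs(q_norm, min(params.n_hvg_cluster, q_norm.n_genes))
    emb = pp.run_pca(q_norm, hvgs, min(params.n_pcs, len(hvgs.genes) - 1))
    graph = pp.build_knn(emb, params.knn_k)
    clust = pp.cluster_louvain(graph, params.louvain_resolution,
                               stage_seed(params.seed, "cluster"))
    annot = pp.annotate_clusters(q_norm, clust, MAJOR_MARKERS)
    clusters = pd.DataFrame(
        {"cell_id": q_norm.cell_ids, "cluster": clust.labels,
         "cell_type": [annot[c] for c in clust.labels]}
    )
    paths = {
        "clusters": _write_tsv(clusters, out / "clusters.tsv"),
        "embedding": _write_tsv(
            pd.DataFrame(emb.coords, index=list(emb.cell_ids)).rename_axis("cell_id"),
            out / "embedding.tsv", index=True),
        "hvgs": _write_tsv(pd.DataFrame({"gene": hvgs.genes, "stat": hvgs.stat}),
                           out / "hvgs.tsv"),
    }
    record("cluster", t0, paths)

    # ---- train -------------------------------------------------------------
    t0 = time.time()
    model = prototype.PrototypeScorer(
        ref_norm, ref_table["subtype"].to_numpy(), params
    ).fit(seed=stage_seed(params.seed, "train"))
    paths = {
        "model": model.to_json(out / "prototype_model.json"),
        "sweep": _write_tsv(model.sweep, out / "regularization_sweep.tsv"),
    }
    (out / "model_summary.txt").write_text(model.summary() + "\n")
    paths["summary"] = out / "model_summary.txt"
    record("train", t0, paths)

    # ---- score OL-lineage query cells ---------------------------------------
    t0 = time.time()
    ol_mask = q_table_f["cell_type"].isin(["OPC", "OL"]).to_numpy()
    q_ol = pp.NormMatrix(q_norm.values[:, np.nonzero(ol_mask)[0]],
                         q_norm.gene_ids, q_norm.cell_ids[ol_mask])
    scores = model.score(q_ol)
    composition = prototype.assign_and_tabulate(
        scores, q_table_f[ol_mask].reset_index(drop=True)
    )
    wheel = prototype.wheel_coordinates(scores)
    paths = {
        "scores": _write_tsv(scores.scores.rename_axis("cell_id"),
                             out / "similarity_scores.tsv", index=True),
        "assignments": _write_tsv(
            scores.assigned.rename_axis("cell_id").reset_index(), out / "assignments.tsv"),
        "composition": _write_tsv(composition, out / "region_composition.tsv"),
        "wheel": _write_tsv(wheel.points.rename_axis("cell_id"),
                            out / "wheel_coordinates.tsv", index=True),
    }
    record("score", t0, paths)

    # ---- inflammatory module score ------------------------------------------
    t0 = time.time()
    gsc = GeneSetCollection({"INFLAMMATORY_RESPONSE": list(INFLAMMATORY_PROGRAM)})
    write_gmt(gsc, out / "inflammatory.gmt")
    msv = modulescore.score_module(
        q_norm, gsc["INFLAMMATORY_RESPONSE"], params,
        seed=stage_seed(params.seed, "module_score"), name="INFLAMMATORY_RESPONSE")
    msum = modulescore.summarize_scores(msv, q_table_f)
    paths = {
        "gmt": out / "inflammatory.gmt",
        "scores": _write_tsv(msv.scores.rename_axis("cell_id").reset_index(),
                             out / "module_scores.tsv"),
        "summary": _write_tsv(msum, out / "module_score_summary.tsv"),
    }
    record("module_score", t0, paths)

    # ---- differential abundance: each MS region vs Control -------------------
    t0 = time.time()
    da_tables = []
    q_table_da = abundance.filter_replicates(q_table_f, "subtype", params)
    da_ids = set(q_table_da["cell_id"])
    for region in ("NAWM", "CA", "CA_edge", "CI", "CI_edge"):
        sel = (
            q_table_f["region"].isin([region, "Control"])
            & q_table_f["cell_id"].isin(da_ids)
        ).to_numpy()
        idx = np.nonzero(sel)[0]
        sub_emb = pp.Embedding(emb.coords[idx], emb.explained_var_frac,
                               emb.cell_ids[idx])
        sub_graph = pp.build_knn(sub_emb, params.knn_k)
        sub_table = q_table_f[sel].reset_index(drop=True)
        res = abundance.NeighborhoodDA(sub_emb, sub_graph, sub_table, params).fit(
            condition_key="region", level_a=region, level_b="Control",
            seed=stage_seed(params.seed, "da"),
        )
        tab = res.table.assign(contrast=f"{region}_vs_Control")
        da_tables.append(tab)
    da_all = pd.concat(da_tables, ignore_index=True)
    da_summary = (
        da_all.groupby(["contrast", "majority_label"])
        .agg(n=("log2fc", "size"), mean_log2fc=("log2fc", "mean"),
             flagged=("fdr", lambda s: int((s < 0.05).sum())))
        .reset_index()
    )
    paths = {
        "neighborhoods": _write_tsv(da_all, out / "da_neighborhoods.tsv"),
        "summary": _write_tsv(da_summary, out / "da_summary.tsv"),
    }
    record("da", t0, paths)

    # ---- cell communication --------------------------------------------------
    t0 = time.time()
    comm = communication.LigandReceptorAnalysis(q_norm, q_table_f, lr_table, params).fit(
        seed=stage_seed(params.seed, "cellcomm")
    )
    counts_long = []
    for region, mat in comm.counts().items():
        long = mat.rename_axis("sender").reset_index().melt(
            id_vars="sender", var_name="receiver", value_name="n_significant")
        long.insert(0, "region", region)
        counts_long.append(long)
    paths = {
        "interactions": _write_tsv(comm.table, out / "lr_interactions.tsv"),
        "counts": _write_tsv(pd.concat(counts_long, ignore_index=True),
                             out / "lr_counts.tsv"),
        "profile": _write_tsv(comm.profile(list(lr_table["pair_id"])),
                              out / "lr_profile.tsv"),
    }
    record("cellcomm", t0, paths)

    # ---- DEG + ORA: assigned Pre-OPC, NAWM vs Control -------------------------
    t0 = time.time()
    meta_ol = q_table_f[ol_mask].set_index("cell_id")
    assigned = scores.assigned
    pre_nawm = [c for c in assigned.index
                if assigned[c] == "Pre-OPC" and meta_ol.loc[c, "region"] == "NAWM"]
    pre_ctrl = [c for c in assigned.index
                if assigned[c] == "Pre-OPC" and meta_ol.loc[c, "region"] == "Control"]
    paths = {}
    if len(pre_nawm) >= 3 and len(pre_ctrl) >= 3:
        de = deg.wilcoxon_deg(q_norm, pre_nawm, pre_ctrl)
        up_std, down_std = deg.filter_degs(de, "standard", params)
        up_vol, down_vol = deg.filter_degs(de, "volcano", params)
        program_sets = GeneSetCollection(
            {f"PROGRAM_{k}": v for k, v in SUBTYPE_MARKERS.items()}
            | {"PROGRAM_INFLAMMATORY": list(INFLAMMATORY_PROGRAM)}
        )
        ora = deg.enrich_hypergeom(up_vol + down_vol, list(q_norm.gene_ids),
                                   program_sets)
        paths["deg"] = _write_tsv(de, out / "deg_preopc_nawm_vs_control.tsv")
        paths["deg_lists"] = out / "deg_lists.json"
        paths["deg_lists"].write_text(json.dumps(
            {"standard_up": up_std, "standard_down": down_std,
             "volcano_up": up_vol, "volcano_down": down_vol}, indent=2))
        if not ora.empty:
            paths["ora"] = _write_tsv(ora, out / "ora_preopc.tsv")
    record("deg", t0, paths)

    # ---- report ---------------------------------------------------------------
    comp_piv = composition.pivot_table(index="region", columns="label",
                                       values="fraction", fill_value=0.0)
    report = {
        "n_query_cells_post_qc": int(q_filt.n_cells),
        "n_clusters": int(clust.n_clusters),
        "lambda_star": model.lambda_,
        "cv_accuracy_at_lambda_star": float(
            model.sweep.loc[model.sweep["lam"] == model.lambda_, "cv_accuracy"].iloc[0]),
        "preopc_nfol_fraction_by_region": {
            r: float(comp_piv.loc[r].get("Pre-OPC", 0.0) + comp_piv.loc[r].get("NFOL", 0.0))
            for r in comp_piv.index
        },
        "significant_lr_rows": int(comm.table["significant"].sum()),
        "da_flagged_neighborhoods": int((da_all["fdr"] < 0.05).sum()),
    }
    (out / "summary.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    manifest["outputs"]["report/summary"] = {
        "path": str(out / "summary.json"), "sha256": _sha256(out / "summary.json")
    }
    manifest["total_wall_time_s"] = round(time.time() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("run_all complete in %.1fs -> %s", manifest["total_wall_time_s"], out)
    return manifest
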