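"""Shared fixtures: one synthetic study, generated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from oligoscore import (CountMatrix, PrototypeScorer, generate_lr_patterns,
                        generate_ms_query, generate_reference_atlas,
                        normalize_log, qc_filter)
from oligoscore.params import PipelineParams
from oligoscore.preprocess import NormMatrix
from oligoscore.simulate import SimConfig

SESSION_SEED = 7


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    return SimConfig(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def params() -> PipelineParams:
    return PipelineParams(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def reference(sim_cfg):
    return generate_reference_atlas(sim_cfg)


@pytest.fixture(scope="session")
def ref_norm(reference):
    counts, _, _ = reference
    return normalize_log(counts)


@pytest.fixture(scope="session")
def query(sim_cfg):
    """Query with the ligand-receptor patterns planted."""
    counts, table, truth = generate_ms_query(sim_cfg)
    lr_table, counts, truth = generate_lr_patterns(sim_cfg, counts, table, truth)
    return counts, table, truth, lr_table


@pytest.fixture(scope="session")
def query_norm(query):
    """QC-filtered, normalized query plus the matching metadata."""
    counts, table, _, _ = query
    filtered, _ = qc_filter(counts)
    nm = normalize_log(filtered)
    meta = table[table["cell_id"].isin(set(filtered.cell_ids))].reset_index(drop=True)
    return nm, meta


@pytest.fixture(scope="session")
def trained(ref_norm, reference):
    """Prototype model fitted on the full synthetic reference."""
    _, ref_table, _ = reference
    return PrototypeScorer(ref_norm, ref_table["subtype"].to_numpy()).fit(
        seed=SESSION_SEED
    )


@pytest.fixture(scope="session")
def query_ol_scores(trained, query_norm):
    """Similarity scores for the OL-lineage query cells."""
    nm, meta = query_norm
    ol = meta["cell_type"].isin(["OPC", "OL"]).to_numpy()
    idx = np.nonzero(ol)[0]
    nm_ol = NormMatrix(nm.values[:, idx], nm.gene_ids, nm.cell_ids[idx])
    return trained.score(nm_ol), meta[ol].reset_index(drop=True)


def make_counts(dense, gene_ids=None, cell_ids=None) -> CountMatrix:
    dense = np.asarray(dense)
    genes = gene_ids or [f"G{i}" for i in range(dense.shape[0])]
    cells = cell_ids or [f"c{i}" for i in range(dense.shape[1])]
    return CountMatrix(sp.csr_matrix(dense.astype(np.int64)), np.asarray(genes, dtype=object),
                       np.asarray(cells, dtype=object))


def make_norm(dense, gene_ids=None, cell_ids=None) -> NormMatrix:
    dense = np.asarray(dense, dtype=float)
    genes = gene_ids or [f"G{i}" for i in range(dense.shape[0])]
    cells = cell_ids or [f"c{i}" for i in range(dense.shape[1])]
    return NormMatrix(sp.csr_matrix(dense), np.asarray(genes, dtype=object),
                      np.asarray(cells, dtype=object))
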