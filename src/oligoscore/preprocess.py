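"""QC, normalization, feature selection, embedding, graph and clustering.

The stages follow the standard droplet/nucleus workflow: cells are kept if
they express 200-6,000 genes (inclusive) with a mitochondrial fraction
strictly below 5%; counts are log-normalized with a scale factor of
10,000 (natural log); highly variable genes are ranked by their variance
standardized within 20 equal-occupancy mean bins; PCA runs on centered,
unit-scaled (clamped at +10) HVG expression; the kNN graph uses exact
Euclidean neighbors (k = 15 by default) with index tie-breaking; and
communities come from Louvain modularity optimization at resolution 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, FormatError
from .params import PipelineParams

logger = logging.getLogger("oligoscore")


class PreprocessError(ValueError):
    """A preprocessing stage received degenerate input."""


# --------------------------------------------------------------------------
# Types


@dataclass
class NormMatrix:
    """Log-normalized expression: value = ln(1 + count / libsize * s)."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.values = sp.csr_matrix(self.values)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class HVGSet:
    """Genes ranked by standardized variance (highest first)."""

    genes: list[str]
    stat: np.ndarray  # standardized variance, aligned with genes


@dataclass
class Embedding:
    coords: np.ndarray               # cells x n_pcs
    explained_var_frac: np.ndarray   # per component, non-increasing
    cell_ids: np.ndarray


@dataclass
class KnnGraph:
    neighbors: np.ndarray        # cells x k directed neighbor indices
    adjacency: sp.csr_matrix     # symmetrized (union) boolean adjacency
    cell_ids: np.ndarray

    def graph_neighbors(self, i: int) -> np.ndarray:
        """Neighbors of cell i in the symmetrized graph."""
        return self.adjacency.indices[
            self.adjacency.indptr[i]: self.adjacency.indptr[i + 1]
        ]


@dataclass
class Clustering:
    labels: np.ndarray
    resolution: float
    modularity: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


# --------------------------------------------------------------------------
# QC


def qc_metrics(m: CountMatrix) -> pd.DataFrame:
    """Per-cell detected-gene counts, total counts and mitochondrial fraction."""
    vals = m.values.tocsc()
    vals.eliminate_zeros()
    detected = np.diff(vals.indptr)
    total = np.asarray(vals.sum(axis=0)).ravel()
    is_mt = np.array([str(g).startswith("MT-") for g in m.gene_ids])
    mt_total = np.asarray(vals[is_mt].sum(axis=0)).ravel() if is_mt.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mt_total / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {"cell_id": m.cell_ids, "n_genes": detected, "total_counts": total,
         "mito_frac": mito_frac}
    )


def qc_filter(
    m: CountMatrix, params: PipelineParams | None = None
) -> tuple[CountMatrix, dict]:
    """Keep cells with min_genes <= detected genes <= max_genes and
    mitochondrial fraction strictly below max_mito.

    Bounds on gene counts are inclusive; zero-count cells have mito
    fraction 0 by definition and fail the gene-count bound.  Idempotent.
    """
    params = params or PipelineParams()
    qc = qc_metrics(m)
    genes_ok = (qc["n_genes"] >= params.min_genes) & (qc["n_genes"] <= params.max_genes)
    mito_ok = qc["mito_frac"] < params.max_mito
    keep = (genes_ok & mito_ok).to_numpy()
    report = {
        "n_input": m.n_cells,
        "n_kept": int(keep.sum()),
        "n_fail_genes": int((~genes_ok).sum()),
        "n_fail_mito": int((~mito_ok).sum()),
    }
    logger.info("qc_filter: kept %d/%d cells (%d failed gene bounds, %d failed mito)",
                report["n_kept"], report["n_input"],
                report["n_fail_genes"], report["n_fail_mito"])
    if report["n_kept"] == 0:
        raise PreprocessError("QC removed every cell")
    return m.subset_cells(keep), report


# --------------------------------------------------------------------------
# Normalization


def normalize_log(m: CountMatrix, params: PipelineParams | None = None) -> NormMatrix:
    """Library-size normalize to ``scale_factor`` and take ln(1 + x)."""
    params = params or PipelineParams()
    libsize = np.asarray(m.values.sum(axis=0)).ravel().astype(float)
    if np.any(libsize == 0):
        raise PreprocessError(
            "cell(s) with zero total counts present; run qc_filter first"
        )
    vals = m.values.tocsc().astype(float)
    scale = params.scale_factor / libsize
    vals = (vals @ sp.diags(scale)).tocsr()
    vals.data = np.log1p(vals.data)
    return NormMatrix(vals, m.gene_ids, m.cell_ids)


# --------------------------------------------------------------------------
# HVG selection


def select_hvgs(nm: NormMatrix, n: int, n_bins: int = 20) -> HVGSet:
    """Rank genes by variance standardized against the mean-variance trend.

    Genes are ordered by mean expression and cut into ``n_bins``
    equal-occupancy bins; within each bin the variance is z-scored.  Ties
    are broken by raw variance (descending) then gene symbol (ascending),
    so the ranking is deterministic.
    """
    if n > nm.n_genes:
        raise PreprocessError(f"requested {n} HVGs from {nm.n_genes} genes")
    X = nm.values
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = np.maximum(sq - mean**2, 0.0)

    order_by_mean = np.argsort(mean, kind="stable")
    z = np.zeros(nm.n_genes)
    for bin_idx in np.array_split(order_by_mean, n_bins):
        if bin_idx.size == 0:
            continue
        v = var[bin_idx]
        sd = v.std()
        z[bin_idx] = (v - v.mean()) / max(sd, 1e-12)

    symbols = np.asarray(nm.gene_ids, dtype=str)
    rank = np.lexsort((symbols, -var, -z))
    top = rank[:n]
    return HVGSet(genes=[str(nm.gene_ids[i]) for i in top], stat=z[top])


# --------------------------------------------------------------------------
# PCA


def run_pca(
    nm: NormMatrix,
    hvgs: HVGSet | list[str],
    n_pcs: int,
    scale: bool = True,
    clamp: float = 10.0,
    allow_truncate: bool = False,
) -> Embedding:
    """PCA on centered (and unit-scaled, clamped at +``clamp``) HVG expression.

    Component signs are fixed by making the largest-magnitude gene loading
    positive.  If the data rank is below ``n_pcs`` an error is raised
    unless ``allow_truncate``.
    """
    genes = hvgs.genes if isinstance(hvgs, HVGSet) else list(hvgs)
    gi = nm.gene_index()
    missing = [g for g in genes if g not in gi]
    if missing:
        raise PreprocessError(f"HVG(s) absent from matrix: {missing[:5]}")
    rows = [gi[g] for g in genes]
    X = nm.values[rows].toarray().T.astype(float)  # cells x genes
    n_cells, n_genes = X.shape
    if n_pcs > min(n_cells, n_genes):
        raise PreprocessError(
            f"n_pcs={n_pcs} exceeds min(n_cells={n_cells}, n_genes={n_genes})"
        )
    X -= X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=0)
        X /= np.maximum(sd, 1e-12)
        np.minimum(X, clamp, out=X)
        X -= X.mean(axis=0)  # re-center after clamping

    total_var = (X**2).sum() / max(n_cells - 1, 1)
    # eigendecompose on the smaller side for speed; both give exact PCA
    if n_genes <= n_cells:
        cov = (X.T @ X) / max(n_cells - 1, 1)
        evals, evecs = np.linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        loadings = evecs
    else:
        gram = (X @ X.T) / max(n_cells - 1, 1)
        evals, u = np.linalg.eigh(gram)
        evals, u = evals[::-1], u[:, ::-1]
        with np.errstate(invalid="ignore", divide="ignore"):
            loadings = X.T @ u / np.sqrt(np.maximum(evals, 1e-300) * max(n_cells - 1, 1))
    evals = np.maximum(evals, 0.0)
    rank = int((evals > max(evals.max(), 1e-300) * 1e-10).sum())
    if n_pcs > rank:
        if not allow_truncate:
            raise PreprocessError(
                f"data rank {rank} is below requested n_pcs={n_pcs}; "
                "pass allow_truncate=True to truncate"
            )
        logger.warning("run_pca: truncating n_pcs from %d to rank %d", n_pcs, rank)
        n_pcs = rank

    L = loadings[:, :n_pcs].copy()
    for j in range(n_pcs):
        top = np.argmax(np.abs(L[:, j]))
        if L[top, j] < 0:
            L[:, j] = -L[:, j]
    coords = X @ L
    frac = evals[:n_pcs] / max(total_var, 1e-300)
    return Embedding(coords=coords, explained_var_frac=frac, cell_ids=nm.cell_ids)


# --------------------------------------------------------------------------
# kNN graph


def build_knn(e: Embedding, k: int, block: int = 1024) -> KnnGraph:
    """Exact Euclidean k nearest neighbors with index tie-breaking.

    Distance ties are resolved toward the lower cell index (stable sort);
    the undirected graph is the union symmetrization of the directed kNN
    relation, so degrees may exceed k.  No self-edges.
    """
    n = e.coords.shape[0]
    if k >= n:
        raise PreprocessError(f"k={k} must be below n_cells={n}")
    if k < 1:
        raise PreprocessError("k must be >= 1")
    X = e.coords
    sq = (X**2).sum(axis=1)
    neighbors = np.empty((n, k), dtype=np.int64)
    for start in range(0, n, block):
        stop = min(start + block, n)
        d2 = sq[start:stop, None] - 2.0 * (X[start:stop] @ X.T) + sq[None, :]
        np.maximum(d2, 0.0, out=d2)
        for i in range(start, stop):
            row = d2[i - start].copy()
            row[i] = np.inf  # exclude self
            order = np.argsort(row, kind="stable")
            neighbors[i] = order[:k]
    rows = np.repeat(np.arange(n), k)
    cols = neighbors.ravel()
    adj = sp.coo_matrix((np.ones(n * k, dtype=bool), (rows, cols)), shape=(n, n))
    adj = ((adj + adj.T) > 0).tocsr()
    adj.setdiag(False)
    adj.eliminate_zeros()
    return KnnGraph(neighbors=neighbors, adjacency=adj, cell_ids=e.cell_ids)


# --------------------------------------------------------------------------
# Louvain clustering


def cluster_louvain(g: KnnGraph, resolution: float, seed: int) -> Clustering:
    """Louvain modularity communities at the given resolution.

    Deterministic given the seed; disconnected components are handled
    independently by the algorithm.  Cluster ids are contiguous from 0,
    ordered by each community's smallest cell index.
    """
    n = g.adjacency.shape[0]
    if n == 0:
        raise PreprocessError("empty graph")
    G = nx.from_scipy_sparse_array(g.adjacency)
    comms = nx.community.louvain_communities(G, resolution=resolution, seed=int(seed))
    comms = sorted(comms, key=min)
    labels = np.empty(n, dtype=np.int64)
    for cid, members in enumerate(comms):
        labels[list(members)] = cid
    mod = nx.community.modularity(G, comms, resolution=resolution)
    logger.info("cluster_louvain: %d clusters, modularity %.4f (resolution %.2f)",
                len(comms), mod, resolution)
    return Clustering(labels=labels, resolution=resolution, modularity=mod)


# --------------------------------------------------------------------------
# Marker-based cluster annotation


def annotate_clusters(
    nm: NormMatrix,
    clustering: Clustering,
    marker_table: Mapping[str, list[str]],
) -> dict[int, str]:
    """Assign each cluster the cell type whose markers score highest.

    Per marker gene, the mean normalized expression per cluster is z-scored
    across clusters; a type's score in a cluster is the mean z over its
    markers present in the matrix.  Ties break alphabetically with a
    warning; markers absent from the matrix are logged and skipped.
    """
    gi = nm.gene_index()
    labels = clustering.labels
    n_clusters = clustering.n_clusters
    onehot = sp.csr_matrix(
        (np.ones(len(labels)), (np.arange(len(labels)), labels)),
        shape=(len(labels), n_clusters),
    )
    sizes = np.asarray(onehot.sum(axis=0)).ravel()

    any_marker = False
    scores = pd.DataFrame(index=range(n_clusters), columns=list(marker_table), dtype=float)
    for cell_type, genes in marker_table.items():
        present = [g for g in genes if g in gi]
        absent = [g for g in genes if g not in gi]
        if absent:
            logger.warning("annotate_clusters: %s marker(s) missing for %s: %s",
                           len(absent), cell_type, absent)
        if not present:
            scores[cell_type] = -np.inf
            continue
        any_marker = True
        expr = nm.values[[gi[g] for g in present]]  # genes x cells
        per_cluster = (expr @ onehot).toarray() / np.maximum(sizes, 1)[None, :]
        z = (per_cluster - per_cluster.mean(axis=1, keepdims=True)) / np.maximum(
            per_cluster.std(axis=1, keepdims=True), 1e-12
        )
        scores[cell_type] = z.mean(axis=0)
    if not any_marker:
        raise PreprocessError("no marker gene of any cell type found in the matrix")

    assignment: dict[int, str] = {}
    for c in range(n_clusters):
        row = scores.loc[c]
        best = row.max()
        winners = sorted(row.index[row == best])
        if len(winners) > 1:
            logger.warning("annotate_clusters: tie in cluster %d between %s; taking %s",
                           c, winners, winners[0])
        assignment[c] = winners[0]
    return assignment
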