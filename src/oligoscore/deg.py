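"""Wilcoxon rank-sum differential expression and GMT over-representation.

Differential expression between two cell groups uses the two-sided
Wilcoxon rank-sum test (exact enumeration for tie-free groups of up to 8
cells each, otherwise the tie-corrected normal approximation) with
Benjamini-Hochberg adjustment across genes.  The log2 fold change is
computed on de-logged means with a pseudocount of 1, so it stays finite
for zero-expression groups and swaps sign exactly when the groups swap.

Two filtering conventions are provided: the "standard" DEG call
(adjusted p < 0.05 and |log2FC| > 0.5) and the "volcano" call
(|log2FC| > 0.585 and -log10 raw p > 1.5); both use strict inequalities.

Over-representation of a query gene list in GMT gene sets is the
hypergeometric upper tail P[X >= k], BH-adjusted across sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection
from .params import PipelineParams
from .preprocess import NormMatrix
from .stats_util import bh_adjust

logger = logging.getLogger("oligoscore")


class DEGError(ValueError):
    pass


EXACT_MAX_N = 8


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p-value.

    Exact null enumeration when both groups have <= 8 observations and no
    ties; otherwise the tie-corrected normal approximation with
    continuity correction.  A completely constant gene returns p = 1.
    """
    pooled = np.concatenate([a, b])
    if pooled.min() == pooled.max():
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(a) <= EXACT_MAX_N and len(b) <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def wilcoxon_deg(
    nm: NormMatrix,
    cells_a,
    cells_b,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene rank-sum DE between two disjoint cell groups.

    Returns log2FC (de-logged means, pseudocount 1), raw and BH-adjusted
    p-values, and the detection fraction in each group.
    """
    ids = {c: i for i, c in enumerate(nm.cell_ids)}
    ia = np.asarray([ids[c] for c in cells_a])
    ib = np.asarray([ids[c] for c in cells_b])
    if len(ia) < 3 or len(ib) < 3:
        raise DEGError("both groups need at least 3 cells")
    if set(ia) & set(ib):
        raise DEGError("groups overlap")

    gi = nm.gene_index()
    gene_rows = (
        [(g, gi[g]) for g in genes] if genes is not None
        else list(zip(nm.gene_ids, range(nm.n_genes)))
    )
    A = nm.values[:, ia].toarray()
    B = nm.values[:, ib].toarray()
    rows = []
    for g, r in gene_rows:
        a, b = A[r], B[r]
        p = _rank_sum_p(a, b)
        mean_a = float(np.expm1(a).mean())
        mean_b = float(np.expm1(b).mean())
        lfc = float(np.log2((mean_a + 1.0) / (mean_b + 1.0)))
        rows.append(
            {
                "gene": g,
                "log2fc": lfc,
                "p_value": p,
                "pct_a": float((a > 0).mean()),
                "pct_b": float((b > 0).mean()),
            }
        )
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["p_value"].to_numpy())
    out["direction"] = np.where(out["log2fc"] > 0, "up", np.where(out["log2fc"] < 0, "down", "none"))
    return out


def filter_degs(
    result: pd.DataFrame,
    mode: str = "standard",
    params: PipelineParams | None = None,
) -> tuple[list[str], list[str]]:
    """Split a DE table into (up, down) gene lists.

    "standard" uses adjusted p < deg_padj and |log2FC| > deg_lfc;
    "volcano" uses raw p (-log10 p > volcano_neglogp) and
    |log2FC| > volcano_lfc.  All inequalities are strict.
    """
    params = params or PipelineParams()
    if result.empty:
        return [], []
    if mode == "standard":
        sig = (result["padj"] < params.deg_padj) & (result["log2fc"].abs() > params.deg_lfc)
        logger.info("filter_degs: standard mode (adjusted p < %g, |log2FC| > %g)",
                    params.deg_padj, params.deg_lfc)
    elif mode == "volcano":
        with np.errstate(divide="ignore"):
            neglogp = -np.log10(result["p_value"].to_numpy())
        sig = pd.Series(neglogp > params.volcano_neglogp, index=result.index) & (
            result["log2fc"].abs() > params.volcano_lfc
        )
        logger.info("filter_degs: volcano mode (raw p; -log10 p > %g, |log2FC| > %g)",
                    params.volcano_neglogp, params.volcano_lfc)
    else:
        raise DEGError(f"unknown mode {mode!r}")
    up = result.loc[sig & (result["log2fc"] > 0), "gene"].tolist()
    down = result.loc[sig & (result["log2fc"] < 0), "gene"].tolist()
    return up, down


def enrich_hypergeom(
    query_genes: list[str],
    universe_genes: list[str],
    sets: GeneSetCollection,
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in gene sets.

    p = P[X >= k] with X ~ Hypergeometric(N = |universe|, K = |set|,
    n = |query|); sets are intersected with the universe first and those
    smaller than ``min_set_size`` after intersection are skipped.  BH
    adjusts across the tested sets.
    """
    universe = list(dict.fromkeys(universe_genes))
    if not universe:
        raise DEGError("empty universe")
    uni = set(universe)
    query = list(dict.fromkeys(query_genes))
    outside = [g for g in query if g not in uni]
    if outside:
        logger.warning("enrich_hypergeom: %d query gene(s) outside universe dropped",
                       len(outside))
    query = [g for g in query if g in uni]
    N, n = len(uni), len(query)

    rows = []
    for name, genes in sets.sets.items():
        members = uni & set(genes)
        K = len(members)
        if K < min_set_size:
            continue
        k = len(members & set(query))
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N, "p_value": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out
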