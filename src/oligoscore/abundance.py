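"""Neighborhood-level differential abundance on the kNN graph.

Local neighborhoods (an index cell plus its graph neighbors on the
k = 15 kNN graph) are sampled at a fixed proportion of cells and refined
toward their embedding centroid, as in neighborhood-based differential
abundance pipelines.  Each neighborhood is then tested for condition
imbalance with a two-sided Fisher exact test on the 2x2 table
(cells in/out of the neighborhood x condition), with BH correction
across neighborhoods.  This is a deliberately simple, exactly testable
replacement for a negative-binomial GLM on per-sample neighborhood
counts; neighborhoods may overlap and no graph-aware FDR weighting is
applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .params import PipelineParams
from .preprocess import Embedding, KnnGraph
from .stats_util import bh_adjust

logger = logging.getLogger("oligoscore")


class AbundanceError(ValueError):
    pass


# --------------------------------------------------------------------------


def filter_replicates(
    cell_table: pd.DataFrame,
    group_key: str,
    params: PipelineParams | None = None,
) -> pd.DataFrame:
    """Drop cell groups present in fewer than ``min_replicates`` samples."""
    params = params or PipelineParams()
    reps = cell_table.groupby(group_key)["sample_id"].nunique()
    drop = reps.index[reps < params.min_replicates].tolist()
    if drop:
        logger.info("filter_replicates: dropping %s (%s) with < %d replicates",
                    drop, group_key, params.min_replicates)
    kept = cell_table[~cell_table[group_key].isin(drop)]
    if kept.empty:
        raise AbundanceError("replicate filtering removed every cell")
    return kept.reset_index(drop=True)


# --------------------------------------------------------------------------


@dataclass
class NeighborhoodSet:
    """Sampled, refined neighborhoods and their per-sample count matrix."""

    index_cells: np.ndarray            # refined index cell positions
    members: list[np.ndarray]          # per neighborhood: index cell + graph neighbors
    sample_counts: pd.DataFrame        # neighborhood x sample_id
    cell_ids: np.ndarray


def sample_neighborhoods(
    g: KnnGraph,
    e: Embedding,
    cell_table: pd.DataFrame | None = None,
    prop: float = 0.1,
    seed: int = 0,
) -> NeighborhoodSet:
    """Sample index cells, refine them toward the neighborhood centroid.

    A fraction ``prop`` of cells is drawn uniformly; each draw is replaced
    by the member of its neighborhood closest to the neighborhood's
    embedding mean (one pass, ties to the lower cell index), duplicates
    are collapsed, and each final neighborhood is the refined index cell
    plus its graph neighbors.
    """
    n = len(g.cell_ids)
    if not (0 < prop <= 1):
        raise AbundanceError("prop must lie in (0, 1]")
    n_index = int(np.floor(prop * n))
    if n_index < 1:
        raise AbundanceError(f"prop={prop} yields no index cells for n={n}")
    rng = np.random.default_rng(seed)
    drawn = rng.choice(n, size=n_index, replace=False)

    refined = []
    for i in drawn:
        members = np.concatenate([[i], g.graph_neighbors(i)])
        center = e.coords[members].mean(axis=0)
        d2 = ((e.coords[members] - center) ** 2).sum(axis=1)
        # stable argmin, then lower cell index on exact ties
        best = members[np.lexsort((members, d2))[0]]
        refined.append(best)
    refined = np.unique(np.asarray(refined, dtype=np.int64))

    members = [np.sort(np.concatenate([[i], g.graph_neighbors(i)])) for i in refined]
    if cell_table is not None:
        samples = cell_table.set_index("cell_id").loc[list(g.cell_ids), "sample_id"].to_numpy()
        sample_levels = sorted(set(samples))
        counts = np.zeros((len(refined), len(sample_levels)), dtype=np.int64)
        col = {s: j for j, s in enumerate(sample_levels)}
        for r, mem in enumerate(members):
            for m in mem:
                counts[r, col[samples[m]]] += 1
        sample_counts = pd.DataFrame(counts, columns=sample_levels)
    else:
        sample_counts = pd.DataFrame(index=range(len(refined)))
    logger.info("sample_neighborhoods: %d neighborhoods (prop=%.2f, refined from %d draws)",
                len(refined), prop, n_index)
    return NeighborhoodSet(index_cells=refined, members=members,
                           sample_counts=sample_counts, cell_ids=g.cell_ids)


# --------------------------------------------------------------------------


def test_da(
    nset: NeighborhoodSet,
    cell_table: pd.DataFrame,
    condition_key: str = "condition",
    level_a: str | None = None,
    level_b: str | None = None,
    annotate_by: str = "subtype",
    params: PipelineParams | None = None,
) -> pd.DataFrame:
    """Fisher-exact differential abundance per neighborhood.

    For each neighborhood the 2x2 table (in/out x condition A/B) is tested
    two-sided; log2FC compares in-neighborhood proportions of the two
    conditions with pseudo-proportion 0.5/min(N_A, N_B).  BH adjusts
    across neighborhoods and each row carries the neighborhood's majority
    ``annotate_by`` label.
    """
    meta = cell_table.set_index("cell_id").loc[list(nset.cell_ids)]
    cond = meta[condition_key].to_numpy()
    levels = [lv for lv in pd.unique(cond)]
    if level_a is None or level_b is None:
        if len(levels) != 2:
            raise AbundanceError(
                f"{condition_key} has {len(levels)} levels; pass level_a/level_b"
            )
        level_a, level_b = levels
    in_a, in_b = cond == level_a, cond == level_b
    N_a, N_b = int(in_a.sum()), int(in_b.sum())
    if N_a == 0 or N_b == 0:
        raise AbundanceError("one condition has no cells")
    labels = meta[annotate_by].to_numpy()
    ps = 0.5 / min(N_a, N_b)

    rows = []
    for idx, mem in zip(nset.index_cells, nset.members):
        sel = np.zeros(len(cond), dtype=bool)
        sel[mem] = True
        use = sel & (in_a | in_b)
        na_in = int((sel & in_a).sum())
        nb_in = int((sel & in_b).sum())
        table = [[na_in, nb_in], [N_a - na_in, N_b - nb_in]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        lfc = float(np.log2((na_in / N_a + ps) / (nb_in / N_b + ps)))
        vals, cnts = np.unique(labels[mem], return_counts=True)
        majority = sorted(vals[cnts == cnts.max()])[0]
        rows.append(
            {"index_cell": int(idx), "cell_id": nset.cell_ids[idx], "size": len(mem),
             "n_in_a": na_in, "n_in_b": nb_in, "log2fc": lfc, "p_value": p,
             "majority_label": majority}
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    return out


def summarize_da(result: pd.DataFrame, by_label: str = "majority_label",
                 fdr: float = 0.05) -> pd.DataFrame:
    """Per-label distribution of neighborhood log2FCs and flagged fractions."""
    rows = []
    for label, grp in result.groupby(by_label, sort=True):
        rows.append(
            {
                by_label: label,
                "n_neighborhoods": len(grp),
                "mean_log2fc": grp["log2fc"].mean(),
                "median_log2fc": grp["log2fc"].median(),
                "flagged_fraction": float((grp["fdr"] < fdr).mean()),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Model/Results wrapper


class NeighborhoodDA:
    """Differential-abundance model over a kNN graph (statsmodels-style)."""

    def __init__(
        self,
        embedding: Embedding,
        graph: KnnGraph,
        cell_table: pd.DataFrame,
        params: PipelineParams | None = None,
    ):
        self.embedding = embedding
        self.graph = graph
        self.cell_table = cell_table
        self.params = params or PipelineParams()

    def fit(
        self,
        condition_key: str = "condition",
        level_a: str | None = None,
        level_b: str | None = None,
        prop: float = 0.1,
        seed: int | None = None,
        annotate_by: str = "subtype",
    ) -> "DAResults":
        seed = self.params.seed if seed is None else seed
        nset = sample_neighborhoods(self.graph, self.embedding, self.cell_table,
                                    prop=prop, seed=seed)
        table = test_da(nset, self.cell_table, condition_key, level_a, level_b,
                        annotate_by, self.params)
        return DAResults(table=table, neighborhoods=nset)


@dataclass
class DAResults:
    table: pd.DataFrame
    neighborhoods: NeighborhoodSet
    fdr_threshold: float = field(default=0.05)

    def summarize(self, by_label: str = "majority_label",
                  fdr: float | None = None) -> pd.DataFrame:
        return summarize_da(self.table, by_label, fdr or self.fdr_threshold)

    def summary(self) -> str:
        flagged = int((self.table["fdr"] < self.fdr_threshold).sum())
        lines = [
            "Neighborhood differential abundance (Fisher exact, BH)",
            "=" * 54,
            f"neighborhoods:  {len(self.table)}",
            f"median size:    {self.table['size'].median():.0f}",
            f"flagged (FDR<{self.fdr_threshold:g}): {flagged}",
        ]
        return "\n".join(lines)
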