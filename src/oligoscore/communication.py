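"""Ligand-receptor communication scoring between cell types, per region.

For every (pair, sender type, receiver type) within a region, the
statistic is the half-sum of the mean normalized ligand expression in the
sender type and the mean receptor expression in the receiver type.  A
combination is tested only if the ligand is detected in at least 10% of
sender cells and the receptor in at least 10% of receiver cells.  The
null distribution comes from shuffling cell-type labels within the region
(1,000 permutations by default, shared across combinations as in the
standard tooling); the permutation p-value uses the add-one convention,
so it is never 0 and never exceeds 1.  Regions are analyzed separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import validate_lr_table
from .params import PipelineParams
from .preprocess import NormMatrix

logger = logging.getLogger("oligoscore")


class CommunicationError(ValueError):
    pass


def pair_statistic(
    nm: NormMatrix,
    labels: np.ndarray,
    pair: tuple[str, str],
    sender: str,
    receiver: str,
    params: PipelineParams | None = None,
) -> tuple[float | None, float, float]:
    """(mean_stat or None if gated out, pct_ligand, pct_receptor)."""
    params = params or PipelineParams()
    ligand, receptor = pair
    gi = nm.gene_index()
    for g in (ligand, receptor):
        if g not in gi:
            raise CommunicationError(f"gene {g!r} absent from the matrix")
    labels = np.asarray(labels, dtype=object)
    s_cells = np.nonzero(labels == sender)[0]
    r_cells = np.nonzero(labels == receiver)[0]
    if s_cells.size == 0 or r_cells.size == 0:
        raise CommunicationError("sender/receiver type has no cells")
    lig = nm.values[gi[ligand]].toarray().ravel()
    rec = nm.values[gi[receptor]].toarray().ravel()
    pct_l = float((lig[s_cells] > 0).mean())
    pct_r = float((rec[r_cells] > 0).mean())
    if pct_l < params.min_expr_frac or pct_r < params.min_expr_frac:
        return None, pct_l, pct_r
    stat = 0.5 * (float(lig[s_cells].mean()) + float(rec[r_cells].mean()))
    return stat, pct_l, pct_r


@dataclass
class InteractionResults:
    """Per (region, pair, sender, receiver) permutation results."""

    table: pd.DataFrame
    n_perm: int
    alpha: float = 0.05

    def counts(self) -> dict[str, pd.DataFrame]:
        """Per-region sender x receiver matrices of significant-pair counts."""
        out = {}
        for region, grp in self.table.groupby("region", sort=True):
            types = sorted(set(grp["sender"]) | set(grp["receiver"]))
            mat = pd.DataFrame(0, index=types, columns=types, dtype=int)
            sig = grp[grp["significant"] == True]  # noqa: E712
            for _, row in sig.iterrows():
                mat.loc[row["sender"], row["receiver"]] += 1
            out[region] = mat
        return out

    def profile(self, pair_ids: list[str]) -> pd.DataFrame:
        """Dot-plot style long table (mean_stat, -log10 p) for named pairs."""
        known = set(self.table["pair_id"])
        unknown = [p for p in pair_ids if p not in known]
        if unknown:
            raise CommunicationError(f"unknown pair_id(s): {unknown}")
        sub = self.table[self.table["pair_id"].isin(pair_ids)].copy()
        with np.errstate(divide="ignore"):
            sub["neglog10_p"] = np.where(
                sub["tested"], -np.log10(sub["p_value"]), np.nan
            )
        return sub.reset_index(drop=True)

    def summary(self) -> str:
        tested = int(self.table["tested"].sum())
        sig = int((self.table["significant"] == True).sum())  # noqa: E712
        lines = [
            "Ligand-receptor permutation analysis",
            "=" * 38,
            f"hypotheses:     {len(self.table)} ({tested} tested after the "
            f"expression gate)",
            f"significant:    {sig} at p < {self.alpha:g} ({self.n_perm} permutations)",
            f"regions:        {', '.join(sorted(set(self.table['region'])))}",
        ]
        return "\n".join(lines)


class LigandReceptorAnalysis:
    """Permutation model of cell-type communication (statsmodels-style)."""

    def __init__(
        self,
        nm: NormMatrix,
        cell_table: pd.DataFrame,
        lr_table: pd.DataFrame,
        params: PipelineParams | None = None,
        type_key: str = "cell_type",
        region_key: str = "region",
    ):
        validate_lr_table(lr_table)
        self.nm = nm
        self.cell_table = cell_table.set_index("cell_id").loc[list(nm.cell_ids)]
        self.lr_table = lr_table.reset_index(drop=True)
        self.params = params or PipelineParams()
        self.type_key = type_key
        self.region_key = region_key
        gi = nm.gene_index()
        for _, row in lr_table.iterrows():
            for g in (row["ligand_gene"], row["receptor_gene"]):
                if g not in gi:
                    raise CommunicationError(f"gene {g!r} absent from the matrix")

    def fit(self, seed: int | None = None, regions: list[str] | None = None,
            alpha: float = 0.05) -> InteractionResults:
        params = self.params
        seed = params.seed if seed is None else seed
        gi = self.nm.gene_index()
        genes = sorted(
            set(self.lr_table["ligand_gene"]) | set(self.lr_table["receptor_gene"])
        )
        gcol = {g: j for j, g in enumerate(genes)}
        E_all = self.nm.values[[gi[g] for g in genes]].toarray().T  # cells x genes

        region_vals = self.cell_table[self.region_key].to_numpy()
        type_vals = self.cell_table[self.type_key].to_numpy(dtype=object)
        regions = regions or sorted(pd.unique(region_vals))

        rows = []
        ss = np.random.SeedSequence(seed)
        cell_ids = np.asarray(self.cell_table.index, dtype=object)
        for region, child in zip(regions, ss.spawn(len(regions))):
            rng = np.random.default_rng(child)
            in_region = np.nonzero(region_vals == region)[0]
            # canonical cell order, so permutation p-values do not depend on
            # the input column ordering
            in_region = in_region[np.argsort(cell_ids[in_region].astype(str), kind="stable")]
            E = E_all[in_region]
            labels = type_vals[in_region]
            types, codes = np.unique(labels, return_inverse=True)
            type_counts = np.bincount(codes, minlength=len(types))
            if (type_counts == 0).any():
                logger.warning("cellcomm: empty type dropped in region %s", region)
            T = len(types)
            tpos = {t: i for i, t in enumerate(types)}

            sums = np.zeros((T, len(genes)))
            np.add.at(sums, codes, E)
            means = sums / type_counts[:, None]
            pos = np.zeros((T, len(genes)))
            np.add.at(pos, codes, E > 0)
            pct = pos / type_counts[:, None]

            # enumerate hypotheses for this region
            hyp = []  # (pair_id, sender, receiver, lig_col, rec_col, tested, obs, pct_l, pct_r)
            for _, pr in self.lr_table.iterrows():
                lc, rc = gcol[pr["ligand_gene"]], gcol[pr["receptor_gene"]]
                for s in types:
                    for r in types:
                        pct_l = pct[tpos[s], lc]
                        pct_r = pct[tpos[r], rc]
                        tested = (pct_l >= params.min_expr_frac
                                  and pct_r >= params.min_expr_frac)
                        obs = 0.5 * (means[tpos[s], lc] + means[tpos[r], rc])
                        hyp.append([pr["pair_id"], s, r, lc, rc, tested, obs,
                                    pct_l, pct_r])

            tested_idx = [i for i, h in enumerate(hyp) if h[5]]
            ge_counts = np.zeros(len(tested_idx), dtype=np.int64)
            if tested_idx:
                s_pos = np.array([tpos[hyp[i][1]] for i in tested_idx])
                r_pos = np.array([tpos[hyp[i][2]] for i in tested_idx])
                l_col = np.array([hyp[i][3] for i in tested_idx])
                r_col = np.array([hyp[i][4] for i in tested_idx])
                obs = np.array([hyp[i][6] for i in tested_idx])
                for _ in range(params.n_perm):
                    perm = rng.permutation(codes)
                    psums = np.zeros((T, len(genes)))
                    np.add.at(psums, perm, E)
                    pmeans = psums / type_counts[:, None]
                    pstat = 0.5 * (pmeans[s_pos, l_col] + pmeans[r_pos, r_col])
                    ge_counts += pstat >= obs - 1e-12
            pvals = (1.0 + ge_counts) / (1.0 + params.n_perm)

            pmap = dict(zip(tested_idx, pvals))
            for i, h in enumerate(hyp):
                tested = h[5]
                p = float(pmap[i]) if tested else np.nan
                rows.append(
                    {
                        "region": region,
                        "pair_id": h[0],
                        "sender": h[1],
                        "receiver": h[2],
                        "mean_stat": h[6] if tested else np.nan,
                        "pct_ligand": h[7],
                        "pct_receptor": h[8],
                        "tested": tested,
                        "p_value": p,
                        "significant": bool(tested and p < alpha),
                    }
                )
        table = pd.DataFrame(rows)
        logger.info("cellcomm: %d hypotheses (%d tested, %d significant) across %d regions",
                    len(table), int(table["tested"].sum()),
                    int(table["significant"].sum()), len(regions))
        return InteractionResults(table=table, n_perm=params.n_perm, alpha=alpha)


def permutation_test(
    nm: NormMatrix,
    cell_table: pd.DataFrame,
    lr_table: pd.DataFrame,
    params: PipelineParams | None = None,
    seed: int | None = None,
    regions: list[str] | None = None,
) -> InteractionResults:
    """Functional entry point for the label-permutation interaction test."""
    return LigandReceptorAnalysis(nm, cell_table, lr_table, params).fit(
        seed=seed, regions=regions
    )


def interaction_counts(result: InteractionResults) -> dict[str, pd.DataFrame]:
    return result.counts()


def pair_region_profile(result: InteractionResults, pair_ids: list[str]) -> pd.DataFrame:
    return result.profile(pair_ids)
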