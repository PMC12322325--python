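"""Synthetic snRNA-seq data with the statistical structure the analysis assumes.

Two datasets are generated: a developmental reference atlas carrying seven
oligodendrocyte-lineage subtypes defined by their canonical marker programs
(pre-OPC, dividing-OPC, late-OPC, COP, NFOL, MFOL, MOL), and a six-region
adult query (Control, NAWM, chronic-active and chronic-inactive lesion
cores and edges) in which pre-OPC and NFOL are present in Control/NAWM,
absent from lesion cores, and rare at lesion edges; microglia split into an
inflamed and a homeostatic state; and three ligand-receptor axes
(SIRPA-CD47, CD74-MIF, CSF1R-CSF1) switch on and off by region.

Counts are negative-binomial (gamma-Poisson) per gene with log-normal
library-size factors; the 13 "MT-" genes are scaled per cell to hit a
Beta-distributed mitochondrial fraction, so QC filtering has realistic
work to do.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import REGIONS, CountMatrix, FormatError, validate_cell_table
from .params import ConfigError

# --------------------------------------------------------------------------
# Gene programs

SUBTYPE_MARKERS: dict[str, list[str]] = {
    "Pre-OPC": ["EGFR", "NES", "ZFP36L1", "GFAP"],
    "Dividing-OPC": ["MKI67", "ASPM", "TOP2A", "CDK1"],
    "Late-OPC": ["SOX10", "NKX2-2", "PCDH15", "CSPG4"],
    "COP": ["NEU4", "SOX6", "GPR17"],
    "NFOL": ["TCF7L2", "ITPR2", "TMEM2", "GPR17"],
    "MFOL": ["MAL", "MOG", "PLP1", "OPALIN", "SERINC5"],
    "MOL": ["KLK6", "APOD", "FAR1", "PMP22"],
}
# GPR17 is deliberately shared between COP and NFOL, making those two the
# hardest classes to separate (a known limit of transitional states).

OL_SUBTYPES = tuple(SUBTYPE_MARKERS)

MAJOR_MARKERS: dict[str, list[str]] = {
    "OL": ["PLP1", "MBP", "TMEM144", "CNP", "MOBP", "MAG"],
    "OPC": ["PCDH15", "PDGFRA", "BCAN", "SOX6", "OLIG1"],
    "MG": ["P2RY12", "CX3CR1", "C3"],
    "AST": ["GFAP", "AQP4", "ADGRV1"],
}

SUBTYPE_TO_MAJOR: dict[str, str] = {
    "Pre-OPC": "OPC",
    "Dividing-OPC": "OPC",
    "Late-OPC": "OPC",
    "COP": "OL",
    "NFOL": "OL",
    "MFOL": "OL",
    "MOL": "OL",
    "MG_homeostatic": "MG",
    "MG_inflamed": "MG",
    "AST": "AST",
}

INFLAMMATORY_PROGRAM: list[str] = [
    "TNF", "IL1B", "IL6", "CCL2", "CCL3", "CCL4", "CCL5", "CXCL8",
    "CXCL9", "CXCL10", "NFKB1", "RELB", "TLR2", "TLR4", "IRF1", "STAT1",
    "ICAM1", "PTGS2", "IL18", "TNFAIP3", "SOCS3", "NLRP3", "IL10RA",
    "IFNGR1",
]

LR_GENES: list[str] = ["SIRPA", "CD47", "MIF", "CD74", "CSF1", "CSF1R"]

# Subtypes that carry an exclusive broad expression program (beyond their
# canonical markers): the seven OL-lineage states plus microglia and
# astrocytes.  Real cell states differ across hundreds of genes, not only
# their confident markers; the broad programs give each state a realistic
# transcriptome-wide footprint.
PROGRAM_SUBTYPES: tuple[str, ...] = OL_SUBTYPES + ("MG", "AST")

MT_GENES: list[str] = [
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8", "MT-CYB",
]


def _default_region_composition() -> dict[str, dict[str, float]]:
    # Fractions per region over the ten query subtypes; MG is split into
    # inflamed/homeostatic afterwards.  Pre-OPC and NFOL are planted at
    # zero in lesion cores, small at edges; MOL reduced in cores; MG and
    # AST expanded in lesions (MG 3-fold in CA vs Control).
    return {
        "Control": {"Pre-OPC": 0.10, "Late-OPC": 0.10, "COP": 0.05, "NFOL": 0.10,
                    "MFOL": 0.15, "MOL": 0.30, "MG": 0.15, "AST": 0.05},
        "NAWM":    {"Pre-OPC": 0.12, "Late-OPC": 0.10, "COP": 0.05, "NFOL": 0.12,
                    "MFOL": 0.13, "MOL": 0.23, "MG": 0.20, "AST": 0.05},
        "CA":      {"Pre-OPC": 0.00, "Late-OPC": 0.05, "COP": 0.02, "NFOL": 0.00,
                    "MFOL": 0.08, "MOL": 0.15, "MG": 0.45, "AST": 0.25},
        "CA_edge": {"Pre-OPC": 0.04, "Late-OPC": 0.08, "COP": 0.04, "NFOL": 0.04,
                    "MFOL": 0.12, "MOL": 0.28, "MG": 0.28, "AST": 0.12},
        "CI":      {"Pre-OPC": 0.00, "Late-OPC": 0.05, "COP": 0.03, "NFOL": 0.00,
                    "MFOL": 0.10, "MOL": 0.22, "MG": 0.35, "AST": 0.25},
        "CI_edge": {"Pre-OPC": 0.04, "Late-OPC": 0.08, "COP": 0.04, "NFOL": 0.04,
                    "MFOL": 0.14, "MOL": 0.30, "MG": 0.24, "AST": 0.12},
    }


def _default_inflamed_frac() -> dict[str, float]:
    # Fraction of microglia in the inflamed state, elevated in NAWM and
    # around the chronic-active lesion.
    return {"Control": 0.2, "NAWM": 0.7, "CA": 0.7, "CA_edge": 0.7,
            "CI": 0.3, "CI_edge": 0.3}


def _default_lr_patterns() -> list[dict]:
    # pair x region on/off table.  SIRPA-CD47 ("don't-eat-me" axis) is
    # active between microglia and oligodendrocytes in healthy-looking
    # white matter and lost in lesion cores; MIF->CD74 (inflammatory
    # migration) switches on in cores; CSF1->CSF1R is NAWM-specific.
    return [
        {"pair_id": "SIRPA-CD47", "ligand_gene": "SIRPA", "receptor_gene": "CD47",
         "sender_type": "MG", "receiver_type": "OL",
         "on_regions": ("Control", "NAWM")},
        {"pair_id": "CD74-MIF", "ligand_gene": "MIF", "receptor_gene": "CD74",
         "sender_type": "OL", "receiver_type": "MG",
         "on_regions": ("CA", "CI")},
        {"pair_id": "CSF1R-CSF1", "ligand_gene": "CSF1", "receptor_gene": "CSF1R",
         "sender_type": "OL", "receiver_type": "MG",
         "on_regions": ("NAWM",)},
    ]


@dataclass
class SimConfig:
    """Generator settings; defaults define the package's study conditions."""

    seed: int = 0
    n_genes: int = 2000
    ref_cells_per_subtype: int = 100
    samples_per_region: int = 3
    cells_per_sample: int = 200
    baseline_mean: float = 0.3          # NB mean per gene before library factor
    gene_mean_sigma: float = 0.4        # log-normal spread of filler-gene means
    dispersion: float = 2.0             # NB size parameter theta (var = mu + mu^2/theta)
    marker_fold: float = 8.0            # subtype marker multiplier f
    major_fold: float = 4.0             # major-cell-type marker multiplier
    program_genes_per_subtype: int = 40  # exclusive broad-program genes per state
    program_fold: float = 4.0           # broad-program multiplier
    inflamed_fold: float = 4.0          # inflammatory-program multiplier
    lr_base_mean: float = 0.05          # LR gene mean when the axis is off
    lr_on_mean: float = 2.0             # LR gene mean in (type, region) where on
    libsize_sigma: float = 0.35         # log-normal sigma of library factors
    mito_beta: tuple[float, float] = (2.0, 78.0)
    regions: Sequence[str] = REGIONS
    region_composition: dict[str, dict[str, float]] = field(
        default_factory=_default_region_composition
    )
    inflamed_frac: dict[str, float] = field(default_factory=_default_inflamed_frac)
    lr_patterns: list[dict] = field(default_factory=_default_lr_patterns)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        named = self.named_genes()
        n_reserved = len(named) + self.program_genes_per_subtype * len(PROGRAM_SUBTYPES)
        if self.n_genes < n_reserved:
            raise ConfigError(
                f"n_genes={self.n_genes} smaller than the {n_reserved} named and "
                "program genes"
            )
        if self.marker_fold <= 1:
            raise ConfigError("marker_fold must exceed 1")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if min(self.ref_cells_per_subtype, self.samples_per_region,
               self.cells_per_sample) < 0:
            raise ConfigError("cell counts must be non-negative")
        unknown = set(self.regions) - set(REGIONS)
        if unknown:
            raise ConfigError(f"unknown region(s): {sorted(unknown)}")
        for r in self.regions:
            if r not in self.region_composition:
                raise ConfigError(f"region {r!r} missing from region_composition")
        for pat in self.lr_patterns:
            for g in (pat["ligand_gene"], pat["receptor_gene"]):
                if g not in LR_GENES:
                    raise ConfigError(f"LR pattern gene {g!r} not in the gene universe")

    @staticmethod
    def named_genes() -> list[str]:
        seen: dict[str, None] = {}
        for genes in SUBTYPE_MARKERS.values():
            seen.update(dict.fromkeys(genes))
        for genes in MAJOR_MARKERS.values():
            seen.update(dict.fromkeys(genes))
        seen.update(dict.fromkeys(INFLAMMATORY_PROGRAM))
        seen.update(dict.fromkeys(LR_GENES))
        seen.update(dict.fromkeys(MT_GENES))
        return list(seen)

    def gene_ids(self) -> np.ndarray:
        named = self.named_genes()
        n_fill = self.n_genes - len(named)
        fillers = [f"GENE{i:04d}" for i in range(1, n_fill + 1)]
        return np.asarray(named + fillers, dtype=object)

    def subtype_program_map(self) -> dict[str, list[str]]:
        """Exclusive broad-program genes per state (first filler genes,
        in fixed blocks, so the assignment is deterministic)."""
        named = self.named_genes()
        n_fill = self.n_genes - len(named)
        fillers = [f"GENE{i:04d}" for i in range(1, n_fill + 1)]
        k = self.program_genes_per_subtype
        return {
            s: fillers[i * k: (i + 1) * k] for i, s in enumerate(PROGRAM_SUBTYPES)
        }


@dataclass
class GroundTruth:
    """Per-cell and per-pattern truth emitted alongside each dataset."""

    cells: pd.DataFrame                 # cell_id, subtype, cell_type, inflamed
    composition: pd.DataFrame | None = None   # region x subtype planted fractions
    interactions: pd.DataFrame | None = None  # pair, sender, receiver, region, active


# --------------------------------------------------------------------------
# Count sampling


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Gamma-Poisson draw with mean mu and dispersion theta (var = mu + mu^2/theta)."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mu, 1e-12) / theta)
    return rng.poisson(lam)


def _baseline_means(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-gene baseline NB means.

    Program genes (markers, inflammatory, LR, MT) sit at controlled
    baselines so planted effects are exact multiples; filler genes get
    log-normal mean heterogeneity for realism.
    """
    genes = cfg.gene_ids()
    mu = np.full(len(genes), cfg.baseline_mean)
    controlled = set(cfg.named_genes())
    for prog in cfg.subtype_program_map().values():
        controlled.update(prog)
    filler = np.array([g not in controlled for g in genes])
    mu[filler] *= rng.lognormal(0.0, cfg.gene_mean_sigma, size=int(filler.sum()))
    idx = {g: i for i, g in enumerate(genes)}
    for g in LR_GENES:
        mu[idx[g]] = cfg.lr_base_mean
    mu[[idx[g] for g in MT_GENES]] = 0.0  # set per cell from the mito fraction
    return mu


def _apply_programs(
    mu: np.ndarray,
    gene_index: Mapping[str, int],
    subtypes: np.ndarray,
    inflamed: np.ndarray,
    cfg: SimConfig,
) -> np.ndarray:
    """Expand per-gene baselines to a gene x cell mean matrix with programs."""
    n_cells = len(subtypes)
    mat = np.repeat(mu[:, None], n_cells, axis=1)
    programs = cfg.subtype_program_map()
    for subtype in np.unique(subtypes):
        cols = subtypes == subtype
        markers = SUBTYPE_MARKERS.get(subtype)
        if subtype.startswith("MG_"):
            markers = None
        if markers:
            rows = [gene_index[g] for g in markers]
            mat[np.ix_(rows, cols)] *= cfg.marker_fold
        major = SUBTYPE_TO_MAJOR.get(subtype)
        if major:
            rows = [gene_index[g] for g in MAJOR_MARKERS[major]]
            mat[np.ix_(rows, cols)] *= cfg.major_fold
        prog_key = major if subtype.startswith("MG_") or subtype == "AST" else subtype
        prog = programs.get(prog_key)
        if prog:
            rows = [gene_index[g] for g in prog]
            mat[np.ix_(rows, cols)] *= cfg.program_fold
    if inflamed.any():
        rows = [gene_index[g] for g in INFLAMMATORY_PROGRAM]
        mat[np.ix_(rows, inflamed)] *= cfg.inflamed_fold
    return mat


def _finalize_counts(
    cfg: SimConfig,
    rng: np.random.Generator,
    mean_mat: np.ndarray,
    gene_index: Mapping[str, int],
) -> np.ndarray:
    """Apply library factors and the mitochondrial program, then sample."""
    n_cells = mean_mat.shape[1]
    lib = rng.lognormal(0.0, cfg.libsize_sigma, size=n_cells)
    mean_mat = mean_mat * lib[None, :]
    mito_frac = rng.beta(*cfg.mito_beta, size=n_cells)
    mt_rows = [gene_index[g] for g in MT_GENES]
    non_mt_total = mean_mat.sum(axis=0)  # MT rows are zero at this point
    mean_mat[mt_rows, :] = (mito_frac / (1.0 - mito_frac)) * non_mt_total / len(mt_rows)
    return _nb_counts(rng, mean_mat, cfg.dispersion)


def _to_count_matrix(counts: np.ndarray, gene_ids: np.ndarray, cell_ids) -> CountMatrix:
    return CountMatrix(
        sp.csr_matrix(counts.astype(np.int64)), gene_ids, np.asarray(cell_ids, dtype=object)
    )


# --------------------------------------------------------------------------
# Reference atlas


def generate_reference_atlas(cfg: SimConfig) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Developmental reference with the seven OL-lineage subtypes.

    Each subtype's marker genes are elevated ``marker_fold``-fold over the
    shared baseline; OPC- and OL-stage cells additionally carry their
    major-type programs, matching the query's structure.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    genes = cfg.gene_ids()
    gene_index = {g: i for i, g in enumerate(genes)}
    n = cfg.ref_cells_per_subtype
    subtypes = np.repeat(list(SUBTYPE_MARKERS), n)
    n_cells = len(subtypes)
    cell_ids = [f"ref_cell_{i:05d}" for i in range(n_cells)]
    samples = np.array(
        [f"ref_s{(i % cfg.samples_per_region) + 1}" for i in range(n_cells)], dtype=object
    )

    mu = _baseline_means(cfg, rng)
    inflamed = np.zeros(n_cells, dtype=bool)
    mean_mat = _apply_programs(mu, gene_index, subtypes, inflamed, cfg)
    counts = _finalize_counts(cfg, rng, mean_mat, gene_index)

    table = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample_id": samples,
            "region": "Control",
            "condition": "control",
            "cell_type": [SUBTYPE_TO_MAJOR[s] for s in subtypes],
            "subtype": subtypes,
        }
    )
    validate_cell_table(table)
    truth = GroundTruth(
        cells=pd.DataFrame(
            {"cell_id": cell_ids, "subtype": subtypes,
             "cell_type": table["cell_type"], "inflamed": False}
        )
    )
    return _to_count_matrix(counts, genes, cell_ids), table, truth


# --------------------------------------------------------------------------
# MS query


def _allocate(fracs: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder allocation of n cells to the given fractions."""
    total = sum(fracs.values())
    quotas = {k: n * v / total for k, v in fracs.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    order = sorted(fracs, key=lambda k: (-(quotas[k] - counts[k]), k))
    for k in order[:short]:
        counts[k] += 1
    return counts


def generate_ms_query(cfg: SimConfig) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Six-region adult query with planted compositions.

    Pre-OPC and NFOL fractions are positive in Control and NAWM, exactly
    zero in the CA and CI lesion cores, and small (below Control) at lesion
    edges; MOL is depleted in cores; microglia are split into inflamed and
    homeostatic states with the inflamed fraction elevated in NAWM and
    around the CA lesion.  Each region carries ``samples_per_region``
    distinct samples.  Per-sample compositions are allocated exactly
    (largest remainder), so planted zeros are structural.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2,)))
    genes = cfg.gene_ids()
    gene_index = {g: i for i, g in enumerate(genes)}

    rows = []
    for region in cfg.regions:
        comp = cfg.region_composition[region]
        for s in range(1, cfg.samples_per_region + 1):
            alloc = _allocate(comp, cfg.cells_per_sample)
            for subtype, k in alloc.items():
                if subtype == "MG":
                    n_infl = int(round(k * cfg.inflamed_frac.get(region, 0.0)))
                    rows += [(region, f"{region}_s{s}", "MG_inflamed")] * n_infl
                    rows += [(region, f"{region}_s{s}", "MG_homeostatic")] * (k - n_infl)
                else:
                    rows += [(region, f"{region}_s{s}", subtype)] * k
    regions_col = np.array([r[0] for r in rows], dtype=object)
    samples_col = np.array([r[1] for r in rows], dtype=object)
    subtypes = np.array([r[2] for r in rows], dtype=object)
    n_cells = len(rows)
    cell_ids = [f"q_cell_{i:05d}" for i in range(n_cells)]
    inflamed = subtypes == "MG_inflamed"

    mu = _baseline_means(cfg, rng)
    mean_mat = _apply_programs(mu, gene_index, subtypes, inflamed, cfg)
    counts = _finalize_counts(cfg, rng, mean_mat, gene_index)

    table = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample_id": samples_col,
            "region": regions_col,
            "condition": np.where(regions_col == "Control", "control", "MS"),
            "cell_type": [SUBTYPE_TO_MAJOR[s] for s in subtypes],
            "subtype": subtypes,
        }
    )
    validate_cell_table(table)

    comp_rows = []
    for region in cfg.regions:
        comp = cfg.region_composition[region]
        total = sum(comp.values())
        for subtype, frac in comp.items():
            comp_rows.append({"region": region, "subtype": subtype, "fraction": frac / total})
    truth = GroundTruth(
        cells=pd.DataFrame(
            {"cell_id": cell_ids, "subtype": subtypes,
             "cell_type": table["cell_type"], "inflamed": inflamed}
        ),
        composition=pd.DataFrame(comp_rows),
    )
    return _to_count_matrix(counts, genes, cell_ids), table, truth


# --------------------------------------------------------------------------
# Ligand-receptor planting


def generate_lr_patterns(
    cfg: SimConfig,
    counts: CountMatrix,
    cell_table: pd.DataFrame,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, CountMatrix, GroundTruth]:
    """Plant region-dependent ligand-receptor expression into query counts.

    For every pattern row and every region where the axis is "on", the
    ligand gene is re-drawn at ``lr_on_mean`` in sender-type cells and the
    receptor gene at ``lr_on_mean`` in receiver-type cells (elsewhere both
    stay at the low off-state baseline).  Returns the LR pair table, the
    modified counts, and ground truth extended with the interaction states.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(3,)))
    gene_index = {g: i for i, g in enumerate(counts.gene_ids)}
    for pat in cfg.lr_patterns:
        for g in (pat["ligand_gene"], pat["receptor_gene"]):
            if g not in gene_index:
                raise ConfigError(f"LR gene {g!r} absent from the count matrix")

    dense = counts.values.toarray().astype(np.int64)
    region = cell_table["region"].to_numpy()
    ctype = cell_table["cell_type"].to_numpy()
    interactions = []
    for pat in cfg.lr_patterns:
        for reg in cfg.regions:
            active = reg in pat["on_regions"]
            interactions.append(
                {"pair_id": pat["pair_id"], "sender": pat["sender_type"],
                 "receiver": pat["receiver_type"], "region": reg, "active": active}
            )
            if not active:
                continue
            for gene, typ in (
                (pat["ligand_gene"], pat["sender_type"]),
                (pat["receptor_gene"], pat["receiver_type"]),
            ):
                cols = np.nonzero((region == reg) & (ctype == typ))[0]
                dense[gene_index[gene], cols] = _nb_counts(
                    rng, np.full(cols.size, cfg.lr_on_mean), cfg.dispersion
                )

    lr_table = pd.DataFrame(
        [
            {"pair_id": p["pair_id"], "ligand_gene": p["ligand_gene"],
             "receptor_gene": p["receptor_gene"]}
            for p in cfg.lr_patterns
        ]
    )
    new_counts = _to_count_matrix(dense, counts.gene_ids, counts.cell_ids)
    cells = truth.cells if truth is not None else None
    new_truth = GroundTruth(
        cells=cells if cells is not None else cell_table[["cell_id", "subtype", "cell_type"]].assign(inflamed=False),
        composition=truth.composition if truth is not None else None,
        interactions=pd.DataFrame(interactions),
    )
    return lr_table, new_counts, new_truth


def make_null_lr_table(gene_ids: Sequence[str], n_pairs: int = 8) -> pd.DataFrame:
    """LR table over filler genes with no planted pattern (for calibration)."""
    fillers = [g for g in gene_ids if str(g).startswith("GENE")]
    if len(fillers) < 2 * n_pairs:
        raise FormatError("not enough filler genes for the requested null pairs")
    rows = [
        {"pair_id": f"NULL{i + 1:02d}", "ligand_gene": fillers[2 * i],
         "receptor_gene": fillers[2 * i + 1]}
        for i in range(n_pairs)
    ]
    return pd.DataFrame(rows)
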