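"""Readers and writers for the on-disk formats used throughout the package.

Count matrices travel as Matrix Market coordinate files (gene x cell,
integer, general) with headerless single-column TSV companions for gene
symbols and cell barcodes -- the de facto 10x-style layout.  Per-cell
metadata is a headered TSV, gene sets are GMT, and ligand-receptor pairs
are a three-column TSV.  Every reader/writer pair round-trips exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("oligoscore")

REGIONS = ("Control", "NAWM", "CA", "CA_edge", "CI", "CI_edge")
CONDITIONS = ("control", "MS")


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


# ---------------------------------------------------------------------------
# CountMatrix


@dataclass
class CountMatrix:
    """Sparse gene x cell matrix of non-negative integer counts.

    Attributes
    ----------
    values : scipy.sparse.csr_matrix
        Shape ``(n_genes, n_cells)``; entries are non-negative integers.
    gene_ids : numpy.ndarray of str
        Row labels (gene symbols), unique.
    cell_ids : numpy.ndarray of str
        Column labels (cell barcodes), unique.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.values = sp.csr_matrix(self.values)
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                seen, dup = set(), None
                for x in ids:
                    if x in seen:
                        dup = x
                        break
                    seen.add(x)
                raise FormatError(f"duplicate {name} id: {dup!r}")
        data = self.values.data
        if data.size:
            if data.min() < 0:
                bad = np.argmin(data)
                raise FormatError(f"negative count {data[bad]} in matrix")
            if not np.issubdtype(data.dtype, np.integer) and np.any(
                data != np.round(data)
            ):
                bad = int(np.nonzero(data != np.round(data))[0][0])
                raise FormatError(f"non-integer count {data[bad]} in matrix")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return CountMatrix(self.values[:, idx], self.gene_ids, self.cell_ids[idx])


def read_counts(
    mtx_path: str | Path, genes_path: str | Path, barcodes_path: str | Path
) -> CountMatrix:
    """Read a gene x cell count matrix from MTX plus companion TSVs.

    The 1-based Matrix Market indices become 0-based in memory.  Dimension
    mismatches between the MTX header and the companion files, duplicate
    ids, and negative or fractional entries raise :class:`FormatError`.
    """
    try:
        raw = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # scipy raises ValueError on bad headers
        raise FormatError(f"malformed MTX file {mtx_path}: {exc}") from exc
    raw = sp.coo_matrix(raw)
    genes = _read_id_column(genes_path)
    cells = _read_id_column(barcodes_path)
    if raw.shape != (len(genes), len(cells)):
        raise FormatError(
            f"MTX declares shape {raw.shape} but companions give "
            f"({len(genes)} genes, {len(cells)} barcodes)"
        )
    if raw.data.size and (raw.data.min() < 0 or np.any(raw.data != np.round(raw.data))):
        bad = int(np.nonzero((raw.data < 0) | (raw.data != np.round(raw.data)))[0][0])
        # +3 = header line + size line + 1-based entry position
        raise FormatError(
            f"invalid count {raw.data[bad]} at entry line {bad + 3} of {mtx_path} "
            f"(gene {raw.row[bad] + 1}, cell {raw.col[bad] + 1}, 1-based)"
        )
    m = CountMatrix(sp.csr_matrix(raw, dtype=np.int64), genes, cells)
    logger.info("read_counts: %d genes x %d cells from %s", m.n_genes, m.n_cells, mtx_path)
    return m


def _read_id_column(path: str | Path) -> np.ndarray:
    ids = [line.rstrip("\n") for line in Path(path).read_text().splitlines()]
    ids = [x for x in ids if x != ""]
    return np.asarray(ids, dtype=object)


def write_counts(m: CountMatrix, dir_path: str | Path) -> dict[str, Path]:
    """Write a CountMatrix as matrix.mtx + genes.tsv + barcodes.tsv.

    Round-trip identity with :func:`read_counts` is guaranteed.
    """
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    for name, ids in (("gene", m.gene_ids), ("barcode", m.cell_ids)):
        for x in ids:
            if "\t" in x or "\n" in x:
                raise FormatError(f"{name} id {x!r} contains a delimiter character")
    paths = {
        "mtx": d / "matrix.mtx",
        "genes": d / "genes.tsv",
        "barcodes": d / "barcodes.tsv",
    }
    scipy.io.mmwrite(
        str(paths["mtx"]), sp.coo_matrix(m.values), field="integer", symmetry="general"
    )
    paths["genes"].write_text("".join(f"{g}\n" for g in m.gene_ids))
    paths["barcodes"].write_text("".join(f"{b}\n" for b in m.cell_ids))
    return paths


# ---------------------------------------------------------------------------
# CellTable

CELL_TABLE_COLUMNS = ("cell_id", "sample_id", "region", "condition")


def validate_cell_table(table: pd.DataFrame, counts: CountMatrix | None = None) -> None:
    """Check per-cell metadata invariants.

    region must be one of the six lesion-region levels; region == Control
    iff condition == control; cell ids must be unique and, when a paired
    CountMatrix is given, exactly its columns.
    """
    missing = [c for c in CELL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"cell table missing column(s): {missing}")
    if table["cell_id"].duplicated().any():
        dup = table.loc[table["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise FormatError(f"duplicate cell_id {dup!r} in cell table")
    bad_region = set(table["region"]) - set(REGIONS)
    if bad_region:
        raise FormatError(f"unknown region level(s): {sorted(bad_region)}")
    bad_cond = set(table["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise FormatError(f"unknown condition level(s): {sorted(bad_cond)}")
    is_ctrl_region = table["region"] == "Control"
    is_ctrl_cond = table["condition"] == "control"
    if not (is_ctrl_region == is_ctrl_cond).all():
        raise FormatError("region == Control must coincide with condition == control")
    if counts is not None:
        if len(table) != counts.n_cells or not np.array_equal(
            table["cell_id"].to_numpy(dtype=object), counts.cell_ids
        ):
            raise FormatError("cell table ids do not match CountMatrix columns")


def read_cell_table(path: str | Path, counts: CountMatrix | None = None) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    validate_cell_table(table, counts)
    return table


def write_cell_table(table: pd.DataFrame, path: str | Path) -> Path:
    validate_cell_table(table)
    table.to_csv(path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# Gene sets (GMT)


@dataclass
class GeneSetCollection:
    """Named gene sets (deduplicated, order-preserving)."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-delimited GMT file (name, description, genes...).

    Duplicate genes within a line are dropped with a logged warning;
    a repeated set name or a line with fewer than 3 fields is an error.
    """
    sets: dict[str, list[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{i}: GMT line has {len(fields)} fields (< 3)")
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        if name in sets:
            raise FormatError(f"{path}:{i}: duplicate gene set name {name!r}")
        deduped = list(dict.fromkeys(genes))
        if len(deduped) < len(genes):
            logger.warning(
                "read_gmt: %d duplicate gene(s) dropped from set %s", len(genes) - len(deduped), name
            )
        sets[name] = deduped
    return GeneSetCollection(sets)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> Path:
    lines = [
        "\t".join([name, "na", *genes]) for name, genes in gsc.sets.items()
    ]
    Path(path).write_text("".join(f"{ln}\n" for ln in lines))
    return Path(path)


# ---------------------------------------------------------------------------
# Ligand-receptor pair tables

LR_COLUMNS = ("pair_id", "ligand_gene", "receptor_gene")


def validate_lr_table(table: pd.DataFrame) -> None:
    missing = [c for c in LR_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"LR table missing column(s): {missing}")
    if table["pair_id"].duplicated().any():
        dup = table.loc[table["pair_id"].duplicated(), "pair_id"].iloc[0]
        raise FormatError(f"duplicate pair_id {dup!r}")
    same = table["ligand_gene"] == table["receptor_gene"]
    if same.any():
        raise FormatError(
            f"ligand == receptor in pair {table.loc[same, 'pair_id'].iloc[0]!r}"
        )


def read_lr_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    validate_lr_table(table)
    return table


def write_lr_table(table: pd.DataFrame, path: str | Path) -> Path:
    validate_lr_table(table)
    table.to_csv(path, sep="\t", index=False)
    return Path(path)
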