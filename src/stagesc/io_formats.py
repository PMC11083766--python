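"""On-disk formats used by the pipeline.

Count matrices travel as 10x-style MatrixMarket triplets (``matrix.mtx`` +
``barcodes.tsv`` + ``features.tsv``), gene sets as one-ID-per-line text files,
and every tabular artifact (marker tables, cluster labels, QC reports) as CSV
with a declared schema.  All writers are deterministic so identical inputs
yield byte-identical files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "StageCountMatrix",
    "GeneSet",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_gene_set",
    "write_gene_set",
    "read_table",
    "write_table",
    "TABLE_SCHEMAS",
]


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its declared dialect."""


@dataclass
class StageCountMatrix:
    """Sparse UMI counts for one developmental stage, oriented cells x genes.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, rows = cells, columns = genes.
    barcodes
        Unique cell identifiers, one per row.
    genes
        Unique gene identifiers, one per column.
    stage
        Stage label shared by every cell in the matrix (e.g. ``"7"``,
        ``"8.1"``, ``"9.1"``).
    mito_mask
        Boolean array marking mitochondrial genes, one entry per column.
    """

    counts: sp.csr_matrix
    barcodes: list[str]
    genes: list[str]
    stage: str
    mito_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("count matrix has negative entries")
        if self.counts.shape[0] != len(self.barcodes):
            raise ValueError(
                f"{len(self.barcodes)} barcodes for {self.counts.shape[0]} rows"
            )
        if self.counts.shape[1] != len(self.genes):
            raise ValueError(
                f"{len(self.genes)} gene IDs for {self.counts.shape[1]} columns"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes within a stage")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if self.mito_mask is None:
            self.mito_mask = np.zeros(len(self.genes), dtype=bool)
        self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
        if self.mito_mask.shape != (len(self.genes),):
            raise ValueError("mito_mask length must equal the number of genes")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def set_mito_by_prefix(self, prefix: str) -> None:
        """Mark every gene whose identifier starts with ``prefix`` as mitochondrial."""
        self.mito_mask = np.array(
            [g.startswith(prefix) for g in self.genes], dtype=bool
        )

    def subset(self, cell_idx=None, gene_idx=None) -> "StageCountMatrix":
        """Return a new matrix restricted to the given cell/gene positions."""
        cell_idx = np.arange(self.n_cells) if cell_idx is None else np.asarray(cell_idx)
        gene_idx = np.arange(self.n_genes) if gene_idx is None else np.asarray(gene_idx)
        return StageCountMatrix(
            counts=self.counts[cell_idx][:, gene_idx],
            barcodes=[self.barcodes[i] for i in cell_idx],
            genes=[self.genes[j] for j in gene_idx],
            stage=self.stage,
            mito_mask=self.mito_mask[gene_idx],
        )


@dataclass
class GeneSet:
    """A named list of gene identifiers (e.g. S-phase genes, mito genes)."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicates")


def _read_ids(path) -> list[str]:
    """One identifier per line; for TSV lines only the first column is kept."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_counts_mtx(
    matrix_path,
    barcodes_path,
    features_path,
    stage_label: str,
    mito_prefix: str | None = None,
    mito_genes: GeneSet | None = None,
) -> StageCountMatrix:
    """Read a 10x-style MTX triplet into a cells x genes :class:`StageCountMatrix`.

    The on-disk matrix may be stored either cells x genes or genes x cells
    (the 10x convention); the orientation is inferred from the lengths of the
    barcode and feature files.  A square matrix with equally long ID files is
    rejected as ambiguous.  Mitochondrial genes can be flagged either by an ID
    prefix or with an explicit :class:`GeneSet`.
    """
    with open(matrix_path, "rb") as fh:
        header = fh.readline().decode()
    if "coordinate" not in header:
        raise FormatError(f"{matrix_path}: expected a coordinate MatrixMarket file")
    mat = scipy.io.mmread(str(matrix_path))
    if not np.issubdtype(mat.dtype, np.integer):
        data = mat.tocoo().data
        if data.size and not np.all(data == np.round(data)):
            raise FormatError(f"{matrix_path}: non-integer values in count matrix")
        mat = mat.astype(np.int64)
    barcodes = _read_ids(barcodes_path)
    genes = _read_ids(features_path)
    n_rows, n_cols = mat.shape
    cells_by_genes = (n_rows == len(barcodes)) and (n_cols == len(genes))
    genes_by_cells = (n_rows == len(genes)) and (n_cols == len(barcodes))
    if cells_by_genes and genes_by_cells:
        raise FormatError(
            "ambiguous orientation: matrix is square and barcode/feature files "
            "have equal length"
        )
    if genes_by_cells:
        mat = mat.T
    elif not cells_by_genes:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither {len(barcodes)} barcodes "
            f"x {len(genes)} features nor its transpose"
        )
    out = StageCountMatrix(
        counts=sp.csr_matrix(mat),
        barcodes=barcodes,
        genes=genes,
        stage=stage_label,
    )
    if mito_genes is not None:
        wanted = set(mito_genes.genes)
        out.mito_mask = np.array([g in wanted for g in out.genes], dtype=bool)
    elif mito_prefix is not None:
        out.set_mito_by_prefix(mito_prefix)
    return out


def write_counts_mtx(matrix: StageCountMatrix, out_dir) -> dict[str, Path]:
    """Write ``matrix.mtx`` (genes x cells, 10x convention), ``barcodes.tsv``
    and ``features.tsv`` into ``out_dir``.

    Entries are emitted in column-major order of the genes x cells matrix so
    two writes of the same object are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "barcodes": out_dir / "barcodes.tsv",
        "features": out_dir / "features.tsv",
    }
    gxc = sp.csc_matrix(matrix.counts.T.astype(np.int64))
    gxc.sort_indices()
    coo = gxc.tocoo()
    buf = io.StringIO()
    buf.write("%%MatrixMarket matrix coordinate integer general\n")
    buf.write(f"{gxc.shape[0]} {gxc.shape[1]} {gxc.nnz}\n")
    # csc->coo iterates column-major already
    for i, j, v in zip(coo.row, coo.col, coo.data):
        buf.write(f"{i + 1} {j + 1} {v}\n")
    paths["matrix"].write_text(buf.getvalue())
    paths["barcodes"].write_text("".join(b + "\n" for b in matrix.barcodes))
    paths["features"].write_text("".join(g + "\n" for g in matrix.genes))
    return paths


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """Read a plain-text gene set, one gene identifier per line."""
    path = Path(path)
    return GeneSet(name=name or path.stem, genes=_read_ids(path))


def write_gene_set(gene_set: GeneSet, path) -> Path:
    path = Path(path)
    path.write_text("".join(g + "\n" for g in gene_set.genes))
    return path


# Declared column schemas for every CSV artifact the pipeline writes.
# Values are pandas dtypes used on read; column order is enforced on write.
TABLE_SCHEMAS: dict[str, dict[str, str]] = {
    "cluster_labels": {"barcode": "str", "cluster": "int64"},
    "markers": {
        "cluster": "str",
        "gene": "str",
        "pct_in": "float64",
        "pct_out": "float64",
        "log2_fc": "float64",
        "p_raw": "float64",
        "p_adj": "float64",
        "direction": "str",
    },
    "qc_report": {"criterion": "str", "n_removed": "int64"},
    "cell_qc": {
        "barcode": "str",
        "total_umi": "int64",
        "n_genes": "int64",
        "mito_fraction": "float64",
    },
    "doublet_scores": {"barcode": "str", "doublet_score": "float64", "removed": "bool"},
    "overlap_tests": {
        "cluster_x": "str",
        "cluster_y": "str",
        "m_x": "int64",
        "m_y": "int64",
        "k": "int64",
        "n_pool": "int64",
        "p_raw": "float64",
        "p_adj": "float64",
    },
    "best_match": {
        "cluster_x": "str",
        "cluster_y": "str",
        "p_adj": "float64",
        "k": "int64",
        "matched": "bool",
    },
    "cycle_scores": {
        "barcode": "str",
        "s_score": "float64",
        "g2m_score": "float64",
        "phase": "str",
    },
    "phase_fractions": {
        "cluster": "int64",
        "fraction_G1": "float64",
        "fraction_S": "float64",
        "fraction_G2M": "float64",
        "g1_flag": "bool",
    },
    "ari_long": {
        "run_a": "str",
        "run_b": "str",
        "ari": "float64",
    },
    "decisions": {
        "component": "int64",
        "old_ids": "str",
        "new_ids": "str",
        "rule": "str",
    },
    "ground_truth_cells": {
        "barcode": "str",
        "stage": "str",
        "true_cluster": "int64",
        "is_doublet": "bool",
        "parent_a": "int64",
        "parent_b": "int64",
        "true_phase": "str",
    },
    "ground_truth_markers": {"cluster": "int64", "gene": "str"},
    "ground_truth_genes": {
        "gene": "str",
        "is_mito": "bool",
        "is_cycle_s": "bool",
        "is_cycle_g2m": "bool",
    },
    "emulation_report": {
        "stage": "str",
        "n_cells": "int64",
        "median_umi": "float64",
        "median_genes": "float64",
        "mean_mito_fraction": "float64",
    },
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a CSV artifact and validate it against a declared schema."""
    if schema not in TABLE_SCHEMAS:
        raise KeyError(f"unknown table schema {schema!r}")
    cols = TABLE_SCHEMAS[schema]
    df = pd.read_csv(path, dtype={c: t for c, t in cols.items() if t == "str"})
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    for c, t in cols.items():
        if t != "str":
            df[c] = df[c].astype(t)
        else:
            df[c] = df[c].astype(object).where(df[c].notna(), None).astype(str)
    return df[list(cols)]


def write_table(df: pd.DataFrame, path, schema: str) -> Path:
    """Write a CSV artifact with the schema's column order; lossless round trip."""
    if schema not in TABLE_SCHEMAS:
        raise KeyError(f"unknown table schema {schema!r}")
    cols = TABLE_SCHEMAS[schema]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"cannot write {schema}: missing column(s) {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df[list(cols)].to_csv(path, index=False)
    return path
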