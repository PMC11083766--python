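"""Per-cell QC metrics, threshold filtering, and pANN doublet scoring.

The filter thresholds default to the study's values: genes expressed in at
least 20 cells; 400-1800 detected genes per cell; stage-specific UMI minima
(650 for stage 7, 700 for 8.1, 500 for 9.1) with a common maximum of 4500;
and at most 1% mitochondrial expression.  Doublets are scored by the
proportion of artificial nearest neighbors (pANN): artificial doublets are
averaged normalized profiles of random cell pairs, PCA is recomputed on the
augmented set, and each real cell is scored by the artificial fraction among
its nearest neighbors; the top 5% of scores are removed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import StageCountMatrix

__all__ = [
    "QCThresholds",
    "DoubletParams",
    "compute_cell_qc",
    "filter_cells_genes",
    "doublet_scores",
    "remove_doublets",
]

# cell-level criteria in application order; a removed cell is attributed to
# the first rule it violates
CELL_CRITERIA = ("n_genes_low", "n_genes_high", "umi_low", "umi_high", "mito_high")


@dataclass
class QCThresholds:
    """Filter thresholds; defaults are the study's published values."""

    min_cells_per_gene: int = 20
    min_genes_per_cell: int = 400
    max_genes_per_cell: int = 1800
    min_umi_by_stage: dict[str, int] = field(
        default_factory=lambda: {"7": 650, "8.1": 700, "9.1": 500}
    )
    max_umi: int = 4500
    max_mito_fraction: float = 0.01
    capture_min_genes: int = 100

    def __post_init__(self) -> None:
        if self.min_genes_per_cell >= self.max_genes_per_cell:
            raise ValueError("min_genes_per_cell must be < max_genes_per_cell")
        if any(v >= self.max_umi for v in self.min_umi_by_stage.values()):
            raise ValueError("stage UMI minima must be < max_umi")
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass
class DoubletParams:
    """pANN doublet-scoring parameters.

    ``artificial_fraction`` is the number of artificial doublets relative to
    the number of real cells; ``pK`` sets the neighborhood size as a fraction
    of the augmented dataset; ``expected_rate`` is the fraction of top-scoring
    cells removed (5% in the study).
    """

    artificial_fraction: float = 0.25
    pK: float = 0.01
    n_pcs: int = 20
    expected_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.artificial_fraction <= 0:
            raise ValueError("artificial_fraction must be > 0")
        if not (0.0 < self.expected_rate < 1.0):
            raise ValueError("expected_rate must be in (0, 1)")


def compute_cell_qc(matrix: StageCountMatrix) -> pd.DataFrame:
    """Exact per-cell totals: UMI, detected genes, mitochondrial fraction.

    The mito fraction of an all-zero cell is defined as 0.
    """
    counts = matrix.counts
    total = np.asarray(counts.sum(axis=1)).ravel().astype(np.int64)
    n_genes = np.asarray((counts > 0).sum(axis=1)).ravel().astype(np.int64)
    mito = np.asarray(counts[:, matrix.mito_mask].sum(axis=1)).ravel()
    mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            "total_umi": total,
            "n_genes": n_genes,
            "mito_fraction": mito_frac,
        }
    )


def filter_cells_genes(
    matrix: StageCountMatrix, thresholds: QCThresholds | None = None
):
    """Apply the gene filter, then the cell filters, in one documented pass.

    Genes must be expressed (count > 0) in at least ``min_cells_per_gene``
    cells of the *input* matrix; cell metrics are then recomputed on the
    gene-filtered matrix and cells are tested against the gene-count bounds,
    the stage-specific UMI bounds and the mito-fraction cap.  The report
    attributes each removed cell to the first violated criterion in
    application order and lists removed-gene counts.

    Returns ``(filtered_matrix, report)`` where ``report`` is a dict with a
    ``summary`` DataFrame (criterion, n_removed) and a ``removed_cells``
    DataFrame (barcode, criterion).
    """
    thresholds = thresholds or QCThresholds()
    if matrix.stage not in thresholds.min_umi_by_stage:
        raise KeyError(
            f"stage {matrix.stage!r} not present in min_umi_by_stage "
            f"{sorted(thresholds.min_umi_by_stage)}"
        )
    min_umi = thresholds.min_umi_by_stage[matrix.stage]

    cells_per_gene = np.asarray((matrix.counts > 0).sum(axis=0)).ravel()
    gene_keep = cells_per_gene >= thresholds.min_cells_per_gene
    n_genes_removed = int((~gene_keep).sum())
    gene_filtered = matrix.subset(gene_idx=np.flatnonzero(gene_keep))

    qc = compute_cell_qc(gene_filtered)
    removed_rows = []
    cell_keep = np.ones(gene_filtered.n_cells, dtype=bool)
    for i in range(gene_filtered.n_cells):
        ng = qc["n_genes"].iat[i]
        umi = qc["total_umi"].iat[i]
        mito = qc["mito_fraction"].iat[i]
        criterion = None
        if ng < thresholds.min_genes_per_cell:
            criterion = "n_genes_low"
        elif ng > thresholds.max_genes_per_cell:
            criterion = "n_genes_high"
        elif umi < min_umi:
            criterion = "umi_low"
        elif umi > thresholds.max_umi:
            criterion = "umi_high"
        elif mito > thresholds.max_mito_fraction:
            criterion = "mito_high"
        if criterion is not None:
            cell_keep[i] = False
            removed_rows.append({"barcode": qc["barcode"].iat[i], "criterion": criterion})

    filtered = gene_filtered.subset(cell_idx=np.flatnonzero(cell_keep))
    if filtered.n_cells == 0:
        warnings.warn("QC filtering removed every cell", stacklevel=2)
    removed_cells = pd.DataFrame(removed_rows, columns=["barcode", "criterion"])
    summary = pd.DataFrame(
        [{"criterion": "genes_min_cells", "n_removed": n_genes_removed}]
        + [
            {
                "criterion": c,
                "n_removed": int((removed_cells["criterion"] == c).sum()),
            }
            for c in CELL_CRITERIA
        ]
    )
    report = {"summary": summary, "removed_cells": removed_cells}
    return filtered, report


def doublet_scores(
    normalized: np.ndarray, params: DoubletParams | None = None
) -> np.ndarray:
    """pANN score per cell on an already filtered, normalized matrix.

    ``round(artificial_fraction * n)`` artificial doublets are built as means
    of the normalized profiles of random cell pairs; PCA (``n_pcs``) is
    recomputed on the augmented set; each real cell's score is the fraction
    of artificial cells among its ``k_d = max(1, round(pK * n_total))``
    nearest Euclidean neighbors (the cell itself excluded).  Exactly
    reproducible from ``params.seed``.
    """
    from sklearn.decomposition import PCA

    params = params or DoubletParams()
    normalized = np.asarray(normalized, dtype=np.float64)
    n = normalized.shape[0]
    if n < 10:
        raise ValueError(f"doublet scoring requires >= 10 cells, got {n}")
    rng = np.random.default_rng(params.seed)
    n_art = int(round(params.artificial_fraction * n))
    pair_a = rng.integers(0, n, size=n_art)
    offset = rng.integers(1, n, size=n_art)
    pair_b = (pair_a + offset) % n  # guarantees two distinct cells
    artificial = 0.5 * (normalized[pair_a] + normalized[pair_b])
    augmented = np.vstack([normalized, artificial])

    n_pcs = min(params.n_pcs, min(augmented.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=0)
    scores = pca.fit_transform(augmented - augmented.mean(axis=0))

    n_total = augmented.shape[0]
    k_d = max(1, int(round(params.pK * n_total)))
    is_art = np.zeros(n_total, dtype=bool)
    is_art[n:] = True
    # full distance matrix with lexicographic (distance, index) tie-break
    sq = np.einsum("ij,ij->i", scores, scores)
    out = np.empty(n)
    real = scores[:n]
    for i in range(n):
        d = sq - 2.0 * scores @ real[i] + sq[i]
        d[i] = np.inf  # exclude self
        order = np.lexsort((np.arange(n_total), d))[:k_d]
        out[i] = is_art[order].mean()
    return out


def remove_doublets(
    scores: np.ndarray, expected_rate: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Remove the ``ceil(expected_rate * n)`` highest-scoring cells.

    Ties are broken toward the smaller cell index so the removed set is
    deterministic.  Returns ``(retained_idx, removed_idx)`` as sorted arrays.
    ``expected_rate`` 0 removes nothing; rates >= 1 are rejected.
    """
    scores = np.asarray(scores, dtype=np.float64)
    n = scores.shape[0]
    if expected_rate >= 1.0:
        raise ValueError("expected_rate must be < 1")
    if expected_rate < 0.0:
        raise ValueError("expected_rate must be >= 0")
    n_remove = int(math.ceil(expected_rate * n)) if expected_rate > 0 else 0
    order = np.lexsort((np.arange(n), -scores))
    removed = np.sort(order[:n_remove])
    retained = np.sort(order[n_remove:])
    return retained, removed
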