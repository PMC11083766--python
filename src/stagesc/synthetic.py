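"""Synthetic multi-stage droplet scRNA-seq data with planted ground truth.

The generator emulates filtered SPLiT-seq-style UMI matrices from three
embryonic stages: counts are negative-binomial (Gamma-Poisson) around
cell-specific, library-size-scaled cluster profiles, with

* shared clusters present in every stage plus stage-enriched clusters whose
  mixture weight is high only in their home stage,
* disjoint planted marker blocks per cluster (fold-change up),
* ~5% planted doublets built from two parent clusters at 1.5x library size,
* planted S / G2M expression programs on dedicated gene sets, with one
  designated low-cycling cluster dominated by G1 cells,
* a small mitochondrial gene block scaled to a target expression fraction.

Default parameters target the per-stage library-size medians of the study
conditions (median UMI per cell 1465 / 1656 / 1343 at reduced cell counts).
Everything is reproducible from a single seed, and every planted fact is
returned as a :class:`GroundTruth` table so downstream tests can score
recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .io_formats import (
    GeneSet,
    StageCountMatrix,
    read_table,
    write_counts_mtx,
    write_table,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_stages",
    "emulation_report",
    "qc_violation_fixture",
]

MITO_PREFIX = "mt-"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-stage experiment.

    Defaults describe the study conditions at reduced scale: 3 stages with
    600/600/900 cells, 2000 genes, 5 shared + 1 stage-specific cluster per
    stage, 20 markers per cluster at 4x fold change, 5% doublets, <1%
    mitochondrial fraction, and per-stage log-normal library sizes whose
    medians match 1465/1656/1343 UMI.
    """

    n_stages: int = 3
    cells_per_stage: tuple[int, ...] = (600, 600, 900)
    stage_labels: tuple[str, ...] = ("7", "8.1", "9.1")
    n_genes: int = 2000
    n_shared_clusters: int = 5
    n_stage_specific_clusters: tuple[int, ...] = (1, 1, 1)
    markers_per_cluster: int = 30
    marker_fold_change: float = 4.0
    # Gamma(shape, scale) for relative gene abundances; shape 0.42 with NB
    # size 10 yields ~650-720 detected genes per cell at these library sizes.
    base_mean_shape: float = 0.42
    base_mean_scale: float = 1.0
    library_size_lognormal_mu: tuple[float, ...] = (
        math.log(1465.0),
        math.log(1656.0),
        math.log(1343.0),
    )
    library_size_lognormal_sigma: float = 0.35
    dispersion: float = 10.0  # NB size (inverse-dispersion); larger = closer to Poisson
    mito_gene_count: int = 10
    mito_target_fraction: float = 0.005
    doublet_fraction: float = 0.05
    doublet_library_scale: float = 1.5
    # phase priors for cycling clusters; the remainder is G1
    cycle_fraction_s: float = 0.45
    cycle_fraction_g2m: float = 0.45
    s_gene_count: int = 43
    g2m_gene_count: int = 54
    cycle_fold_change: float = 2.0
    low_cycle_cluster: int | None = 1
    low_cycle_g1_fraction: float = 0.8
    # mixture weights of a stage-specific cluster in / outside its home
    # stage, relative to weight 1 for every shared cluster; home weight 2
    # makes stage-enriched clusters comparable in size to shared ones
    home_stage_weight: float = 2.0
    off_stage_weight: float = 0.05
    capture_min_genes: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        if len(self.cells_per_stage) != self.n_stages:
            raise ValueError("cells_per_stage length must equal n_stages")
        if len(self.n_stage_specific_clusters) != self.n_stages:
            raise ValueError("n_stage_specific_clusters length must equal n_stages")
        if len(self.stage_labels) != self.n_stages:
            raise ValueError("stage_labels length must equal n_stages")
        if len(self.library_size_lognormal_mu) != self.n_stages:
            raise ValueError("library_size_lognormal_mu length must equal n_stages")
        if self.n_clusters < 1:
            raise ValueError("at least one cluster is required")
        for name in ("mito_target_fraction", "doublet_fraction",
                     "cycle_fraction_s", "cycle_fraction_g2m"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.cycle_fraction_s + self.cycle_fraction_g2m >= 1.0:
            raise ValueError("cycle_fraction_s + cycle_fraction_g2m must be < 1")
        if self.marker_fold_change <= 1.0:
            raise ValueError("marker_fold_change must be > 1")
        needed = (self.n_clusters * self.markers_per_cluster
                  + self.s_gene_count + self.g2m_gene_count + self.mito_gene_count)
        if needed > self.n_genes:
            raise ValueError(
                f"infeasible config: {needed} dedicated genes exceed n_genes={self.n_genes}"
            )

    @property
    def n_clusters(self) -> int:
        return self.n_shared_clusters + sum(self.n_stage_specific_clusters)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        for key in ("cells_per_stage", "stage_labels", "n_stage_specific_clusters",
                    "library_size_lognormal_mu"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted facts of one simulation, as tidy tables.

    ``cells`` has one row per cell (barcode, stage, true_cluster, is_doublet,
    parent clusters, true_phase); ``markers`` lists the planted marker genes
    per cluster; ``genes`` flags mito and cycle genes.
    """

    cells: pd.DataFrame
    markers: pd.DataFrame
    genes: pd.DataFrame

    def marker_genes(self, cluster: int) -> list[str]:
        return self.markers.loc[self.markers["cluster"] == cluster, "gene"].tolist()

    @property
    def s_gene_set(self) -> GeneSet:
        return GeneSet("S", self.genes.loc[self.genes["is_cycle_s"], "gene"].tolist())

    @property
    def g2m_gene_set(self) -> GeneSet:
        return GeneSet("G2M", self.genes.loc[self.genes["is_cycle_g2m"], "gene"].tolist())

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        write_table(self.cells, out_dir / "ground_truth_cells.csv", "ground_truth_cells")
        write_table(self.markers, out_dir / "ground_truth_markers.csv", "ground_truth_markers")
        write_table(self.genes, out_dir / "ground_truth_genes.csv", "ground_truth_genes")

    @classmethod
    def load(cls, out_dir) -> "GroundTruth":
        out_dir = Path(out_dir)
        return cls(
            cells=read_table(out_dir / "ground_truth_cells.csv", "ground_truth_cells"),
            markers=read_table(out_dir / "ground_truth_markers.csv", "ground_truth_markers"),
            genes=read_table(out_dir / "ground_truth_genes.csv", "ground_truth_genes"),
        )


def _gene_layout(config: SimulationConfig):
    """Deterministic assignment of gene indices to roles.

    Marker blocks come first (clusters in ID order), then the S and G2M
    program genes, then background; the mitochondrial block sits at the end
    with a ``mt-`` ID prefix.
    """
    K = config.n_clusters
    mpc = config.markers_per_cluster
    marker_idx = {c + 1: np.arange(c * mpc, (c + 1) * mpc) for c in range(K)}
    pos = K * mpc
    s_idx = np.arange(pos, pos + config.s_gene_count)
    pos += config.s_gene_count
    g2m_idx = np.arange(pos, pos + config.g2m_gene_count)
    mito_idx = np.arange(config.n_genes - config.mito_gene_count, config.n_genes)
    names = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    for rank, j in enumerate(mito_idx):
        names[j] = f"{MITO_PREFIX}{rank + 1}"
    return names, marker_idx, s_idx, g2m_idx, mito_idx


def _cluster_profiles(config: SimulationConfig, rng) -> tuple[np.ndarray, dict]:
    """Relative expression profile per cluster (rows sum to 1)."""
    from scipy.stats import gamma as gamma_dist

    names, marker_idx, s_idx, g2m_idx, mito_idx = _gene_layout(config)
    base = rng.gamma(config.base_mean_shape, config.base_mean_scale, config.n_genes)
    base = np.maximum(base, 1e-8)
    # planted-program genes (markers, S, G2M) must be detectable to serve as
    # ground truth: draw their base abundance from the mid-to-upper quantiles
    # of the same gamma instead of its full range
    program = np.concatenate(
        [np.concatenate(list(marker_idx.values())), s_idx, g2m_idx]
    ).astype(int)
    if program.size:
        u = rng.uniform(0.5, 0.95, size=program.size)
        base[program] = gamma_dist.ppf(
            u, config.base_mean_shape, scale=config.base_mean_scale
        )
    # rescale the mito block to hit the target expression fraction
    f = config.mito_target_fraction
    nonmito = np.ones(config.n_genes, dtype=bool)
    nonmito[mito_idx] = False
    if config.mito_gene_count:
        base[mito_idx] *= (f / (1.0 - f)) * base[nonmito].sum() / base[mito_idx].sum()
    profiles = np.tile(base, (config.n_clusters, 1))
    for c in range(1, config.n_clusters + 1):
        profiles[c - 1, marker_idx[c]] *= config.marker_fold_change
    profiles /= profiles.sum(axis=1, keepdims=True)
    layout = {
        "names": names,
        "markers": marker_idx,
        "s": s_idx,
        "g2m": g2m_idx,
        "mito": mito_idx,
    }
    return profiles, layout


def _stage_cluster_weights(config: SimulationConfig, stage_i: int) -> np.ndarray:
    w = np.ones(config.n_clusters)
    pos = config.n_shared_clusters
    for t, n_spec in enumerate(config.n_stage_specific_clusters):
        for _ in range(n_spec):
            w[pos] = config.home_stage_weight if t == stage_i else config.off_stage_weight
            pos += 1
    return w / w.sum()


def _draw_phase(config: SimulationConfig, cluster: int, rng) -> str:
    if config.low_cycle_cluster is not None and cluster == config.low_cycle_cluster:
        g1 = config.low_cycle_g1_fraction
        rest = (1.0 - g1) / 2.0
        probs = [g1, rest, rest]
    else:
        s, g2m = config.cycle_fraction_s, config.cycle_fraction_g2m
        probs = [1.0 - s - g2m, s, g2m]
    return ("G1", "S", "G2M")[rng.choice(3, p=probs)]


def simulate_stages(
    config: SimulationConfig | None = None,
) -> tuple[list[StageCountMatrix], GroundTruth]:
    """Generate one matrix per stage plus the planted ground truth.

    Counts for cell i with relative profile w (cluster profile, cycle-program
    fold change applied to S/G2M genes for cycling cells) are drawn as
    Gamma-Poisson with mean ``L_i * w`` and NB size ``config.dispersion``,
    where ``L_i`` is log-normal per stage.  Doublets average the profiles of
    two parent cells from distinct clusters and draw a 1.5x library size.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    profiles, layout = _cluster_profiles(config, rng)
    names = layout["names"]
    mito_mask = np.zeros(config.n_genes, dtype=bool)
    mito_mask[layout["mito"]] = True

    matrices: list[StageCountMatrix] = []
    cell_rows = []
    for si in range(config.n_stages):
        stage = config.stage_labels[si]
        n_cells = config.cells_per_stage[si]
        weights = _stage_cluster_weights(config, si)
        n_doub = int(round(config.doublet_fraction * n_cells))
        is_doub = np.zeros(n_cells, dtype=bool)
        if n_doub:
            is_doub[rng.choice(n_cells, size=n_doub, replace=False)] = True
        mu_log = config.library_size_lognormal_mu[si]
        sigma = config.library_size_lognormal_sigma

        mean_mat = np.empty((n_cells, config.n_genes))
        for i in range(n_cells):
            if is_doub[i]:
                # parents come from distinct clusters when possible; with a
                # single planted cluster both parents share it
                pa, pb = rng.choice(
                    config.n_clusters, size=2,
                    replace=config.n_clusters == 1, p=weights,
                ) + 1
                w = 0.5 * (profiles[pa - 1] + profiles[pb - 1])
                lib = math.exp(rng.normal(mu_log, sigma)) * config.doublet_library_scale
                cluster, parent_a, parent_b = int(pa), int(pa), int(pb)
                phase = _draw_phase(config, cluster, rng)
            else:
                cluster = int(rng.choice(config.n_clusters, p=weights)) + 1
                w = profiles[cluster - 1].copy()
                lib = math.exp(rng.normal(mu_log, sigma))
                parent_a = parent_b = 0
                phase = _draw_phase(config, cluster, rng)
            if phase == "S":
                w = w.copy()
                w[layout["s"]] *= config.cycle_fold_change
            elif phase == "G2M":
                w = w.copy()
                w[layout["g2m"]] *= config.cycle_fold_change
            w = w / w.sum()
            mean_mat[i] = lib * w
            cell_rows.append(
                {
                    "barcode": f"{stage}_{i + 1:04d}",
                    "stage": stage,
                    "true_cluster": cluster,
                    "is_doublet": bool(is_doub[i]),
                    "parent_a": parent_a,
                    "parent_b": parent_b,
                    "true_phase": phase,
                }
            )
        lam = rng.gamma(config.dispersion, mean_mat / config.dispersion)
        counts = rng.poisson(lam).astype(np.int64)
        barcodes = [r["barcode"] for r in cell_rows[-n_cells:]]
        # upstream capture pre-filter: cells must report >= capture_min_genes genes
        keep = (counts > 0).sum(axis=1) >= config.capture_min_genes
        if not keep.all():
            counts = counts[keep]
            kept_set = {b for b, k in zip(barcodes, keep) if k}
            barcodes = [b for b in barcodes if b in kept_set]
            dropped = {
                r["barcode"]
                for r, k in zip(cell_rows[-n_cells:], keep)
                if not k
            }
            cell_rows = [r for r in cell_rows if r["barcode"] not in dropped]
        matrices.append(
            StageCountMatrix(
                counts=sp.csr_matrix(counts),
                barcodes=barcodes,
                genes=list(names),
                stage=stage,
                mito_mask=mito_mask.copy(),
            )
        )

    marker_rows = [
        {"cluster": c, "gene": names[j]}
        for c in range(1, config.n_clusters + 1)
        for j in layout["markers"][c]
    ]
    gene_rows = pd.DataFrame(
        {
            "gene": names,
            "is_mito": mito_mask,
            "is_cycle_s": np.isin(np.arange(config.n_genes), layout["s"]),
            "is_cycle_g2m": np.isin(np.arange(config.n_genes), layout["g2m"]),
        }
    )
    truth = GroundTruth(
        cells=pd.DataFrame(cell_rows),
        markers=pd.DataFrame(marker_rows),
        genes=gene_rows,
    )
    return matrices, truth


def emulation_report(matrices: list[StageCountMatrix]) -> pd.DataFrame:
    """Per-stage summary (median UMI, median detected genes, mean mito fraction).

    The statistics are invariant to cell order; all-zero matrices report
    zero medians.
    """
    rows = []
    for m in matrices:
        counts = m.counts
        total = np.asarray(counts.sum(axis=1)).ravel()
        n_genes = np.asarray((counts > 0).sum(axis=1)).ravel()
        mito = np.asarray(counts[:, m.mito_mask].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
        rows.append(
            {
                "stage": m.stage,
                "n_cells": m.n_cells,
                "median_umi": float(np.median(total)) if m.n_cells else 0.0,
                "median_genes": float(np.median(n_genes)) if m.n_cells else 0.0,
                "mean_mito_fraction": float(mito_frac.mean()) if m.n_cells else 0.0,
            }
        )
    return pd.DataFrame(rows)


def save_simulation(matrices, truth: GroundTruth, out_dir) -> None:
    """Write MTX triplets per stage plus the ground-truth CSVs."""
    from .io_formats import write_gene_set

    out_dir = Path(out_dir)
    for m in matrices:
        write_counts_mtx(m, out_dir / f"stage_{m.stage}")
    truth.save(out_dir)
    if truth.genes["is_cycle_s"].any():
        write_gene_set(truth.s_gene_set, out_dir / "s_genes.txt")
    if truth.genes["is_cycle_g2m"].any():
        write_gene_set(truth.g2m_gene_set, out_dir / "g2m_genes.txt")
    write_table(emulation_report(matrices), out_dir / "emulation_report.csv",
                "emulation_report")


def qc_violation_fixture(stage: str = "7"):
    """Deterministic QC fixture with exactly seven planted filter violations.

    60 compliant cells (35 expressing genes 1-1700 once; 25 'donor' cells
    expressing genes 1-900 and 1701-2500 once, which keeps every gene above
    the 20-cell gene filter and gives donors a tiny mito fraction) plus seven
    violators, each breaking exactly one cell-level rule at the default
    thresholds (400-1800 genes, 650-4500 UMI for stage 7, <=1% mito):

    ========== ======================= ==========================
    barcode     construction            violated rule
    ========== ======================= ==========================
    viol_low_genes_1/2  300 genes x3    n_genes < 400
    viol_high_genes     1900 genes x1   n_genes > 1800
    viol_low_umi        500 genes x1    UMI 500 < 650
    viol_high_umi       900 genes x6    UMI 5400 > 4500
    viol_mito_1/2       500 genes x2 +  mito fraction 2.9% > 1%
                        30 on a mito gene
    ========== ======================= ==========================

    Returns the matrix and a DataFrame mapping each planted violator barcode
    to its criterion label (as used in the QC filter report).
    """
    n_genes = 2500
    mito_lo = 2494  # genes 2495..2499 0-based 2494..2498 are mito
    rows, cols, vals, barcodes = [], [], [], []

    def add_cell(barcode: str, gene_counts: dict[int, int]) -> None:
        i = len(barcodes)
        barcodes.append(barcode)
        for j, v in gene_counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(v)

    for i in range(35):
        add_cell(f"ok_{i + 1:02d}", {j: 1 for j in range(1700)})
    for i in range(25):
        counts = {j: 1 for j in range(900)}
        counts.update({j: 1 for j in range(1700, 2500)})
        add_cell(f"donor_{i + 1:02d}", counts)
    expected = []
    add_cell("viol_low_genes_1", {j: 3 for j in range(300)})
    expected.append(("viol_low_genes_1", "n_genes_low"))
    add_cell("viol_low_genes_2", {j: 3 for j in range(300)})
    expected.append(("viol_low_genes_2", "n_genes_low"))
    add_cell("viol_high_genes", {j: 1 for j in range(1900)})
    expected.append(("viol_high_genes", "n_genes_high"))
    add_cell("viol_low_umi", {j: 1 for j in range(500)})
    expected.append(("viol_low_umi", "umi_low"))
    add_cell("viol_high_umi", {j: 6 for j in range(900)})
    expected.append(("viol_high_umi", "umi_high"))
    for k in (1, 2):
        counts = {j: 2 for j in range(500)}
        counts[mito_lo] = 30
        add_cell(f"viol_mito_{k}", counts)
        expected.append((f"viol_mito_{k}", "mito_high"))

    names = [f"g{i + 1:04d}" for i in range(n_genes)]
    mito_mask = np.zeros(n_genes, dtype=bool)
    for rank, j in enumerate(range(mito_lo, n_genes)):
        names[j] = f"{MITO_PREFIX}{rank + 1}"
        mito_mask[j] = True
    matrix = StageCountMatrix(
        counts=sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(barcodes), n_genes), dtype=np.int64
        ),
        barcodes=barcodes,
        genes=names,
        stage=stage,
        mito_mask=mito_mask,
    )
    expected_df = pd.DataFrame(expected, columns=["barcode", "criterion"])
    return matrix, expected_df
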