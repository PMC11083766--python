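# stagesc

Multi-stage single-cell RNA-seq analysis pipeline with planted-truth
validation: per-stage quality control and doublet removal, integrated Leiden
clustering, Wilcoxon marker detection, hypergeometric marker-list
concordance between cluster sets, an adjusted-Rand-index stability sweep,
cell-cycle phase scoring, and rule-based reconciliation of two genome
annotations.

The package targets the analysis pattern of staged embryonic atlases (the
motivating system is spider embryogenesis, stages 7 / 8.1 / 9.1 profiled by
combinatorial split-pool barcoding): several developmental stages are
dissociated and sequenced separately, QC'd with stage-specific thresholds,
integrated, clustered, and then *compared* — do independently clustered
stages find the same cell types, and how stable is the integrated clustering
under its hyperparameters? Everything is exercised end to end on a
negative-binomial simulator with planted clusters, markers, doublets and
cell-cycle programs, so every statistic ships with a test that measures
recovery of known truth.

## The statistics at the core

**Marker concordance.** For clusters x and y from two datasets with marker
sets of sizes m_x, m_y drawn from a pool of N genes (the total gene count of
the expression matrix), the overlap k is scored with the inclusive
hypergeometric upper tail

    p = P(X >= k),  X ~ Hypergeometric(N, m_x, m_y)

Bonferroni-corrected over all cluster pairs; each cluster's best match is
the row-minimum adjusted p, unmatched above alpha = 0.05.

**Clustering stability.** Clusterings across a grid of HVG thresholds
(1.2–1.7) and integration strengths λ (mapping anchor counts 5–45) are
compared all-vs-all with the adjusted Rand index

    ARI = (Σ_ij C(n_ij,2) − E) / (½[Σ_i C(a_i,2) + Σ_j C(b_j,2)] − E),
    E = Σ_i C(a_i,2) · Σ_j C(b_j,2) / C(n,2)

computed in exact rational arithmetic; the most stable grid point is the
medoid (maximal mean ARI to the rest of the grid).

**Markers.** One-vs-rest Wilcoxon rank-sum (exact enumeration for small
groups, tie- and continuity-corrected normal otherwise), expression-fraction
pre-filter pct_in ≥ 0.25, Bonferroni over all genes in the matrix, adjusted
p ≤ 1e-5.

QC thresholds, pipeline parameters (HVG threshold 1.3, 50 PCs, k = 100
neighbors, Leiden resolution 1.2, seed 42) and the 5% doublet-removal rate
follow the motivating study; `docs/methods.md` documents every model,
default and substitution.

## Worked example

```python
from stagesc import (
    SimulationConfig, simulate_stages, emulation_report,
    filter_cells_genes, run_pipeline, PipelineParams,
    find_markers, adjusted_rand_index,
)

matrices, truth = simulate_stages(SimulationConfig(seed=1))
print(emulation_report(matrices).to_string(index=False))

filtered = [filter_cells_genes(m)[0] for m in matrices]
result = run_pipeline(filtered, PipelineParams())
planted = truth.cells.set_index("barcode").loc[
    result.clustering.barcodes, "true_cluster"
].to_numpy()
print("clusters:", result.clustering.n_clusters,
      " ARI vs planted:", round(adjusted_rand_index(planted, result.clustering.labels), 3))
print("marker records:", len(find_markers(result.normalized, result.clustering)))
```

prints

```
stage  n_cells  median_umi  median_genes  mean_mito_fraction
    7      600      1519.5         715.5            0.004563
  8.1      600      1672.5         750.5            0.004572
  9.1      900      1350.5         674.5            0.004667
clusters: 8  ARI vs planted: 0.945
marker records: 240
```

Three stages of 600/600/900 simulated cells hit the emulated per-stage
median UMI targets (1465/1656/1343, within 15%) at under 0.5% mitochondrial
expression; the integrated pipeline recovers all 8 planted clusters almost
exactly (ARI 0.95 here, higher still after doublet removal), and marker
detection returns the 240 planted marker genes (30 per cluster) at the
default thresholds.

The same steps are available as CLI subcommands (`stagesc simulate`, `qc`,
`cluster`, `markers`, `concord`, `sweep`, `cellcycle`, `dendro`,
`annotmerge`); every subcommand is seeded and byte-reproducible.

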