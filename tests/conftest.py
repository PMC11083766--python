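"""Shared fixtures: simulated datasets are expensive, so they are cached
per seed at session scope and reused across module and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from stagesc import (
    DoubletParams,
    PipelineParams,
    SimulationConfig,
    doublet_scores,
    filter_cells_genes,
    normalize,
    remove_doublets,
    run_pipeline,
    simulate_stages,
)


@pytest.fixture(scope="session")
def sim_cache():
    """Factory returning (matrices, truth) for a seed, computed once."""
    cache: dict[int, tuple] = {}

    def get(seed: int):
        if seed not in cache:
            cache[seed] = simulate_stages(SimulationConfig(seed=seed))
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def processed_cache(sim_cache):
    """Factory: per seed, QC-filter each stage, score and remove 5% doublets.

    Returns (qc_matrices, truth, per_stage_doublet_info) where the doublet
    info holds, per stage, (pre-removal barcodes, scores, removed indices).
    """
    cache: dict[int, tuple] = {}

    def get(seed: int):
        if seed not in cache:
            matrices, truth = sim_cache(seed)
            filtered, info = [], []
            for m in matrices:
                f, _ = filter_cells_genes(m)
                norm = normalize(f)
                scores = doublet_scores(norm.values, DoubletParams(seed=seed))
                keep, removed = remove_doublets(scores, expected_rate=0.05)
                info.append((list(f.barcodes), scores, removed))
                filtered.append(f.subset(cell_idx=keep))
            cache[seed] = (filtered, truth, info)
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def pipeline_cache(processed_cache):
    """Factory: full pipeline result (default parameters) per seed."""
    cache: dict[int, tuple] = {}

    def get(seed: int):
        if seed not in cache:
            filtered, truth, _ = processed_cache(seed)
            result = run_pipeline(filtered, PipelineParams())
            cache[seed] = (result, truth)
        return cache[seed]

    return get


def true_labels(truth, barcodes, column: str = "true_cluster") -> np.ndarray:
    """Ground-truth values aligned to a barcode order."""
    return truth.cells.set_index("barcode").loc[list(barcodes), column].to_numpy()


@pytest.fixture(scope="session")
def small_noise_config():
    """Single-cluster iid NB noise (constant library size, no programs)."""

    def make(seed: int = 7, n_clusters: int = 1, sigma: float = 0.0, cells: int = 400):
        return SimulationConfig(
            n_stages=1,
            cells_per_stage=(cells,),
            stage_labels=("7",),
            library_size_lognormal_mu=(float(np.log(1465.0)),),
            library_size_lognormal_sigma=sigma,
            n_shared_clusters=n_clusters,
            n_stage_specific_clusters=(0,),
            markers_per_cluster=0 if n_clusters == 1 else 30,
            cycle_fraction_s=0.0,
            cycle_fraction_g2m=0.0,
            s_gene_count=0,
            g2m_gene_count=0,
            doublet_fraction=0.0,
            low_cycle_cluster=None,
            seed=seed,
        )

    return make
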