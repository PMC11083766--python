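"""Adjusted Rand index and the integration-stability hyperparameter sweep.

The sweep mirrors the study's grid: HVG thresholds 1.2-1.7 crossed with
integration strengths standing in for anchor counts 5-45 (mapped linearly
onto λ 0.1-0.9).  Each grid point is clustered with a fixed seed and all
grid-point pairs are compared with the ARI; the "most stable" point is the
medoid — the point with the highest mean ARI to all others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .io_formats import StageCountMatrix
from .pipeline import (
    Clustering,
    PipelineParams,
    integrate_stage_embeddings,
    knn_graph,
    leiden_cluster,
    normalize,
    pca,
    concat_stages,
    select_hvgs,
)

__all__ = [
    "adjusted_rand_index",
    "anchors_to_strength",
    "SweepResult",
    "sweep",
    "stable_region",
    "DEFAULT_HVG_GRID",
    "DEFAULT_STRENGTH_GRID",
]

# the study's grids: HVG threshold 1.2-1.7 (step 0.1), anchors 5-45 (step 5)
DEFAULT_HVG_GRID = tuple(round(1.2 + 0.1 * i, 1) for i in range(6))
DEFAULT_ANCHOR_GRID = tuple(range(5, 46, 5))


def anchors_to_strength(anchors: float) -> float:
    """Linear map of the anchor-count dial (5-45) onto λ in [0.1, 0.9].

    Both are monotone integration-strength dials; the mapping is a
    documented convention, not an equivalence claim.
    """
    return 0.1 + 0.8 * (anchors - 5) / 40.0


DEFAULT_STRENGTH_GRID = tuple(round(anchors_to_strength(a), 3) for a in DEFAULT_ANCHOR_GRID)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected Rand index from the contingency-table formula.

    ARI = (sum_ij C(n_ij,2) - E) / (M - E) with
    E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2) and
    M = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2, evaluated in exact rational
    arithmetic.  1 for identical partitions; can be negative for
    worse-than-chance agreement (raw values are reported).  Two trivial
    identical partitions (denominator 0) return 1.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("ARI requires at least 2 items")

    def comb2(x: int) -> int:
        return x * (x - 1) // 2

    from collections import Counter

    cont: Counter = Counter(zip(a.tolist(), b.tolist()))
    row = Counter(a.tolist())
    col = Counter(b.tolist())
    sum_ij = sum(comb2(v) for v in cont.values())
    sum_a = sum(comb2(v) for v in row.values())
    sum_b = sum(comb2(v) for v in col.values())
    total = comb2(n)
    expected = Fraction(sum_a * sum_b, total)
    max_index = Fraction(sum_a + sum_b, 2)
    if max_index == expected:
        return 1.0
    return float(Fraction(sum_ij) - expected) / float(max_index - expected)


@dataclass
class SweepResult:
    """Clusterings and all-vs-all ARI over the hyperparameter grid."""

    grid: list[tuple[float, float]]  # (hvg_threshold, strength)
    clusterings: dict[tuple[float, float], Clustering]
    ari: pd.DataFrame  # symmetric, unit diagonal; index/columns = grid keys
    flagged: list[tuple[float, float]] = field(default_factory=list)  # single-cluster points

    def long_table(self) -> pd.DataFrame:
        rows = []
        for ka in self.ari.index:
            for kb in self.ari.columns:
                rows.append({"run_a": ka, "run_b": kb, "ari": self.ari.loc[ka, kb]})
        return pd.DataFrame(rows)


def _grid_key(t: float, lam: float) -> str:
    return f"hvg={t:g}|lambda={lam:g}"


def sweep(
    matrices: list[StageCountMatrix],
    hvg_thresholds=DEFAULT_HVG_GRID,
    strengths=DEFAULT_STRENGTH_GRID,
    params: PipelineParams | None = None,
    seed: int | None = None,
) -> SweepResult:
    """Cluster every (HVG threshold, λ) grid point and compare all pairs.

    Normalization and the merged matrix are shared across the grid; PCA is
    recomputed per threshold and integration/graph/Leiden per grid point,
    all with one fixed seed so the sweep is reproducible end to end.  Grid
    points yielding a single cluster are flagged but still compared.
    """
    params = params or PipelineParams()
    if seed is not None:
        params = PipelineParams(
            hvg_threshold=params.hvg_threshold,
            n_pcs=params.n_pcs,
            knn_k=params.knn_k,
            leiden_resolution=params.leiden_resolution,
            integration_strength=params.integration_strength,
            seed=seed,
        )
    merged = concat_stages(matrices) if len(matrices) > 1 else matrices[0]
    norm = normalize(merged)
    clusterings: dict[tuple[float, float], Clustering] = {}
    flagged = []
    grid = [(t, lam) for t in hvg_thresholds for lam in strengths]
    for t in hvg_thresholds:
        hvgs = select_hvgs(norm, t)
        emb = pca(norm, hvgs, n_pcs=params.n_pcs, seed=params.seed)
        for lam in strengths:
            integrated = integrate_stage_embeddings(emb.scores, norm.stages, lam)
            graph = knn_graph(integrated, k=min(params.knn_k, norm.n_cells - 1))
            cl = leiden_cluster(
                graph, resolution=params.leiden_resolution, seed=params.seed,
                params_hash=_grid_key(t, lam),
            )
            clusterings[(t, lam)] = cl
            if cl.n_clusters <= 1:
                flagged.append((t, lam))
    keys = [_grid_key(t, lam) for t, lam in grid]
    ari = pd.DataFrame(np.eye(len(grid)), index=keys, columns=keys)
    for i, gi in enumerate(grid):
        for j in range(i + 1, len(grid)):
            v = adjusted_rand_index(
                clusterings[gi].labels, clusterings[grid[j]].labels
            )
            ari.iloc[i, j] = v
            ari.iloc[j, i] = v
    return SweepResult(grid=grid, clusterings=clusterings, ari=ari, flagged=flagged)


def stable_region(result: SweepResult) -> tuple[float, float]:
    """Medoid grid point: maximal mean ARI to all other grid points.

    Formalizes "most stable" as the point whose clustering agrees best with
    the rest of the grid on average; ties break toward smaller λ, then
    smaller HVG threshold.
    """
    n = len(result.grid)
    if n == 0:
        raise ValueError("empty sweep grid")
    if n == 1:
        return result.grid[0]
    best = None
    best_score = -np.inf
    for i, (t, lam) in enumerate(result.grid):
        others = [result.ari.iloc[i, j] for j in range(n) if j != i]
        score = float(np.mean(others))
        if (
            best is None
            or score > best_score + 1e-12
            or (abs(score - best_score) <= 1e-12 and (lam, t) < (best[1], best[0]))
        ):
            best = (t, lam)
            best_score = score
    return best
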