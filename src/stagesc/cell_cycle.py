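"""Cell-cycle module scoring and phase assignment.

Implements the binned-control module score behind the usual single-cell
cell-cycle call: genes are binned by mean expression, each gene-set member
draws expression-matched control genes from its bin, and a cell's score is
the mean expression of the set minus the mean expression of the controls.
Phase is G1 when both the S and G2/M scores are non-positive, otherwise the
larger score wins.  Clusters with more than 25% G1 cells are flagged as
low-cycling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_formats import GeneSet
from .pipeline import Clustering, NormalizedExpression

__all__ = ["module_score", "assign_phase", "cycle_scores", "phase_fractions"]


def module_score(
    normalized: NormalizedExpression,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Binned-control module score per cell.

    Genes are ranked by mean expression across cells and cut into ``n_bins``
    equal-size bins; for each gene-set member, up to ``n_ctrl`` control genes
    are sampled (without replacement, seeded) from the member's bin.  The
    score is mean(set expression) - mean(control expression) per cell, so a
    cell with identical expression everywhere scores exactly 0.  Members
    absent from the matrix are dropped with a warning; an empty set after
    dropping is an error.
    """
    values = normalized.values
    n_genes = values.shape[1]
    if n_genes < n_bins:
        raise ValueError(f"need >= {n_bins} genes for {n_bins} expression bins")
    pos = {g: j for j, g in enumerate(normalized.genes)}
    members = [pos[g] for g in gene_set.genes if g in pos]
    dropped = len(gene_set.genes) - len(members)
    if dropped:
        warnings.warn(
            f"{dropped} gene(s) of set {gene_set.name!r} absent from the matrix",
            stacklevel=2,
        )
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} is empty after dropping")
    rng = np.random.default_rng(seed)
    avg = values.mean(axis=0)
    # equal-size bins over the mean-expression ranking (ties broken by index)
    order = np.lexsort((np.arange(n_genes), avg))
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = (np.arange(n_genes) * n_bins) // n_genes
    member_set = set(members)
    ctrl: list[int] = []
    for j in members:
        candidates = np.flatnonzero(bin_of == bin_of[j])
        candidates = candidates[[c not in member_set for c in candidates]]
        if candidates.size == 0:
            continue
        take = min(n_ctrl, candidates.size)
        ctrl.extend(rng.choice(candidates, size=take, replace=False).tolist())
    if not ctrl:
        raise ValueError("no control genes available for module scoring")
    return values[:, members].mean(axis=1) - values[:, sorted(set(ctrl))].mean(axis=1)


def assign_phase(s_score, g2m_score) -> np.ndarray:
    """Phase call per cell: G1 if both scores <= 0, else the larger score.

    An exact positive tie is called S.  Vectorized over arrays; scalar inputs
    return a 0-d array convertible with ``str()``.
    """
    s = np.asarray(s_score, dtype=float)
    g = np.asarray(g2m_score, dtype=float)
    if not (np.isfinite(s).all() and np.isfinite(g).all()):
        raise ValueError("phase assignment requires finite scores")
    out = np.where((s <= 0) & (g <= 0), "G1", np.where(s >= g, "S", "G2M"))
    return out


def cycle_scores(
    normalized: NormalizedExpression,
    s_genes: GeneSet,
    g2m_genes: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """S and G2/M module scores plus the phase call, one row per cell."""
    s = module_score(normalized, s_genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    g = module_score(normalized, g2m_genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + 1)
    return pd.DataFrame(
        {
            "barcode": normalized.barcodes,
            "s_score": s,
            "g2m_score": g,
            "phase": assign_phase(s, g),
        }
    )


def phase_fractions(
    clustering: Clustering, phases, g1_threshold: float = 0.25
) -> pd.DataFrame:
    """Per-cluster phase fractions and the >25%-G1 low-cycling flag."""
    labels = np.asarray(clustering.labels)
    phases = np.asarray(phases)
    if labels.shape != phases.shape:
        raise ValueError("labels and phases must align")
    rows = []
    for c in np.unique(labels):
        mask = labels == c
        n = mask.sum()
        frac = {ph: float((phases[mask] == ph).sum()) / n for ph in ("G1", "S", "G2M")}
        rows.append(
            {
                "cluster": int(c),
                "fraction_G1": frac["G1"],
                "fraction_S": frac["S"],
                "fraction_G2M": frac["G2M"],
                "g1_flag": frac["G1"] > g1_threshold,
            }
        )
    return pd.DataFrame(rows)
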