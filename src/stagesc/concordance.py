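"""Hypergeometric marker-list concordance between cluster sets.

Two clusterings (e.g. two stages, or integrated vs per-stage runs) are
compared all-vs-all: for each cluster pair, the overlap k between their
marker lists is tested against a Hypergeometric(N, m_x, m_y) null where the
pool N is the total number of genes in the expression matrix, with Bonferroni
correction across all tested pairs.  Utilities for best-match assignment,
cluster mean-expression profiles, Pearson profile correlation, and an
average-linkage cluster dendrogram round out the module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.special import gammaln, logsumexp

from .pipeline import Clustering, NormalizedExpression

__all__ = [
    "hypergeom_upper_tail",
    "marker_overlap_tests",
    "best_match",
    "cluster_mean_profiles",
    "profile_correlation",
    "cluster_dendrogram",
]


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(
    k: int, m_x: int, m_y: int, N: int, inclusive: bool = True
) -> float:
    """P(X >= k) for X ~ Hypergeometric(pool N, successes m_x, draws m_y).

    Computed as a log-space sum of hypergeometric point masses for numerical
    stability; symmetric in (m_x, m_y).  ``inclusive=False`` gives the strict
    tail P(X > k).  P(X >= 0) is exactly 1; the tail is non-increasing in k.
    """
    for name, v in (("k", k), ("m_x", m_x), ("m_y", m_y), ("N", N)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if m_x > N or m_y > N:
        raise ValueError(f"marker counts ({m_x}, {m_y}) exceed pool N={N}")
    if k > min(m_x, m_y):
        raise ValueError(f"overlap k={k} exceeds min(m_x, m_y)={min(m_x, m_y)}")
    lo = k if inclusive else k + 1
    lo = max(lo, m_x + m_y - N, 0)
    hi = min(m_x, m_y)
    if lo > hi:
        return 0.0
    if lo <= max(0, m_x + m_y - N):
        return 1.0
    i = np.arange(lo, hi + 1)
    log_terms = (
        _log_binom(m_x, i) + _log_binom(N - m_x, m_y - i) - _log_binom(N, m_y)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def _marker_sets(table: pd.DataFrame) -> dict[str, set]:
    sets: dict[str, set] = {}
    for c, grp in table.groupby("cluster", sort=False):
        sets[str(c)] = set(grp["gene"])
    return sets


def _cluster_sort_key(c: str):
    try:
        return (0, int(c), c)
    except ValueError:
        return (1, 0, c)


def marker_overlap_tests(
    markers_x: pd.DataFrame,
    markers_y: pd.DataFrame,
    n_pool: int | None = None,
    universe_x: list | None = None,
    universe_y: list | None = None,
    inclusive: bool = True,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """All-vs-all hypergeometric overlap tests between two marker tables.

    The pool size N is either supplied explicitly (``n_pool`` — the total
    number of genes in the shared expression matrix) or derived as the size
    of the intersection of the two gene universes, in which case markers
    outside the intersection are dropped (their counts appear in the
    DataFrame's ``attrs['dropped_x'/'dropped_y']``).  Overlaps use unique
    gene IDs.  Clusters with zero markers are recorded with p_raw = 1 and
    flagged.  Correction is Bonferroni over all tested pairs ("bh" is
    available as an alternative).
    """
    sets_x = _marker_sets(markers_x)
    sets_y = _marker_sets(markers_y)
    dropped_x = dropped_y = 0
    if n_pool is None:
        if universe_x is None or universe_y is None:
            raise ValueError("supply either n_pool or both gene universes")
        universe = set(universe_x) & set(universe_y)
        n_pool = len(universe)
        # cluster keys survive even if all their markers fall outside the pool
        for sets in (sets_x, sets_y):
            for c in sets:
                kept = sets[c] & universe
                if sets is sets_x:
                    dropped_x += len(sets[c]) - len(kept)
                else:
                    dropped_y += len(sets[c]) - len(kept)
                sets[c] = kept
    rows = []
    for cx in sorted(sets_x, key=_cluster_sort_key):
        for cy in sorted(sets_y, key=_cluster_sort_key):
            mx, my = sets_x[cx], sets_y[cy]
            k = len(mx & my)
            if len(mx) == 0 or len(my) == 0:
                p = 1.0
                flagged = True
            else:
                p = hypergeom_upper_tail(k, len(mx), len(my), n_pool,
                                         inclusive=inclusive)
                flagged = False
            rows.append(
                {
                    "cluster_x": cx,
                    "cluster_y": cy,
                    "m_x": len(mx),
                    "m_y": len(my),
                    "k": k,
                    "n_pool": n_pool,
                    "p_raw": p,
                    "zero_markers": flagged,
                }
            )
    out = pd.DataFrame(rows)
    n_pairs = len(out)
    if correction == "bonferroni":
        out["p_adj"] = np.minimum(1.0, out["p_raw"] * n_pairs)
    elif correction == "bh":
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    out.attrs["dropped_x"] = dropped_x
    out.attrs["dropped_y"] = dropped_y
    return out


def best_match(overlaps: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Row-wise best counterpart: argmin p_adj per cluster_x.

    Ties are broken by larger overlap k, then smaller cluster_y ID; a cluster
    is unmatched when its best p_adj exceeds alpha.
    """
    rows = []
    for cx, grp in overlaps.groupby("cluster_x", sort=False):
        grp = grp.assign(_key=grp["cluster_y"].map(_cluster_sort_key))
        grp = grp.sort_values(["p_adj", "k", "_key"], ascending=[True, False, True],
                              kind="mergesort")
        top = grp.iloc[0]
        rows.append(
            {
                "cluster_x": cx,
                "cluster_y": top["cluster_y"],
                "p_adj": top["p_adj"],
                "k": int(top["k"]),
                "matched": bool(top["p_adj"] <= alpha),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        "cluster_x", key=lambda s: s.map(_cluster_sort_key), kind="mergesort"
    ).reset_index(drop=True)


def cluster_mean_profiles(
    normalized: NormalizedExpression,
    clustering: Clustering,
    genes: list[str],
) -> pd.DataFrame:
    """Per-cluster arithmetic mean of normalized expression over a gene set.

    Rows are cluster IDs, columns the requested genes (which must be present
    in the matrix); invariant to cell order.
    """
    if not genes:
        raise ValueError("empty gene set")
    pos = {g: j for j, g in enumerate(normalized.genes)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise KeyError(f"genes absent from the matrix: {missing[:5]}")
    idx = np.array([pos[g] for g in genes])
    labels = np.asarray(clustering.labels)
    rows = {
        int(c): normalized.values[labels == c][:, idx].mean(axis=0)
        for c in np.unique(labels)
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=genes).sort_index()


def profile_correlation(profile_a, profile_b) -> float:
    """Pearson correlation between two per-cluster expression profiles."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if len(a) < 3:
        raise ValueError("profile correlation requires length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("profile with zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def cluster_dendrogram(profiles: pd.DataFrame) -> str:
    """Average-linkage hierarchy of cluster profiles as a newick string.

    Euclidean distance between mean profiles, UPGMA agglomeration, leaves
    labeled with cluster IDs; profiles are sorted by cluster ID first so ties
    resolve deterministically.  Branch lengths are derived from merge heights.
    """
    if profiles.shape[0] < 2:
        raise ValueError("dendrogram requires at least 2 clusters")
    profiles = profiles.sort_index()
    Z = linkage(profiles.values, method="average", metric="euclidean")
    root = to_tree(Z)
    names = [str(i) for i in profiles.index]

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = walk(root.left, root.dist)
    right = walk(root.right, root.dist)
    return f"({left},{right});"
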