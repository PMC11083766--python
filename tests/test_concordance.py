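"""Hypergeometric overlap testing, best-match assignment, profiles, dendrogram."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from stagesc import (
    best_match,
    cluster_dendrogram,
    cluster_mean_profiles,
    hypergeom_upper_tail,
    marker_overlap_tests,
    profile_correlation,
)
from stagesc.pipeline import Clustering, NormalizedExpression


def enumerate_upper_tail(k, m_x, m_y, N):
    """Brute-force P(|S ∩ X| >= k) over all C(N, m_y) draws S."""
    x_set = set(range(m_x))
    hits = total = 0
    for draw in itertools.combinations(range(N), m_y):
        total += 1
        if len(x_set.intersection(draw)) >= k:
            hits += 1
    return hits / total


def _marker_table(cluster_to_genes):
    rows = [
        {"cluster": c, "gene": g, "pct_in": 0.5, "pct_out": 0.1, "log2_fc": 1.0,
         "p_raw": 1e-9, "p_adj": 1e-6, "direction": "up"}
        for c, genes in cluster_to_genes.items()
        for g in genes
    ]
    return pd.DataFrame(rows)


class TestHypergeomUpperTail:
    @pytest.mark.parametrize(
        "k, mx, my, N, expect",
        [
            (0, 3, 4, 10, 1.0),
            (2, 3, 4, 10, 1 / 3),
            (3, 3, 3, 6, 0.05),
        ],
    )
    def test_hand_derived_values(self, k, mx, my, N, expect):
        assert hypergeom_upper_tail(k, mx, my, N) == pytest.approx(expect, abs=1e-12)

    def test_matches_enumeration_on_sample(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            N = int(rng.integers(2, 11))
            mx = int(rng.integers(0, N + 1))
            my = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(mx, my) + 1))
            got = hypergeom_upper_tail(k, mx, my, N)
            assert got == pytest.approx(enumerate_upper_tail(k, mx, my, N), abs=1e-12)

    def test_non_increasing_in_k(self):
        ps = [hypergeom_upper_tail(k, 6, 8, 30) for k in range(7)]
        assert ps == sorted(ps, reverse=True)
        assert ps[0] == 1.0

    def test_symmetric_in_marker_counts(self):
        assert hypergeom_upper_tail(3, 5, 9, 40) == pytest.approx(
            hypergeom_upper_tail(3, 9, 5, 40), rel=1e-12
        )

    def test_scipy_survival_cross_check(self):
        from scipy.stats import hypergeom

        for k, mx, my, N in [(4, 20, 30, 500), (1, 3, 3, 2000), (10, 40, 60, 1500)]:
            assert hypergeom_upper_tail(k, mx, my, N) == pytest.approx(
                float(hypergeom.sf(k - 1, N, mx, my)), rel=1e-9
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k": 4, "m_x": 3, "m_y": 5, "N": 10},
            {"k": 1, "m_x": 11, "m_y": 5, "N": 10},
            {"k": -1, "m_x": 3, "m_y": 5, "N": 10},
        ],
    )
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(**kwargs)


class TestMarkerOverlapTests:
    def test_identity_comparison_minimizes_diagonal(self):
        table = _marker_table({"1": ["a", "b", "c"], "2": ["d", "e"], "3": ["f", "g", "h"]})
        out = marker_overlap_tests(table, table, n_pool=100)
        for c in ["1", "2", "3"]:
            row = out[out["cluster_x"] == c]
            diag = row[row["cluster_y"] == c]["p_adj"].iloc[0]
            assert diag == row["p_adj"].min()
            col = out[out["cluster_y"] == c]
            assert diag == col["p_adj"].min()

    def test_disjoint_lists_have_unit_p(self):
        out = marker_overlap_tests(
            _marker_table({"1": ["a", "b"]}), _marker_table({"1": ["c", "d"]}),
            n_pool=50,
        )
        assert out["k"].iloc[0] == 0
        assert out["p_raw"].iloc[0] == 1.0

    def test_swap_transposes_with_identical_p(self):
        tx = _marker_table({"1": ["a", "b", "c"], "2": ["c", "d"]})
        ty = _marker_table({"1": ["b", "c"], "2": ["e", "f", "a"]})
        ab = marker_overlap_tests(tx, ty, n_pool=60)
        ba = marker_overlap_tests(ty, tx, n_pool=60)
        merged = ab.merge(
            ba, left_on=["cluster_x", "cluster_y"], right_on=["cluster_y", "cluster_x"],
            suffixes=("", "_t"),
        )
        assert np.allclose(merged["p_raw"], merged["p_raw_t"])
        assert (merged["k"] == merged["k_t"]).all()
        assert (merged["m_x"] == merged["m_y_t"]).all()

    def test_markers_outside_intersection_counted_as_dropped(self):
        tx = _marker_table({"1": ["zz", "a"]})
        ty = _marker_table({"1": ["a"], "2": ["b"]})
        out = marker_overlap_tests(tx, ty, universe_x=["zz", "a", "b"],
                                   universe_y=["a", "b"])
        assert out.attrs["dropped_x"] == 1
        assert out.attrs["dropped_y"] == 0
        assert (out["m_x"] == 1).all()

    def test_intersection_universe_pool(self):
        tx = _marker_table({"1": ["a", "b"]})
        ty = _marker_table({"1": ["a", "c"]})
        out = marker_overlap_tests(
            tx, ty, universe_x=list("abdef"), universe_y=list("acdef")
        )
        # universe intersection = {a, d, e, f}; markers b and c dropped
        assert out["n_pool"].iloc[0] == 4
        assert out["m_x"].iloc[0] == 1 and out["m_y"].iloc[0] == 1
        assert out["k"].iloc[0] == 1

    def test_bonferroni_monotone_in_pair_count(self):
        tx_small = _marker_table({"1": ["a", "b"]})
        tx_big = _marker_table({"1": ["a", "b"], "2": ["c"], "3": ["d"]})
        ty = _marker_table({"1": ["a", "b"], "2": ["e"]})
        p_small = marker_overlap_tests(tx_small, ty, n_pool=40)
        p_big = marker_overlap_tests(tx_big, ty, n_pool=40)
        row_s = p_small.query("cluster_x == '1' and cluster_y == '1'")["p_adj"].iloc[0]
        row_b = p_big.query("cluster_x == '1' and cluster_y == '1'")["p_adj"].iloc[0]
        assert row_b >= row_s


class TestBestMatch:
    def test_identity_experiment_maps_to_itself(self):
        table = _marker_table({"1": ["a", "b", "c"], "2": ["d", "e", "f"]})
        out = marker_overlap_tests(table, table, n_pool=1000)
        bm = best_match(out)
        assert dict(zip(bm["cluster_x"], bm["cluster_y"])) == {"1": "1", "2": "2"}
        assert bm["matched"].all()

    def test_alpha_zero_unmatches_everything(self):
        table = _marker_table({"1": ["a", "b", "c"]})
        bm = best_match(marker_overlap_tests(table, table, n_pool=1000), alpha=0.0)
        assert not bm["matched"].any()

    def test_tie_breaks_by_overlap_then_id(self):
        df = pd.DataFrame(
            {
                "cluster_x": ["1"] * 3,
                "cluster_y": ["3", "2", "10"],
                "m_x": [5] * 3,
                "m_y": [5] * 3,
                "k": [2, 3, 3],
                "n_pool": [100] * 3,
                "p_raw": [0.01] * 3,
                "p_adj": [0.03] * 3,
            }
        )
        bm = best_match(df)
        assert bm["cluster_y"].iloc[0] == "2"  # larger k wins, then smaller ID


class TestProfiles:
    def _norm(self):
        rng = np.random.default_rng(0)
        values = rng.poisson(2.0, size=(9, 5)).astype(float)
        return NormalizedExpression(
            values=values,
            barcodes=[f"b{i}" for i in range(9)],
            genes=[f"g{j}" for j in range(5)],
            stages=np.repeat("7", 9),
        )

    def test_singleton_cluster_profile_equals_cell(self):
        norm = self._norm()
        labels = np.arange(1, 10)
        prof = cluster_mean_profiles(
            norm, Clustering(labels=labels, resolution=1, params_hash=""),
            genes=["g0", "g3"],
        )
        assert np.allclose(prof.loc[4].values, norm.values[3, [0, 3]])

    def test_invariant_to_cell_order(self):
        norm = self._norm()
        labels = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
        perm = np.random.default_rng(1).permutation(9)
        norm_p = NormalizedExpression(
            values=norm.values[perm], barcodes=[norm.barcodes[i] for i in perm],
            genes=norm.genes, stages=norm.stages[perm],
        )
        a = cluster_mean_profiles(norm, Clustering(labels, 1, ""), norm.genes)
        b = cluster_mean_profiles(norm_p, Clustering(labels[perm], 1, ""), norm.genes)
        assert np.allclose(a.values, b.values)

    def test_missing_gene_rejected(self):
        with pytest.raises(KeyError):
            cluster_mean_profiles(
                self._norm(), Clustering(np.ones(9, dtype=int), 1, ""), ["nope"]
            )

    def test_planted_markers_peak_in_their_cluster(self, pipeline_cache):
        result, truth = pipeline_cache(1)
        from conftest import true_labels

        labels = true_labels(truth, result.normalized.barcodes)
        clust = Clustering(labels=labels, resolution=0, params_hash="")
        sample = truth.markers.groupby("cluster").head(3)
        present = [g for g in sample["gene"] if g in result.normalized.genes]
        prof = cluster_mean_profiles(result.normalized, clust, present)
        for _, row in sample.iterrows():
            if row["gene"] in present:
                assert prof[row["gene"]].idxmax() == row["cluster"]


class TestProfileCorrelation:
    def test_self_correlation_is_one(self):
        assert profile_correlation([1.0, 2.0, 5.0], [1.0, 2.0, 5.0]) == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        a = np.array([1.0, 2.0, 5.0])
        assert profile_correlation(a, -a) == pytest.approx(-1.0)

    def test_perfect_linearity(self):
        assert profile_correlation([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            profile_correlation([1, 1, 1], [1, 2, 3])


class TestDendrogram:
    def test_identical_profiles_merge_at_height_zero(self):
        prof = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], index=[1, 2, 3])
        newick = cluster_dendrogram(prof)
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.is_rooted = True
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {"1", "2", "3"}
        # 1 and 2 are siblings below 3
        mrca = tree.mrca(taxon_labels=["1", "2"])
        assert {leaf.taxon.label for leaf in mrca.leaf_iter()} == {"1", "2"}

    def test_outlier_merges_last(self):
        prof = pd.DataFrame([[0.0], [1.0], [10.0]], index=[1, 2, 3])
        newick = cluster_dendrogram(prof)
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.is_rooted = True
        mrca = tree.mrca(taxon_labels=["1", "2"])
        assert {leaf.taxon.label for leaf in mrca.leaf_iter()} == {"1", "2"}

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_dendrogram(pd.DataFrame([[1.0]], index=[1]))
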