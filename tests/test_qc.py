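"""QC metrics, threshold filtering, and pANN doublet scoring."""

import numpy as np
import pytest
import scipy.sparse as sp

from stagesc import (
    DoubletParams,
    QCThresholds,
    SimulationConfig,
    StageCountMatrix,
    compute_cell_qc,
    doublet_scores,
    filter_cells_genes,
    normalize,
    qc_violation_fixture,
    remove_doublets,
    simulate_stages,
)
from conftest import true_labels


def _matrix(counts, mito=None, stage="7"):
    counts = np.asarray(counts)
    return StageCountMatrix(
        sp.csr_matrix(counts),
        [f"b{i}" for i in range(counts.shape[0])],
        [f"g{j}" for j in range(counts.shape[1])],
        stage,
        mito_mask=mito,
    )


class TestCellQC:
    def test_arithmetic_on_known_cell(self):
        m = _matrix([[5, 0, 3]], mito=[False, False, True])
        qc = compute_cell_qc(m)
        assert qc.loc[0, "total_umi"] == 8
        assert qc.loc[0, "n_genes"] == 2
        assert qc.loc[0, "mito_fraction"] == pytest.approx(0.375)

    def test_all_zero_cell_defined_as_zero(self):
        m = _matrix([[0, 0, 0]], mito=[True, False, False])
        qc = compute_cell_qc(m)
        assert qc.loc[0, "total_umi"] == 0
        assert qc.loc[0, "n_genes"] == 0
        assert qc.loc[0, "mito_fraction"] == 0.0

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 5, size=(6, 10))
        mito = np.zeros(10, dtype=bool)
        mito[3] = True
        m = _matrix(counts, mito=mito)
        perm = rng.permutation(10)
        mp = _matrix(counts[:, perm], mito=mito[perm])
        a = compute_cell_qc(m).drop(columns="barcode")
        b = compute_cell_qc(mp).drop(columns="barcode")
        assert np.allclose(a.values, b.values)


class TestFilterCellsGenes:
    def test_fixture_loses_exactly_the_planted_violators(self):
        matrix, expected = qc_violation_fixture()
        filtered, report = filter_cells_genes(matrix)
        removed = report["removed_cells"]
        assert len(removed) == 7
        got = dict(zip(removed["barcode"], removed["criterion"]))
        want = dict(zip(expected["barcode"], expected["criterion"]))
        assert got == want
        assert filtered.n_cells == matrix.n_cells - 7

    def test_report_counts_sum_to_cells_removed(self):
        matrix, _ = qc_violation_fixture()
        filtered, report = filter_cells_genes(matrix)
        cell_rows = report["summary"][report["summary"]["criterion"] != "genes_min_cells"]
        assert cell_rows["n_removed"].sum() == matrix.n_cells - filtered.n_cells

    def test_compliant_matrix_is_fixed_point(self):
        matrix, _ = qc_violation_fixture()
        filtered, _ = filter_cells_genes(matrix)
        again, report = filter_cells_genes(filtered)
        assert again.n_cells == filtered.n_cells
        assert again.n_genes == filtered.n_genes
        assert (report["summary"]["n_removed"] == 0).all()

    def test_stage_specific_umi_minimum(self):
        # 30 base cells at UMI 700 keep every gene above the 20-cell filter;
        # the probe cell has 450 genes and UMI 520: legal for stage 9.1
        # (minimum 500) but below stage 7's minimum of 650
        base = np.zeros((31, 450), dtype=np.int64)
        base[:30, :250] = 2
        base[:30, 250:] = 1  # UMI 700, 450 genes
        base[30, :70] = 2
        base[30, 70:450] = 1  # UMI 520, 450 genes
        for stage, kept in (("9.1", True), ("7", False)):
            m = _matrix(base, stage=stage)
            filtered, report = filter_cells_genes(m)
            probe_removed = "b30" in set(report["removed_cells"]["barcode"])
            assert probe_removed != kept
            if not kept:
                crit = report["removed_cells"].set_index("barcode").loc["b30", "criterion"]
                assert crit == "umi_low"

    def test_unknown_stage_rejected(self):
        m = _matrix([[1, 2], [3, 4]], stage="99")
        with pytest.raises(KeyError, match="99"):
            filter_cells_genes(m)

    def test_retained_cells_satisfy_all_thresholds(self):
        matrix, _ = qc_violation_fixture()
        thresholds = QCThresholds()
        filtered, _ = filter_cells_genes(matrix, thresholds)
        qc = compute_cell_qc(filtered)
        assert (qc["n_genes"] >= thresholds.min_genes_per_cell).all()
        assert (qc["n_genes"] <= thresholds.max_genes_per_cell).all()
        assert (qc["total_umi"] >= thresholds.min_umi_by_stage["7"]).all()
        assert (qc["total_umi"] <= thresholds.max_umi).all()
        assert (qc["mito_fraction"] <= thresholds.max_mito_fraction).all()


class TestDoubletScores:
    def test_reproducible_from_seed(self, processed_cache):
        _, _, info = processed_cache(1)
        barcodes, scores, _ = info[0]
        # recompute through the same path
        matrices, _ = simulate_stages(SimulationConfig(seed=1))
        f, _ = filter_cells_genes(matrices[0])
        again = doublet_scores(normalize(f).values, DoubletParams(seed=1))
        assert np.array_equal(scores, again)

    def test_planted_doublets_score_higher_than_singlets(self, processed_cache):
        _, truth, info = processed_cache(1)
        barcodes, scores, _ = info[0]
        is_doub = true_labels(truth, barcodes, "is_doublet").astype(bool)
        assert np.median(scores[is_doub]) > np.median(scores[~is_doub])

    def test_tiny_pk_gives_binary_scores(self, small_noise_config):
        cfg = small_noise_config(seed=2, n_clusters=2, cells=60)
        (m,), _ = simulate_stages(cfg)
        norm = normalize(m)
        scores = doublet_scores(norm.values, DoubletParams(pK=1e-6, seed=0))
        assert set(np.unique(scores)) <= {0.0, 1.0}

    def test_single_cluster_doublets_not_enriched(self, small_noise_config):
        # doublets whose parents share one cluster are invisible to pANN
        cfg = small_noise_config(seed=4, n_clusters=1, cells=400)
        cfg.doublet_fraction = 0.05
        (m,), truth = simulate_stages(cfg)
        norm = normalize(m)
        scores = doublet_scores(norm.values, DoubletParams(seed=4))
        _, removed = remove_doublets(scores, 0.05)
        is_doub = true_labels(truth, norm.barcodes, "is_doublet").astype(bool)
        enrichment = is_doub[removed].mean() / is_doub.mean()
        assert enrichment == pytest.approx(1.0, abs=1.0)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="10 cells"):
            doublet_scores(np.ones((5, 8)), DoubletParams())


class TestRemoveDoublets:
    def test_ceil_arithmetic(self):
        retained, removed = remove_doublets(np.linspace(0, 1, 200), 0.05)
        assert len(removed) == 10
        assert len(retained) == 190

    def test_rate_zero_removes_nothing(self):
        retained, removed = remove_doublets(np.ones(50), 0.0)
        assert len(removed) == 0 and len(retained) == 50

    def test_rate_at_least_one_rejected(self):
        with pytest.raises(ValueError):
            remove_doublets(np.ones(10), 1.0)

    def test_ties_break_by_cell_index(self):
        scores = np.array([0.5, 0.5, 0.5, 0.1])
        _, removed = remove_doublets(scores, 0.5)  # ceil(2.0) = 2
        assert removed.tolist() == [0, 1]
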