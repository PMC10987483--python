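import numpy as np
import pytest
import scipy.sparse as sp

from tmesuite.io_core import SignatureCollection, ValidationError
from tmesuite.scrna_pipeline import (
    CellClustering,
    SCCountMatrix,
    annotate_clusters,
    cluster_cells,
    find_markers,
    normalize,
    pca_embed,
    qc_filter,
    read_mtx_dir,
    select_hvg,
    write_mtx_dir,
)
from tmesuite.synthetic_data import SCSimConfig, gen_sc_cohort


def _counts(arr, genes=None, cells=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cells = cells or [f"c{i}" for i in range(arr.shape[1])]
    return SCCountMatrix(genes, cells, sp.csr_matrix(arr))


class TestQCFilter:
    def test_toy_matrix_matches_bruteforce(self):
        # 6 genes x 8 cells: 2 high-mito cells, 1 low-complexity cell, 1 rare gene
        genes = ["MT-1", "g1", "g2", "g3", "g4", "rare"]
        arr = np.array([
            #  c0  c1  c2  c3  c4  c5  c6  c7
            [1,  1,  1, 50, 60,  1,  1,  1],   # MT-1: c3,c4 high mito
            [5,  6,  7,  5,  5,  8,  0,  5],
            [4,  5,  6,  4,  4,  7,  0,  4],
            [3,  4,  5,  3,  3,  6,  0,  3],
            [2,  3,  4,  2,  2,  5,  0,  2],
            [0,  0,  9,  0,  0,  0,  0,  0],   # rare gene: 1 cell after filtering
        ])
        counts = _counts(arr, genes=genes)
        out = qc_filter(counts, min_cells=2, min_genes=3, max_mito=0.2)
        # brute force: mito fraction per cell
        mito_frac = arr[0] / arr.sum(axis=0)
        keep_cells = mito_frac <= 0.2
        keep_cells &= (arr > 0).sum(axis=0) >= 3
        sub = arr[:, keep_cells]
        keep_genes = (sub > 0).sum(axis=1) >= 2
        assert out.cell_ids == [f"c{i}" for i in np.where(keep_cells)[0]]
        assert out.gene_ids == [g for g, k in zip(genes, keep_genes) if k]
        np.testing.assert_array_equal(out.counts.toarray(), sub[keep_genes])

    def test_noop_thresholds_identity(self):
        rng = np.random.default_rng(0)
        counts = _counts(rng.integers(0, 5, size=(10, 12)))
        out = qc_filter(counts, min_cells=0, min_genes=0, max_mito=1.0)
        np.testing.assert_array_equal(out.counts.toarray(), counts.counts.toarray())

    def test_planted_lowquality_cells_removed_exactly(self, sc_cohort):
        counts, truth = sc_cohort
        out = qc_filter(counts)
        removed = set(counts.cell_ids) - set(out.cell_ids)
        assert removed == set(truth.lowquality_cells)

    def test_all_cells_removed_is_error(self):
        counts = _counts([[1, 1], [0, 1]])
        with pytest.raises(ValidationError):
            qc_filter(counts, min_genes=5)

    def test_matches_bruteforce_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            arr = rng.integers(0, 4, size=(30, 40))
            genes = [f"MT-{i}" if i < 3 else f"g{i}" for i in range(30)]
            counts = _counts(arr, genes=genes)
            try:
                out = qc_filter(counts, min_cells=3, min_genes=10, max_mito=0.15)
            except ValidationError:
                continue
            totals = arr.sum(axis=0)
            frac = np.divide(arr[:3].sum(axis=0), np.maximum(totals, 1))
            kc = (frac <= 0.15) & ((arr > 0).sum(axis=0) >= 10)
            kg = (arr[:, kc] > 0).sum(axis=1) >= 3
            np.testing.assert_array_equal(out.counts.toarray(), arr[np.ix_(kg, kc)])


class TestNormalize:
    def test_formula_values(self):
        arr = np.zeros((2, 1), dtype=int)
        arr[0, 0] = 1
        arr[1, 0] = 10**4 - 1
        counts = _counts(arr)
        norm = normalize(counts)
        assert norm.values[0, 0] == pytest.approx(np.log1p(1e4 * 1 / 1e4))
        assert norm.values.toarray()[0, 0] == pytest.approx(np.log(2))

    def test_library_scaling_invariance(self):
        arr = np.array([[2, 4], [6, 12], [2, 4]])  # second cell = 2x first
        norm = normalize(_counts(arr))
        np.testing.assert_allclose(norm.values.toarray()[:, 0],
                                   norm.values.toarray()[:, 1])

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValidationError):
            normalize(_counts([[1, 0], [1, 0]]))


class TestHVG:
    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(2)
        arr = rng.poisson(2.0, size=(50, 80)).astype(float)
        arr[7] = 3.0  # constant
        norm_vals = sp.csr_matrix(arr)
        from tmesuite.scrna_pipeline import SCExpression
        norm = SCExpression([f"g{i}" for i in range(50)],
                            [f"c{i}" for i in range(80)], norm_vals)
        hvg = select_hvg(norm, n=20)
        assert "g7" not in hvg and len(hvg) == 20

    def test_n_exceeding_total_returns_all_variable(self):
        rng = np.random.default_rng(3)
        arr = rng.poisson(2.0, size=(30, 40)).astype(float)
        from tmesuite.scrna_pipeline import SCExpression
        norm = SCExpression([f"g{i}" for i in range(30)],
                            [f"c{i}" for i in range(40)], sp.csr_matrix(arr))
        hvg = select_hvg(norm, n=100)
        assert set(hvg) == {f"g{i}" for i in range(30)
                            if arr[i].std() > 0}

    def test_planted_markers_mostly_selected(self, sc_cohort):
        counts, truth = sc_cohort
        norm = normalize(qc_filter(counts))
        hvg = set(select_hvg(norm, n=200))
        planted = [g for genes in truth.marker_genes.values() for g in genes
                   if g in set(norm.gene_ids)]
        frac = np.mean([g in hvg for g in planted])
        assert frac >= 0.9


class TestPCA:
    def _norm(self, arr):
        from tmesuite.scrna_pipeline import SCExpression
        return SCExpression([f"g{i}" for i in range(arr.shape[0])],
                            [f"c{i}" for i in range(arr.shape[1])],
                            sp.csr_matrix(arr))

    def test_component_variances_ordered(self):
        rng = np.random.default_rng(4)
        arr = rng.normal(size=(30, 50)) + 1.0
        norm = self._norm(np.abs(arr))
        emb = pca_embed(norm, norm.gene_ids, n_pcs=5)
        v = emb.var(axis=0)
        assert np.all(np.diff(v) <= 1e-10)

    def test_two_type_separation_on_pc1(self):
        rng = np.random.default_rng(5)
        a = np.abs(rng.normal(0.2, 0.1, size=(20, 30)))
        b = a.copy()
        b[:10] += 5.0
        arr = np.hstack([a, b])
        norm = self._norm(arr)
        emb = pca_embed(norm, norm.gene_ids, n_pcs=3)
        pc1 = emb[:, 0]
        assert (pc1[:30].max() < pc1[30:].min()) or (pc1[:30].min() > pc1[30:].max())

    def test_repeat_runs_bit_identical(self):
        rng = np.random.default_rng(6)
        arr = np.abs(rng.normal(size=(25, 40)))
        norm = self._norm(arr)
        e1 = pca_embed(norm, norm.gene_ids, n_pcs=4)
        e2 = pca_embed(norm, norm.gene_ids, n_pcs=4)
        np.testing.assert_array_equal(e1, e2)

    def test_npcs_too_large_rejected(self):
        rng = np.random.default_rng(7)
        norm = self._norm(np.abs(rng.normal(size=(5, 8))))
        with pytest.raises(ValidationError):
            pca_embed(norm, norm.gene_ids, n_pcs=6)


class TestClustering:
    def test_separated_types_recovered(self, sc_cohort):
        counts, truth = sc_cohort
        norm = normalize(qc_filter(counts))
        hvg = select_hvg(norm, n=500)
        emb = pca_embed(norm, hvg, n_pcs=10)
        cl = cluster_cells(emb, norm.cell_ids, seed=0)
        from sklearn.metrics import adjusted_rand_score
        t = [truth.labels[c] for c in cl.cell_ids]
        assert adjusted_rand_score(t, cl.clusters) >= 0.9

    def test_duplicated_cells_cocluster(self):
        rng = np.random.default_rng(8)
        centers = np.repeat(np.eye(3) * 10, 15, axis=0)
        emb = centers + rng.normal(0, 0.1, centers.shape)
        emb = np.vstack([emb, emb[:2]])  # exact duplicates of first two cells
        ids = [f"c{i}" for i in range(len(emb))]
        cl = cluster_cells(emb, ids, k_neighbors=5, seed=0)
        assert cl.clusters[0] == cl.clusters[45]
        assert cl.clusters[1] == cl.clusters[46]

    def test_same_seed_identical_partition(self):
        rng = np.random.default_rng(9)
        emb = rng.normal(size=(60, 5))
        ids = [f"c{i}" for i in range(60)]
        a = cluster_cells(emb, ids, k_neighbors=10, seed=3)
        b = cluster_cells(emb, ids, k_neighbors=10, seed=3)
        np.testing.assert_array_equal(a.clusters, b.clusters)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValidationError):
            cluster_cells(np.zeros((5, 2)), [f"c{i}" for i in range(5)],
                          k_neighbors=10)


class TestMarkers:
    def _dataset(self, seed=10):
        rng = np.random.default_rng(seed)
        n_per = 60
        arr = rng.poisson(1.0, size=(40, 2 * n_per)).astype(float)
        arr[5, :n_per] += 5.0   # marker of cluster 0
        arr[9, n_per:] += 5.0   # marker of cluster 1
        from tmesuite.scrna_pipeline import SCExpression
        norm = SCExpression([f"g{i}" for i in range(40)],
                            [f"c{i}" for i in range(2 * n_per)],
                            sp.csr_matrix(np.log1p(arr)))
        cl = CellClustering(norm.cell_ids,
                            np.r_[np.zeros(n_per, int), np.ones(n_per, int)])
        return norm, cl

    def test_exclusive_gene_retained_with_positive_lfc(self):
        norm, cl = self._dataset()
        mk = find_markers(norm, cl)
        row = mk[(mk.cluster == 0) & (mk.gene == "g5")]
        assert len(row) == 1
        assert row.log2_fold_change.iloc[0] > 0.25
        assert row.fdr.iloc[0] < 0.05

    def test_constant_gene_never_retained(self):
        norm, cl = self._dataset()
        dense = norm.values.toarray()
        dense[3] = 1.0
        norm.values = sp.csr_matrix(dense)
        mk = find_markers(norm, cl)
        assert "g3" not in set(mk.gene)

    def test_label_shuffle_false_positive_rate(self):
        rng = np.random.default_rng(11)
        from tmesuite.scrna_pipeline import SCExpression
        arr = np.log1p(rng.poisson(1.0, size=(500, 120)).astype(float))
        norm = SCExpression([f"g{i}" for i in range(500)],
                            [f"c{i}" for i in range(120)], sp.csr_matrix(arr))
        cl = CellClustering(norm.cell_ids, rng.integers(0, 2, 120))
        mk = find_markers(norm, cl)
        # BH at 5% across null genes: expect few retained rows
        assert len(mk) <= 0.05 * 500 * 2


class TestAnnotate:
    def test_planted_reference_recovers_types(self, sc_cohort):
        counts, truth = sc_cohort
        norm = normalize(qc_filter(counts))
        cl = CellClustering(norm.cell_ids,
                            np.array([truth.labels[c] for c in norm.cell_ids]))
        mk = find_markers(norm, cl)
        ref = SignatureCollection(
            {f"Type{t}": genes for t, genes in truth.marker_genes.items()})
        ann = annotate_clusters(mk, ref, norm.gene_ids)
        assert all(ann[t] == f"Type{t}" for t in range(4))

    def test_cluster_without_markers_unknown(self):
        import pandas as pd
        mk = pd.DataFrame({"cluster": [0], "gene": ["g1"],
                           "log2_fold_change": [-1.0], "p_value": [0.001],
                           "fdr": [0.01], "pct_in": [0.1], "pct_out": [0.9]})
        ref = SignatureCollection({"T": ["g1", "g2"]})
        ann = annotate_clusters(mk, ref, [f"g{i}" for i in range(10)])
        assert ann[0] == "unknown"  # only a negative marker

    def test_single_reference_set_labels_or_unknown(self):
        import pandas as pd
        mk = pd.DataFrame({"cluster": [0, 1], "gene": ["g1", "g5"],
                           "log2_fold_change": [1.0, 1.0],
                           "p_value": [0.001] * 2, "fdr": [0.01] * 2,
                           "pct_in": [0.9] * 2, "pct_out": [0.1] * 2})
        ref = SignatureCollection({"T": ["g1", "g2"]})
        ann = annotate_clusters(mk, ref, [f"g{i}" for i in range(10)])
        assert set(ann.values()) <= {"T", "unknown", "unlabeled"}


class TestMtxIO:
    def test_round_trip(self, tmp_path, sc_cohort):
        counts, _ = sc_cohort
        sub = SCCountMatrix(counts.gene_ids[:50], counts.cell_ids[:30],
                            counts.counts[:50, :30])
        write_mtx_dir(sub, tmp_path / "mtx")
        back = read_mtx_dir(tmp_path / "mtx")
        assert back.gene_ids == sub.gene_ids
        assert back.cell_ids == sub.cell_ids
        assert (back.counts != sub.counts).nnz == 0
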