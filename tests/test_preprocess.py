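"""QC filters, normalisation, variable genes and the hurdle DE test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_counts, make_norm
from preadapt.preprocess import (
    QcConfig,
    differential_expression,
    filter_by_housekeeping,
    filter_cells,
    filter_genes,
    find_variable_genes,
    lognormalize,
    remove_mito,
)
from preadapt.simulate import generate_gene_annotation


def _cells_with(detected_genes, umis, n_genes=1600):
    """One column per (detected, umis) spec: `detected` genes share the UMIs."""
    cols = []
    for det, total in zip(detected_genes, umis):
        col = np.zeros(n_genes, dtype=int)
        base, extra = divmod(total, det)
        col[:det] = base
        col[:extra] += 1
        cols.append(col)
    return make_counts(np.column_stack(cols))


class TestFilterCells:
    def test_too_few_detected_genes_removed(self):
        counts = _cells_with([1499, 1600], [9000, 9000])
        kept = filter_cells(counts, QcConfig())
        assert kept.cell_ids == [counts.cell_ids[1]]

    def test_thresholds_inclusive(self):
        counts = _cells_with([1500, 1500], [5000, 4999])
        kept = filter_cells(counts, QcConfig())
        assert kept.cell_ids == [counts.cell_ids[0]]

    def test_top_n_by_umi_preselects(self):
        rng = np.random.default_rng(0)
        dense = rng.poisson(3.0, size=(50, 10))
        counts = make_counts(dense)
        cfg = QcConfig(min_genes_per_cell=0, min_umis_per_cell=0, top_n_by_umi=3)
        kept = filter_cells(counts, cfg)
        totals = dense.sum(axis=0)
        expected = sorted(np.argsort(-totals, kind="stable")[:3])
        assert kept.cell_ids == [counts.cell_ids[i] for i in expected]

    def test_idempotent(self):
        counts = _cells_with([1499, 1600, 1550], [9000, 9000, 6000])
        cfg = QcConfig()
        once = filter_cells(counts, cfg)
        twice = filter_cells(once, cfg)
        assert once.cell_ids == twice.cell_ids
        assert (once.matrix != twice.matrix).nnz == 0


class TestRemoveMito:
    def test_counts_and_identity(self):
        ann = generate_gene_annotation(100, 4, seed=0)
        counts = make_counts(np.ones((100, 3), dtype=int), gene_ids=list(ann["gene_id"]))
        ann2 = ann.copy()
        ann2.loc[:2, "chromosome"] = "MT"
        assert remove_mito(counts, ann2).n_genes == 97
        assert remove_mito(counts, ann).n_genes == 100  # no mito genes

    def test_all_mito_rejected(self):
        ann = generate_gene_annotation(5, 1, seed=0)
        ann["chromosome"] = "MT"
        counts = make_counts(np.ones((5, 2), dtype=int), gene_ids=list(ann["gene_id"]))
        with pytest.raises(ValueError):
            remove_mito(counts, ann)


class TestHousekeepingFilter:
    def _counts(self, n_cells, seed=0, low_cells=()):
        rng = np.random.default_rng(seed)
        dense = rng.poisson(20.0, size=(10, n_cells)) + 1
        for c in low_cells:
            dense[:3, c] = 0  # kill the housekeeping genes in these cells
        return make_counts(dense)

    def test_exact_quantile_count_removed(self):
        counts = self._counts(200, low_cells=(5, 17))
        cfg = QcConfig(hk_genes=("g000", "g001", "g002"), hk_bottom_quantile=0.01)
        kept = filter_by_housekeeping(counts, cfg)
        assert kept.n_cells == 198  # floor(200 * 0.01) = 2
        assert counts.cell_ids[5] not in kept.cell_ids
        assert counts.cell_ids[17] not in kept.cell_ids

    def test_ties_broken_by_cell_order(self):
        dense = np.full((5, 100), 7, dtype=int)
        counts = make_counts(dense)
        cfg = QcConfig(hk_genes=("g000", "g001"), hk_bottom_quantile=0.02)
        kept = filter_by_housekeeping(counts, cfg)
        assert kept.cell_ids == counts.cell_ids[2:]  # first floor(100*.02) removed

    def test_quantile_zero_keeps_all(self):
        counts = self._counts(50)
        cfg = QcConfig(hk_genes=("g000",), hk_bottom_quantile=0.0)
        assert filter_by_housekeeping(counts, cfg).n_cells == 50

    def test_missing_hk_genes_named_in_error(self):
        counts = self._counts(10)
        cfg = QcConfig(hk_genes=("GAPDH", "RPL26"))
        with pytest.raises(ValueError, match="GAPDH"):
            filter_by_housekeeping(counts, cfg)


class TestFilterGenes:
    @pytest.mark.parametrize("n_nonzero,min_cells,kept", [(19, 20, False), (20, 20, True)])
    def test_detection_boundary(self, n_nonzero, min_cells, kept):
        dense = np.zeros((1, 30), dtype=int)
        dense[0, :n_nonzero] = 5
        counts = make_counts(dense)
        assert (filter_genes(counts, min_cells).n_genes == 1) is kept

    def test_min_cells_zero_is_identity(self):
        dense = np.zeros((4, 6), dtype=int)
        dense[0, 0] = 1
        counts = make_counts(dense)
        assert filter_genes(counts, 0).n_genes == 4


class TestLognormalize:
    def test_zero_count_maps_to_zero(self):
        counts = make_counts([[0, 3], [10, 7]])
        norm = lognormalize(counts)
        assert norm.values[0, 0] == 0.0

    def test_closed_form_single_gene_cell(self):
        counts = make_counts([[10_000], [0]])
        norm = lognormalize(counts)
        assert norm.values[0, 0] == pytest.approx(np.log2(10_000 + 1))

    def test_depth_invariance(self):
        dense = np.array([[3, 6], [7, 14], [90, 180]])
        norm = lognormalize(make_counts(dense))
        np.testing.assert_allclose(norm.values[:, 0], norm.values[:, 1], atol=1e-12)

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError):
            lognormalize(make_counts([[0, 1], [0, 2]]))


class TestVariableGenes:
    def test_high_mean_excluded_regardless_of_dispersion(self):
        rng = np.random.default_rng(0)
        vals = np.log2(rng.poisson(4.0, size=(50, 100)) + 1.0)
        vals[0] = np.log2(rng.poisson(200.0, size=100) + 1.0)  # mean metric > 6
        norm = make_norm(vals)
        assert "g000" not in find_variable_genes(norm, y_cutoff=-10)

    def test_iid_genes_select_about_half_at_zero_cutoff(self):
        rng = np.random.default_rng(1)
        vals = np.log2(rng.poisson(5.0, size=(1000, 300)) + 1.0)
        selected = find_variable_genes(make_norm(vals), y_cutoff=0.0)
        assert 0.4 <= len(selected) / 1000 <= 0.6

    def test_singleton_bin_gets_zero_score(self):
        rng = np.random.default_rng(2)
        vals = np.log2(rng.poisson(2.0, size=(30, 100)) + 1.0)
        vals[0] = np.log2(rng.poisson(40.0, size=100) + 1.0)  # alone in its bin
        selected = find_variable_genes(make_norm(vals), y_cutoff=0.01, num_bins=10)
        assert "g000" not in selected


class TestDifferentialExpression:
    def test_all_zero_gene_is_null(self):
        vals = np.zeros((2, 20))
        vals[1] = np.r_[np.zeros(10), np.ones(10)]
        labels = ["A"] * 10 + ["B"] * 10
        de = differential_expression(make_norm(vals), labels)
        row = de.set_index("gene_id").loc["g000"]
        assert row["p_value"] == 1.0
        assert row["auc"] == 0.5

    def test_perfect_separation_auc_one(self):
        vals = np.array([np.r_[np.full(8, 5.0), np.full(8, 1.0)]])
        labels = ["A"] * 8 + ["B"] * 8
        de = differential_expression(make_norm(vals), labels, focal_group="A")
        assert de["auc"].iloc[0] == 1.0
        assert de["marker"].iloc[0]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 6), min_size=4, max_size=24))
    def test_auc_equals_pairwise_comparison_oracle(self, pooled):
        """AUC matches the brute-force count of (a > b) pairs, ties half."""
        n_a = len(pooled) // 2
        a, b = pooled[:n_a], pooled[n_a:]
        vals = np.array([pooled], dtype=float)
        labels = ["A"] * n_a + ["B"] * (len(pooled) - n_a)
        de = differential_expression(make_norm(vals), labels, focal_group="A")
        oracle = np.mean([(x > y) + 0.5 * (x == y) for x in a for y in b])
        assert de["auc"].iloc[0] == pytest.approx(oracle, abs=1e-12)

    def test_bh_preserves_p_value_ordering(self, rng):
        vals = rng.poisson(3.0, size=(50, 40)).astype(float)
        labels = ["A"] * 20 + ["B"] * 20
        de = differential_expression(make_norm(vals), labels)
        order = de.sort_values("p_value")
        assert order["q_value"].is_monotonic_increasing

    def test_null_calibration(self):
        """Two groups from identical NB counts: ~5% of genes at p<0.05."""
        rng = np.random.default_rng(0)
        mu = np.exp2(rng.normal(1.5, 1.0, size=500))
        theta = 2.0
        counts = rng.negative_binomial(theta, theta / (theta + mu[:, None]), size=(500, 200))
        norm = lognormalize(make_counts(counts))
        de = differential_expression(norm, ["A"] * 100 + ["B"] * 100)
        assert (de["p_value"] < 0.05).mean() == pytest.approx(0.05, abs=0.02)

    def test_requires_two_nonempty_groups(self):
        vals = np.ones((2, 4))
        with pytest.raises(ValueError):
            differential_expression(make_norm(vals), ["A"] * 4)
        with pytest.raises(ValueError):
            differential_expression(make_norm(vals), ["A", "B", "C", "A"])
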