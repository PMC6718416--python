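"""Gene-set scoring, overlap statistics, cell cycle, k-NN imputation."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_norm
from preadapt.containers import GeneSet
from preadapt.signatures import (
    AucellConfig,
    assign_cell_cycle,
    aucell_score,
    coexpression_test,
    geneset_overlap_test,
    knn_impute_labels,
    score_signature_sum,
)


class TestSumScore:
    def test_hand_sum(self):
        norm = make_norm([[1.5], [2.5], [9.0]])
        gs = GeneSet("s", ["g000", "g001"])
        assert score_signature_sum(norm, gs).iloc[0] == pytest.approx(4.0)

    def test_single_gene_set_equals_gene_value(self, rng):
        norm = make_norm(rng.random((5, 8)))
        gs = GeneSet("s", ["g003"])
        np.testing.assert_allclose(score_signature_sum(norm, gs).to_numpy(), norm.values[3])

    def test_all_zero_signature_scores_zero(self):
        norm = make_norm(np.zeros((4, 3)))
        assert (score_signature_sum(norm, GeneSet("s", ["g000", "g001"])) == 0).all()

    def test_additive_over_disjoint_union(self, rng):
        norm = make_norm(rng.random((10, 6)))
        a = GeneSet("a", ["g000", "g001"])
        b = GeneSet("b", ["g005", "g008"])
        union = GeneSet("u", a.genes + b.genes)
        np.testing.assert_allclose(
            score_signature_sum(norm, union).to_numpy(),
            (score_signature_sum(norm, a) + score_signature_sum(norm, b)).to_numpy(),
        )


def aucell_oracle(values, in_set, max_rank):
    """Direct step-curve integration for one cell."""
    order = np.argsort(-values, kind="stable")
    hits = in_set[order][:max_rank]
    area = 0.0
    running = 0
    for h in hits:
        running += int(h)
        area += running
    m = int(in_set.sum())
    perfect = sum(min(x, m) for x in range(1, max_rank + 1))
    return area / perfect


class TestAucell:
    def test_signature_on_top_saturates_to_one(self):
        vals = np.r_[np.full(5, 9.0), np.zeros(95)][:, None]
        norm = make_norm(vals)
        gs = GeneSet("s", [f"g{i:03d}" for i in range(5)])
        out = aucell_score(norm, gs, AucellConfig(auc_max_rank_fraction=0.05))
        assert out["auc"].iloc[0] == pytest.approx(1.0)

    def test_signature_below_cap_scores_zero(self):
        vals = np.r_[np.full(95, 9.0), np.ones(5)][:, None]
        norm = make_norm(vals)
        gs = GeneSet("s", [f"g{i:03d}" for i in range(95, 100)])
        out = aucell_score(norm, gs, AucellConfig(auc_max_rank_fraction=0.05))
        assert out["auc"].iloc[0] == 0.0

    def test_matches_integration_oracle(self, rng):
        vals = rng.random((200, 30))
        norm = make_norm(vals)
        genes = np.asarray(norm.gene_ids)
        gs = GeneSet("s", list(rng.choice(genes, size=20, replace=False)))
        cfg = AucellConfig(auc_max_rank_fraction=0.1)
        out = aucell_score(norm, gs, cfg)
        in_set = np.isin(genes, gs.genes)
        max_rank = int(np.ceil(0.1 * 200))
        for c in range(30):
            assert out["auc"].iloc[c] == pytest.approx(
                aucell_oracle(vals[:, c], in_set, max_rank), abs=1e-9
            )

    def test_invariant_under_monotone_transforms(self, rng):
        vals = rng.random((150, 20)) + 0.5
        norm = make_norm(vals)
        gs = GeneSet("s", list(rng.choice(norm.gene_ids, size=15, replace=False)))
        base = aucell_score(norm, gs)["auc"]
        for transform in (np.exp2, np.cbrt, lambda x: 3 * x + 1):
            other = aucell_score(make_norm(transform(vals)), gs)["auc"]
            np.testing.assert_allclose(base.to_numpy(), other.to_numpy(), atol=1e-12)

    def test_threshold_columns(self, rng):
        norm = make_norm(rng.random((100, 10)))
        gs = GeneSet("s", list(norm.gene_ids[:10]))
        out = aucell_score(norm, gs, AucellConfig(thresholds={"strict": 0.5}))
        assert "positive_strict" in out
        assert out["positive_strict"].equals(out["auc"] >= 0.5)


class TestHypergeometric:
    def test_forced_total_overlap(self):
        gs = GeneSet("s", [f"g{i}" for i in range(10)])
        res = geneset_overlap_test(gs.genes[:4], gs, universe_size=10)
        assert res["p_value"] == pytest.approx(1.0)

    def test_zero_overlap_in_huge_universe(self):
        gs = GeneSet("s", ["a", "b", "c"])
        res = geneset_overlap_test(["x", "y"], gs, universe_size=20_000)
        assert res["overlap"] == 0
        assert res["p_value"] == pytest.approx(1.0, abs=1e-3)

    def test_small_parameters_match_enumeration_exactly(self):
        """All parameter combinations <= 50 agree with the direct pmf-sum
        oracle to 1e-12."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            universe = int(rng.integers(2, 51))
            n_set = int(rng.integers(1, universe + 1))
            n_query = int(rng.integers(1, universe + 1))
            k = int(rng.integers(0, min(n_set, n_query) + 1))
            oracle = sum(
                math.comb(n_set, i) * math.comb(universe - n_set, n_query - i)
                for i in range(k, min(n_set, n_query) + 1)
                if n_query - i <= universe - n_set
            ) / math.comb(universe, n_query)
            gs = GeneSet("s", [f"s{i}" for i in range(n_set)])
            query = [f"s{i}" for i in range(k)] + [f"q{i}" for i in range(n_query - k)]
            res = geneset_overlap_test(query, gs, universe)
            assert res["p_value"] == pytest.approx(min(oracle, 1.0), abs=1e-12)

    def test_printed_style_parameters_match_tail_sum(self):
        from scipy import stats

        gs = GeneSet("s", [f"s{i}" for i in range(300)])
        query = [f"s{i}" for i in range(30)] + [f"q{i}" for i in range(470)]
        res = geneset_overlap_test(query, gs, universe_size=20_000)
        oracle = float(np.sum(stats.hypergeom.pmf(np.arange(30, 301), 20_000, 300, 500)))
        assert res["p_value"] == pytest.approx(oracle, abs=1e-12)


class TestCoexpression:
    def test_pair_count_for_two_gene_set(self, rng):
        expr = pd.DataFrame(rng.normal(size=(20, 30)), index=[f"g{i}" for i in range(20)])
        res = coexpression_test(expr, GeneSet("s", ["g0", "g1"]), n_random_sets=5, seed=0)
        assert res["observed"].shape == (1,)

    def test_planted_factor_detected(self):
        rng = np.random.default_rng(1)
        factor = rng.normal(size=80)
        expr = rng.normal(size=(60, 80))
        expr[:10] = factor[None, :] + rng.normal(0, 0.5, size=(10, 80))
        frame = pd.DataFrame(expr, index=[f"g{i}" for i in range(60)])
        res = coexpression_test(frame, GeneSet("s", [f"g{i}" for i in range(10)]), seed=2)
        assert res["observed_median"] > res["null_median"]
        assert res["p_value"] < 0.01

    def test_null_calibration(self):
        """Independent genes: the test p-value is uniform across seeds."""
        from scipy import stats

        ps = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            expr = pd.DataFrame(rng.normal(size=(100, 50)), index=[f"g{i}" for i in range(100)])
            gs = GeneSet("s", [f"g{i}" for i in range(8)])
            ps.append(coexpression_test(expr, gs, n_random_sets=30, seed=seed + 1)["p_value"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestCellCycle:
    def test_zero_phase_expression_gives_g1(self, rng):
        vals = rng.random((50, 10))
        vals[:10] = 0.0
        norm = make_norm(vals)
        s = GeneSet("S", [f"g{i:03d}" for i in range(5)])
        g2m = GeneSet("G2M", [f"g{i:03d}" for i in range(5, 10)])
        out = assign_cell_cycle(norm, s, g2m, seed=0)
        assert (out["phase"] == "G1").all()

    def test_planted_s_phase_cells_recovered(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(1.0, 0.2, size=(200, 100)).clip(0)
        s_cells = np.arange(40)  # first 40 cells are S phase
        vals[np.ix_(np.arange(20), s_cells)] += 2.0
        norm = make_norm(vals)
        s = GeneSet("S", [f"g{i:03d}" for i in range(20)])
        g2m = GeneSet("G2M", [f"g{i:03d}" for i in range(20, 40)])
        out = assign_cell_cycle(norm, s, g2m, seed=1)
        recall = (out["phase"].to_numpy()[s_cells] == "S").mean()
        assert recall >= 0.9

    def test_deterministic_under_fixed_seed(self, rng):
        vals = rng.random((80, 30))
        norm = make_norm(vals)
        s = GeneSet("S", [f"g{i:03d}" for i in range(10)])
        g2m = GeneSet("G2M", [f"g{i:03d}" for i in range(10, 20)])
        a = assign_cell_cycle(norm, s, g2m, seed=5)
        b = assign_cell_cycle(norm, s, g2m, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestKnnImputation:
    def test_identical_point_single_neighbour(self):
        train = np.array([[0.0, 0.0], [5.0, 5.0]])
        out = knn_impute_labels(train, ["lumA", "lumB"], np.array([[5.0, 5.0]]), k=1)
        assert out["label"].iloc[0] == "lumB"
        assert out["probability"].iloc[0] == 1.0

    def test_exact_cutoff_vote_stays_unassigned(self):
        train = np.array([[0.0], [0.1], [0.2], [10.0], [10.1]])
        labels = ["a", "a", "a", "b", "b"]
        out = knn_impute_labels(train, labels, np.array([[5.0]]), k=5, prob_cutoff=0.6)
        assert out["probability"].iloc[0] == pytest.approx(0.6)
        assert out["label"].iloc[0] is None

    def test_separated_gaussians_high_accuracy(self):
        rng = np.random.default_rng(4)
        train = np.vstack([rng.normal(0, 1, (200, 5)), rng.normal(4, 1, (200, 5))])
        labels = ["a"] * 200 + ["b"] * 200
        test = np.vstack([rng.normal(0, 1, (100, 5)), rng.normal(4, 1, (100, 5))])
        out = knn_impute_labels(train, labels, test, k=5, prob_cutoff=0.0)
        truth = ["a"] * 100 + ["b"] * 100
        assert (out["label"].to_numpy() == truth).mean() >= 0.95
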