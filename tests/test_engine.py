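"""Cell tables, risk labels, balanced accuracy and the cross-validated search."""

import itertools

import numpy as np
import pytest

from oracle import brute_force_cv, brute_force_rank
from robust_gmdr import (
    DegenerateInputError,
    GenotypeMatrix,
    ScoreVector,
    SearchResult,
    ValidationError,
    balanced_accuracy,
    build_cell_table,
    classify_cells,
    classify_cells_binary,
    confusion_table,
    cross_validate,
    exhaustive_search,
    make_folds,
    select_best,
)
from robust_gmdr.engine import HIGH, LOW, CellTable, RiskModel

from conftest import random_geno


def _scores(vals, included=None):
    vals = np.asarray(vals, float)
    inc = np.ones(len(vals), bool) if included is None else np.asarray(included)
    return ScoreVector(vals, "ordinary", float("nan"), inc)


class TestCellTable:
    def test_two_snp_table_has_nine_cells(self, small_geno):
        ct = build_cell_table(small_geno, ("snp1", "snp2"), _scores([1, -0.4, 2, 3]))
        assert ct.n_cells == 9

    def test_scores_sum_within_cell(self, small_geno):
        # samples A and B both land in cell (0,0)
        ct = build_cell_table(small_geno, ("snp1", "snp2"),
                              _scores([1.0, -0.4, 2.0, 3.0]))
        assert ct.cell_score_sum[0] == pytest.approx(0.6)
        assert ct.cell_count[0] == 2

    def test_missing_genotype_excluded_from_table(self):
        g = GenotypeMatrix(["a", "b"], ["r1", "r2"],
                          np.array([[0, -1], [1, 1]], dtype=np.int8))
        ct = build_cell_table(g, ("r1", "r2"), _scores([5.0, 1.0]))
        assert ct.cell_count.sum() == 1

    def test_trimmed_sample_excluded_everywhere(self, small_geno):
        ct = build_cell_table(small_geno, ("snp1", "snp2"),
                              _scores([1.0, -0.4, 2.0, 3.0],
                                      [False, True, True, True]))
        assert ct.cell_count[0] == 1
        assert ct.cell_score_sum[0] == pytest.approx(-0.4)

    def test_ordinary_scores_sum_to_zero_over_cells(self, simple_pheno):
        from robust_gmdr import fit_null_model, score_ordinary

        rng = np.random.default_rng(14)
        g = random_geno(rng, simple_pheno.n_samples, 3)
        sv = score_ordinary(fit_null_model(simple_pheno))
        ct = build_cell_table(g, ("rs0", "rs1"), sv)
        assert ct.cell_score_sum.sum() == pytest.approx(0.0, abs=1e-9)
        assert ct.cell_count.sum() == simple_pheno.n_samples

    def test_order_cap(self, small_geno):
        with pytest.raises(ValidationError, match="lower"):
            build_cell_table(small_geno, ("snp1",), _scores([1, 1, 1, 1]),
                             max_cells=2)


class TestClassification:
    def test_positive_sum_is_high_zero_and_negative_low(self):
        ct = CellTable(("a",), np.array([3.2, 0.0, -0.001]),
                       np.array([2, 0, 1]), np.zeros(3, int), np.zeros(3, int))
        labels = classify_cells(ct).cell_label
        assert labels.tolist() == [HIGH, LOW, LOW]

    def test_binary_ratio_rule(self):
        ct = CellTable(("a",), np.zeros(3), np.array([8, 4, 4]),
                       np.array([5, 2, 0]), np.array([3, 2, 4]),
                       cell_case_count=np.array([5, 2, 0]),
                       cell_control_count=np.array([3, 2, 4]))
        labels = classify_cells_binary(ct, 1.0).cell_label
        # 5/3 > 1 -> HIGH; 2/2 does not exceed -> LOW; 0 cases -> LOW
        assert labels.tolist() == [HIGH, LOW, LOW]

    def test_binary_cases_without_controls_is_high(self):
        ct = CellTable(("a",), np.zeros(1), np.array([3]), np.array([3]),
                       np.array([0]), np.array([3]), np.array([0]))
        assert classify_cells_binary(ct).cell_label.tolist() == [HIGH]


class TestBalancedAccuracy:
    def _ct(self, pos, neg):
        pos, neg = np.asarray(pos), np.asarray(neg)
        return CellTable(("a",), np.zeros(len(pos)), pos + neg, pos, neg)

    def test_perfect_separation_gives_one(self):
        ct = self._ct([5, 0], [0, 5])
        rm = RiskModel(("a",), np.array([HIGH, LOW]))
        assert balanced_accuracy(rm, ct) == 1.0

    def test_eq_arithmetic(self):
        # sens 0.6, spec 0.4 -> BA 0.5
        ct = self._ct([3, 2], [3, 2])
        rm = RiskModel(("a",), np.array([HIGH, LOW]))
        c = confusion_table(rm, ct)
        assert (c.tp, c.fn, c.fp, c.tn) == (3, 2, 3, 2)
        assert balanced_accuracy(rm, ct) == pytest.approx(0.5)

    def test_absent_class_term_is_half(self):
        ct = self._ct([4, 1], [0, 0])  # no negative outcomes at all
        rm = RiskModel(("a",), np.array([HIGH, LOW]))
        assert balanced_accuracy(rm, ct) == pytest.approx(0.5 * (0.8 + 0.5))

    def test_no_classifiable_samples_errors(self):
        rm = RiskModel(("a",), np.array([LOW]))
        with pytest.raises(DegenerateInputError):
            balanced_accuracy(rm, self._ct([0], [0]))

    def test_label_flip_maps_ba_to_complement(self):
        rng = np.random.default_rng(3)
        pos = rng.integers(1, 10, 9)
        neg = rng.integers(1, 10, 9)
        ct = self._ct(pos, neg)
        labels = rng.integers(0, 2, 9)
        ba = balanced_accuracy(RiskModel(("a",), labels), ct)
        ba_flip = balanced_accuracy(RiskModel(("a",), 1 - labels), ct)
        assert ba + ba_flip == pytest.approx(1.0)

    def test_random_labels_average_half(self):
        """Labels assigned independently of outcomes average BA 0.5 over
        all label assignments (permutation-style oracle on a fixed table)."""
        ct = self._ct([4, 2, 7], [3, 5, 1])
        bas = [
            balanced_accuracy(RiskModel(("a",), np.array(lab)), ct)
            for lab in itertools.product([0, 1], repeat=3)
        ]
        assert np.mean(bas) == pytest.approx(0.5)


class TestCrossValidation:
    def test_fold_sizes_balanced(self):
        fid = make_folds(1000, 10, 1)
        assert np.bincount(fid).tolist() == [100] * 10

    def test_fold_sizes_differ_by_at_most_one(self):
        fid = make_folds(47, 10, 0)
        counts = np.bincount(fid)
        assert counts.max() - counts.min() <= 1

    def test_single_candidate_wins_every_fold(self):
        rng = np.random.default_rng(2)
        g = random_geno(rng, 50, 3)
        sv = _scores(rng.standard_normal(50))
        res = cross_validate(g, sv, [("rs0", "rs1")], folds=5, seed=0)
        assert res[0].cvc == 5

    def test_duplicate_columns_tie_broken_lexicographically(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 3, size=(60, 1)).astype(np.int8)
        g = GenotypeMatrix([f"s{i}" for i in range(60)], ["rsA", "rsB"],
                           np.hstack([calls, calls]))
        sv = _scores(rng.standard_normal(60))
        res = cross_validate(g, sv, [("rsA",), ("rsB",)], folds=5, seed=1)
        by_combo = {r.combo: r for r in res}
        assert by_combo[("rsA",)].cvc == 5
        assert by_combo[("rsB",)].cvc == 0

    def test_sum_of_fold_winners_equals_folds(self):
        rng = np.random.default_rng(9)
        g = random_geno(rng, 80, 5)
        sv = _scores(rng.standard_normal(80))
        combos = list(itertools.combinations(g.snp_ids, 2))
        res = cross_validate(g, sv, combos, folds=10, seed=3)
        assert sum(r.cvc for r in res) == 10
        assert all(0 <= r.mean_test_ba <= 1 and 0 <= r.mean_train_ba <= 1
                   for r in res)


class TestSearch:
    def test_all_pairs_enumerated(self):
        rng = np.random.default_rng(8)
        g = random_geno(rng, 40, 5)
        res = exhaustive_search(g, _scores(rng.standard_normal(40)), k=2,
                                folds=4, seed=0)
        assert len(res) == 10

    def test_combo_cap(self):
        rng = np.random.default_rng(8)
        g = random_geno(rng, 40, 6)
        with pytest.raises(ValidationError, match="screen"):
            exhaustive_search(g, _scores(rng.standard_normal(40)), k=2,
                              folds=4, seed=0, max_combos=5)

    def test_planted_interaction_ranked_first(self):
        rng = np.random.default_rng(12)
        n = 300
        g = random_geno(rng, n, 6)
        s1 = g.calls[:, 2].astype(float)
        s2 = g.calls[:, 4].astype(float)
        sv = _scores(2.0 * (s1 * s2 - np.mean(s1 * s2)) + 0.2 * rng.standard_normal(n))
        res = exhaustive_search(g, sv, k=2, folds=10, seed=5)
        assert set(res[0].combo) == {"rs2", "rs4"}

    def test_select_best_orderings(self):
        mk = lambda combo, cvc, ba: SearchResult(combo, cvc, 0.5, ba,
                                                 np.zeros(10, bool))
        assert select_best([mk(("a", "b"), 9, 0.5), mk(("a", "c"), 4, 0.9)]).cvc == 9
        best = select_best([mk(("a", "b"), 5, 0.61), mk(("a", "c"), 5, 0.55)])
        assert best.combo == ("a", "b")
        single = mk(("x", "y"), 3, 0.5)
        assert select_best([single]) is single
        with pytest.raises(ValidationError):
            select_best([])

    def test_column_order_invariance(self):
        rng = np.random.default_rng(21)
        g = random_geno(rng, 100, 5)
        sv = _scores(rng.standard_normal(100))
        res1 = exhaustive_search(g, sv, k=2, folds=5, seed=7)
        perm = [3, 0, 4, 1, 2]
        g2 = GenotypeMatrix(list(g.sample_ids), [g.snp_ids[j] for j in perm],
                            g.calls[:, perm])
        res2 = exhaustive_search(g2, sv, k=2, folds=5, seed=7)
        assert [(r.combo, r.cvc, r.mean_test_ba) for r in res1] == \
               [(r.combo, r.cvc, r.mean_test_ba) for r in res2]

    def test_ordinary_equals_winsorized_at_infinite_threshold(self, simple_pheno):
        from robust_gmdr import fit_null_model, score_ordinary, score_winsorized

        rng = np.random.default_rng(31)
        g = random_geno(rng, simple_pheno.n_samples, 5)
        fit = fit_null_model(simple_pheno)
        res_o = exhaustive_search(g, score_ordinary(fit), k=2, folds=5, seed=2)
        res_w = exhaustive_search(g, score_winsorized(fit, 1e12), k=2, folds=5, seed=2)
        # scores differ by a positive rescaling, so labels/BA/rankings agree
        assert [(r.combo, r.cvc) for r in res_o] == [(r.combo, r.cvc) for r in res_w]
        np.testing.assert_allclose([r.mean_test_ba for r in res_o],
                                   [r.mean_test_ba for r in res_w])


class TestOracleEquivalence:
    def test_engine_matches_brute_force_on_small_instances(self):
        """Full-pipeline equivalence with the independent loop/dict MDR."""
        rng = np.random.default_rng(99)
        for rep in range(10):
            n = int(rng.integers(30, 61))
            p = int(rng.integers(3, 7))
            g = random_geno(rng, n, p, missing_rate=0.05)
            scores = rng.standard_normal(n)
            included = rng.random(n) > 0.1
            sv = ScoreVector(np.where(included, scores, 0.0), "trimmed", 1.5,
                             included)
            combos = list(itertools.combinations(sorted(g.snp_ids), 2))
            seed = int(rng.integers(0, 2**31))
            res = cross_validate(g, sv, combos, folds=5, seed=seed)
            ref = brute_force_cv(g.calls, g.snp_ids, sv.scores, sv.included,
                                 combos, folds=5, seed=seed)
            for r in res:
                assert r.cvc == ref[r.combo]["cvc"]
                assert r.mean_train_ba == ref[r.combo]["mean_train_ba"]
                assert r.mean_test_ba == ref[r.combo]["mean_test_ba"]
            assert select_best(res).combo == brute_force_rank(ref)[0]


class TestBinaryMode:
    def test_binary_cv_runs_and_matches_case_outcomes(self):
        rng = np.random.default_rng(17)
        n = 200
        g = random_geno(rng, n, 4)
        # cases enriched in high product cells of rs0 x rs1
        prob = 0.2 + 0.6 * (g.calls[:, 0] * g.calls[:, 1] >= 2)
        case = rng.random(n) < prob
        res = exhaustive_search(g, None, k=2, folds=5, seed=4, case=case)
        assert set(res[0].combo) == {"rs0", "rs1"}
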