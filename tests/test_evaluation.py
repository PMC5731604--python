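import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import modsep as m
from modsep.exceptions import DataError

from oracle import brute_auc, brute_threshold


@pytest.fixture()
def planted():
    g0 = m.generate_graph(300, 2, seed=42)
    return m.plant_pair(g0, m.SyntheticConfig(n_nodes=300, seed=43))


class TestMakeCVSplit:
    def test_takes_what_is_available(self):
        A, B = {"1", "2", "3", "9"}, {"3", "4", "5"}
        split = m.make_cv_split(A, B, n_pos=10, n_neg=10, seed=0)
        assert split.positives == {"3"}          # only common gene
        assert len(split.negatives) == 5

    def test_seeded_determinism(self, planted):
        s1 = m.make_cv_split(planted.g_a, planted.g_b, seed=5)
        s2 = m.make_cv_split(planted.g_a, planted.g_b, seed=5)
        s3 = m.make_cv_split(planted.g_a, planted.g_b, seed=6)
        assert (s1.positives, s1.negatives) == (s2.positives, s2.negatives)
        assert (s1.positives, s1.negatives) != (s3.positives, s3.negatives)

    def test_reserved_positives_left_out_of_both_sides(self, planted):
        split = m.make_cv_split(planted.g_a, planted.g_b, seed=1)
        for p in split.positives:
            assert p not in split.working_a and p not in split.working_b
        assert split.demotion == {}

    def test_demoted_positives_on_exactly_one_side(self, planted):
        split = m.make_cv_split(planted.g_a, planted.g_b, seed=1, holdout="demote")
        for p in split.positives:
            assert (p in split.working_a) != (p in split.working_b)
            assert split.demotion[p] in ("A", "B")

    def test_sampling_respects_class_pools(self, planted):
        split = m.make_cv_split(planted.g_a, planted.g_b, seed=2)
        common = planted.g_a & planted.g_b
        assert split.positives <= common
        assert split.negatives <= (planted.g_a ^ planted.g_b)
        assert not (split.positives & split.negatives)

    def test_no_common_genes_rejected(self):
        with pytest.raises(DataError):
            m.make_cv_split({"1", "2"}, {"3", "4"}, seed=0)

    def test_all_common_rejected(self):
        with pytest.raises(DataError):
            m.make_cv_split({"1", "2"}, {"1", "2"}, seed=0)


class TestScoreTestSet:
    def test_scores_finite_and_labels_carried(self, planted):
        split = m.make_cv_split(planted.g_a, planted.g_b, seed=3)
        rows = m.score_test_set(planted.graph, split)
        assert len(rows) == len(split.positives) + len(split.negatives)
        assert all(np.isfinite(s) for _, s, _ in rows)
        assert {gene for gene, _, lab in rows if lab == 1} == set(split.positives)

    def test_ties_are_retained(self):
        # both classes may share a score; roc_auc handles the tie credit
        rows = [("a", 0.5, 1), ("b", 0.5, 0)]
        assert m.roc_auc(rows) == 0.5


class TestRocAuc:
    def test_perfect_and_pure_tie(self):
        assert m.roc_auc([(2.0, 1), (1.0, 1), (0.5, 0)]) == 1.0
        assert m.roc_auc([(1.0, 1), (1.0, 0), (1.0, 1), (1.0, 0)]) == 0.5

    def test_worked_example(self):
        assert m.roc_auc([(0.9, 1), (0.8, 0), (0.7, 1), (0.6, 0)]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            m.roc_auc([(1.0, 1), (0.5, 1)])

    def test_matches_brute_force_and_sklearn(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            pairs = list(zip(scores.tolist(), labels.tolist()))
            ours = m.roc_auc(pairs)
            assert ours == pytest.approx(brute_auc(pairs), abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_label_flip_complements(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=20).tolist()
        labels = ([1] * 8) + ([0] * 12)
        auc = m.roc_auc(list(zip(scores, labels)))
        flipped = m.roc_auc([(s, 1 - y) for s, y in zip(scores, labels)])
        assert auc + flipped == pytest.approx(1.0, abs=1e-12)


class TestThresholdAndPrecisionRecall:
    EXAMPLE = [(0.9, 1), (0.8, 1), (0.7, 0), (0.6, 1), (0.5, 0)]

    def test_youden_threshold_worked_example(self):
        assert m.choose_threshold(self.EXAMPLE) == pytest.approx(0.8)
        assert m.choose_threshold(self.EXAMPLE) == brute_threshold(self.EXAMPLE)

    def test_separated_classes_take_lowest_positive(self):
        scores = [(0.9, 1), (0.8, 1), (0.2, 0), (0.1, 0)]
        assert m.choose_threshold(scores) == pytest.approx(0.8)

    def test_all_tied_returns_common_score(self):
        assert m.choose_threshold([(0.4, 1), (0.4, 0)]) == pytest.approx(0.4)

    def test_precision_recall_at_chosen_threshold(self):
        p, r = m.precision_recall(self.EXAMPLE, 0.8)
        assert p == pytest.approx(1.0) and r == pytest.approx(2 / 3)

    def test_extreme_thresholds(self):
        p, r = m.precision_recall(self.EXAMPLE, 2.0)
        assert (p, r) == (0.0, 0.0)
        _, r_low = m.precision_recall(self.EXAMPLE, -1.0)
        assert r_low == 1.0

    def test_threshold_matches_brute_force_randomly(self):
        rng = np.random.default_rng(29)
        for _ in range(100):
            n = int(rng.integers(4, 20))
            rows = list(zip(np.round(rng.normal(size=n), 1).tolist(),
                            rng.integers(0, 2, size=n).tolist()))
            if len({y for _, y in rows}) < 2:
                continue
            assert m.choose_threshold(rows) == brute_threshold(rows)


class TestRandomizeCommonGenes:
    def test_counts_preserved_and_replacements_fresh(self, planted):
        A, B = set(planted.g_a), set(planted.g_b)
        A2, B2 = m.randomize_common_genes(planted.graph, A, B, seed=0)
        assert len(A2) == len(A) and len(B2) == len(B)
        assert len(A2 & B2) == len(A & B)
        assert not ((A2 & B2) & (A | B))

    def test_seeded_reproducibility(self, planted):
        one = m.randomize_common_genes(planted.graph, planted.g_a, planted.g_b, seed=4)
        two = m.randomize_common_genes(planted.graph, planted.g_a, planted.g_b, seed=4)
        assert one == two

    def test_no_common_genes_rejected(self, planted):
        with pytest.raises(DataError):
            m.randomize_common_genes(planted.graph, {"g000", "g001"},
                                     {"g002", "g003"}, seed=0)


class TestEvaluatePair:
    def test_record_contract(self, planted):
        rec = m.evaluate_pair(planted.graph, planted.g_a, planted.g_b,
                              seed=0, rr=1.5, pair=("da", "db"))
        assert 0.0 <= rec.roc_score <= 1.0
        assert 0.0 <= rec.precision <= 1.0 and 0.0 <= rec.recall <= 1.0
        assert rec.n_common == len(planted.shared)
        assert rec.pair == ("da", "db") and rec.rr == 1.5

    def test_bit_reproducible_given_seed(self, planted):
        a = m.evaluate_pair(planted.graph, planted.g_a, planted.g_b, seed=9)
        b = m.evaluate_pair(planted.graph, planted.g_a, planted.g_b, seed=9)
        assert (a.roc_score, a.threshold, a.precision, a.recall) == \
               (b.roc_score, b.threshold, b.precision, b.recall)

    def test_repeats_average_metrics(self, planted):
        rec = m.evaluate_pair(planted.graph, planted.g_a, planted.g_b,
                              seed=0, repeats=3)
        singles = [m.evaluate_pair(planted.graph, planted.g_a, planted.g_b,
                                   seed=s).roc_score for s in (0, 1, 2)]
        assert rec.roc_score == pytest.approx(np.mean(singles))


class TestEvaluatePairs:
    def test_skips_with_reasons(self, planted):
        assoc = {"da": set(planted.g_a), "db": set(planted.g_b),
                 "same": set(planted.g_a), "lonely": {"g000", "g001"}}
        records, skipped = m.evaluate_pairs(
            planted.graph, assoc,
            [("da", "db", 1.0), ("da", "same", 2.0), ("da", "lonely", 0.5),
             ("da", "ghost", 1.0)])
        assert len(records) == 1 and records[0].pair == ("da", "db")
        reasons = dict((p, r) for p, r in skipped)
        assert "no candidates" in reasons[("da", "same")]
        assert "no common genes" in reasons[("da", "lonely")]
        assert "ghost" in reasons[("da", "ghost")]

    def test_randomized_baseline_runs(self, planted):
        assoc = {"da": set(planted.g_a), "db": set(planted.g_b)}
        records, _ = m.evaluate_pairs(planted.graph, assoc, [("da", "db")],
                                      baseline="randomized")
        assert len(records) == 1


class TestStratifiedReport:
    def _rec(self, roc, rr, n_common):
        return m.EvaluationRecord(pair=("a", "b"), roc_score=roc, threshold=0.0,
                                  precision=roc, recall=roc, n_common=n_common,
                                  method=m.NEAREST, rr=rr)

    def test_single_record_bins_have_zero_sd(self):
        records = [self._rec(0.9, 0.5, 3), self._rec(0.7, 1.5, 7)]
        table = m.stratified_report(records)
        row = table[(table.stratum == "rr") & (table.bin == "[0, 1)")].iloc[0]
        assert row.n_pairs == 1 and row.roc_mean == 0.9 and row.roc_sd == 0.0

    def test_empty_bins_reported_as_missing(self):
        table = m.stratified_report([self._rec(0.9, 0.5, 3)])
        row = table[(table.stratum == "rr") & (table.bin == ">=3")].iloc[0]
        assert row.n_pairs == 0 and np.isnan(row.roc_mean)

    def test_overall_counts_all_records(self):
        records = [self._rec(0.8, r, c) for r, c in ((0.5, 2), (2.5, 12), (9.0, 20))]
        table = m.stratified_report(records)
        assert table[table.stratum == "overall"].iloc[0].n_pairs == 3

    def test_rr_bins_left_closed(self):
        table = m.stratified_report([self._rec(0.8, 1.0, 3)])
        assert table[(table.stratum == "rr") & (table.bin == "[1, 2)")].iloc[0].n_pairs == 1
        assert table[(table.stratum == "rr") & (table.bin == "[0, 1)")].iloc[0].n_pairs == 0

    def test_histogram_is_cumulative_fraction(self):
        records = [self._rec(x, 1.0, 3) for x in (0.2, 0.6, 1.0)]
        hist = m.roc_histogram(records)
        at = dict(zip(hist.roc_score, hist.fraction_ge))
        assert at[0.0] == 1.0 and at[0.5] == pytest.approx(2 / 3) and at[1.0] == pytest.approx(1 / 3)


class TestBenchmarkBehaviour:
    def test_null_baseline_near_chance(self, benchmark):
        assert 0.40 <= benchmark["null"].mean() <= 0.70

    def test_nearest_beats_all_pair_average(self, benchmark):
        assert benchmark["nearest"].mean() > benchmark["allpair"].mean()
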