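import itertools
import math
import random

import pytest

from pharmaboost.corpus_io import GoldStandard
from pharmaboost.errors import ValidationError
from pharmaboost.evaluation import (
    RECALL_LEVELS,
    CurationLabels,
    curation_metrics,
    f1_score,
    interpolated_pr,
    precision_at_recall,
    relative_change,
    set_metrics,
)


def brute_force_11pt(ranked, gold_pairs):
    """Oracle: precision/recall at every rank, max-precision per level."""
    denom = len([p for p in ranked if p in gold_pairs])
    if denom == 0:
        return None
    points = []
    tp = 0
    for k, p in enumerate(ranked, start=1):
        if p in gold_pairs:
            tp += 1
        points.append((tp / denom, tp / k))
    interp = []
    for level in RECALL_LEVELS:
        cands = [prec for rec, prec in points if rec >= level]
        interp.append(max(cands) if cands else 0.0)
    return interp, sum(interp) / 11


def _gold(*pairs):
    return GoldStandard(frozenset(pairs))


class TestSetMetrics:
    def test_counts_and_rates(self):
        gold = _gold(("a", "x"), ("b", "y"), ("c", "z"))
        m = set_metrics({("a", "x"), ("d", "w")}, gold)
        assert (m.tp, m.fp, m.fn) == (1, 1, 2)
        assert m.precision == 0.5
        assert m.recall == pytest.approx(1 / 3)

    def test_perfect_extraction(self):
        gold = _gold(("a", "x"), ("b", "y"))
        m = set_metrics(set(gold.pairs), gold)
        assert m.precision == m.recall == m.f1 == 1.0

    def test_empty_extraction_has_undefined_precision_zero_recall(self):
        m = set_metrics(set(), _gold(("a", "x")))
        assert math.isnan(m.precision)
        assert m.recall == 0.0

    def test_swapping_arguments_swaps_precision_and_recall(self):
        gold = _gold(("a", "x"), ("b", "y"), ("c", "z"))
        extracted = {("a", "x"), ("d", "w"), ("e", "v"), ("b", "y")}
        fwd = set_metrics(extracted, gold)
        rev = set_metrics(set(gold.pairs), GoldStandard(frozenset(extracted)))
        assert fwd.precision == rev.recall
        assert fwd.recall == rev.precision
        assert fwd.f1 == pytest.approx(rev.f1)

    @pytest.mark.parametrize(
        "p,r,f1_3dp",
        [
            (0.140, 0.138, 0.139),
            (0.111, 0.234, 0.151),
            (0.025, 0.507, 0.048),
        ],
    )
    def test_f1_harmonic_mean_identities(self, p, r, f1_3dp):
        assert round(f1_score(p, r), 3) == f1_3dp


class TestInterpolatedPR:
    def test_perfect_ranking_is_flat_one(self):
        gold = _gold(("a", "x"), ("b", "y"))
        curve = interpolated_pr([("a", "x"), ("b", "y"), ("c", "z")], gold)
        assert curve.interp_precision == tuple([1.0] * 11)
        assert curve.average_precision == 1.0

    def test_three_item_hand_example(self):
        gold = _gold(("g1", "s"), ("g2", "s"))
        ranked = [("g1", "s"), ("n", "s"), ("g2", "s")]
        curve = interpolated_pr(ranked, gold)
        # recall 0.0-0.5 -> precision 1.0; recall 0.6-1.0 -> 2/3
        assert curve.interp_precision[:6] == tuple([1.0] * 6)
        assert curve.interp_precision[6:] == tuple([pytest.approx(2 / 3)] * 5)
        assert curve.average_precision == pytest.approx((6 + 5 * 2 / 3) / 11)
        assert precision_at_recall(curve, 0.1) == 1.0
        assert precision_at_recall(curve, 0.6) == pytest.approx(2 / 3)

    def test_curve_is_non_increasing(self):
        rng = random.Random(5)
        universe = [(f"d{i}", "s") for i in range(30)]
        gold = _gold(*universe[:7])
        for _ in range(50):
            ranked = rng.sample(universe, k=len(universe))
            curve = interpolated_pr(ranked, gold)
            for hi, lo in zip(curve.interp_precision, curve.interp_precision[1:]):
                assert hi >= lo

    def test_exhaustive_oracle_agreement_on_small_rankings(self):
        items = [(f"d{i}", "s") for i in range(6)]
        for gold_size in (1, 2, 3, 5):
            gold_pairs = frozenset(items[:gold_size])
            gold = GoldStandard(gold_pairs)
            for ranked in itertools.permutations(items):
                expected = brute_force_11pt(list(ranked), gold_pairs)
                curve = interpolated_pr(list(ranked), gold)
                assert list(curve.interp_precision) == pytest.approx(expected[0])
                assert curve.average_precision == pytest.approx(expected[1])

    def test_random_ten_item_rankings_match_oracle(self):
        rng = random.Random(17)
        items = [(f"d{i}", "s") for i in range(10)]
        gold_pairs = frozenset(items[:5])
        gold = GoldStandard(gold_pairs)
        for _ in range(200):
            ranked = rng.sample(items, k=10)
            expected = brute_force_11pt(ranked, gold_pairs)
            curve = interpolated_pr(ranked, gold)
            assert list(curve.interp_precision) == pytest.approx(expected[0])
            assert curve.average_precision == pytest.approx(expected[1])

    def test_appending_non_gold_after_last_gold_never_changes_ap(self):
        gold = _gold(("a", "x"), ("b", "y"))
        ranked = [("a", "x"), ("n1", "s"), ("b", "y")]
        extended = ranked + [("n2", "s"), ("n3", "s")]
        assert interpolated_pr(ranked, gold).average_precision == pytest.approx(
            interpolated_pr(extended, gold).average_precision
        )

    def test_inserting_gold_later_can_change_max_precision(self):
        gold = _gold(("a", "x"), ("b", "y"), ("c", "z"))
        short = [("a", "x"), ("n", "s"), ("b", "y")]
        # appending a further gold pair raises recall coverage and changes AP
        longer = short + [("c", "z")]
        ap_short = interpolated_pr(short, gold).average_precision
        ap_long = interpolated_pr(longer, gold).average_precision
        assert ap_long != pytest.approx(ap_short)

    def test_disjoint_gold_yields_undefined_curve(self):
        curve = interpolated_pr([("a", "x")], _gold(("q", "q")))
        assert not curve.defined
        assert all(math.isnan(v) for v in curve.interp_precision)

    def test_full_denominator_option_caps_recall(self):
        gold = _gold(("a", "x"), ("zz", "unreachable"))
        ranked = [("a", "x"), ("n", "s")]
        reachable = interpolated_pr(ranked, gold, denominator="reachable")
        full = interpolated_pr(ranked, gold, denominator="full")
        assert reachable.average_precision == 1.0
        # recall never exceeds 0.5, so levels 0.6+ fall to zero
        assert full.interp_precision[6:] == tuple([0.0] * 5)

    def test_off_grid_level_rejected(self):
        curve = interpolated_pr([("a", "x")], _gold(("a", "x")))
        with pytest.raises(ValidationError):
            precision_at_recall(curve, 0.15)


class TestRelativeChange:
    def test_top_rank_precision_increase(self):
        rc = relative_change(0.278, 0.025)
        assert rc.percent == 1012
        assert rc.fraction == pytest.approx(10.12)

    def test_boosted_precision_fold_elevation(self):
        assert relative_change(0.371, 0.025).fold == 13.8

    def test_no_change_is_zero(self):
        rc = relative_change(0.4, 0.4)
        assert rc.fraction == 0.0 and rc.fold == 0.0 and rc.percent == 0

    def test_requires_positive_baseline(self):
        with pytest.raises(ValidationError):
            relative_change(0.5, 0.0)


class TestCurationMetrics:
    def _labels(self, n_cause, n_treat, n_none):
        labels = {}
        for i in range(n_cause):
            labels[(f"d{i}", "cv")] = "CAUSE"
        for i in range(n_treat):
            labels[(f"t{i}", "cv")] = "TREAT"
        for i in range(n_none):
            labels[(f"n{i}", "cv")] = "NONE"
        return CurationLabels(labels)

    def test_cause_fraction_and_novelty(self):
        labels = self._labels(320, 154, 143)  # 617 curated pairs
        in_gold = frozenset((f"d{i}", "cv") for i in range(320 - 258))
        report = curation_metrics(labels, GoldStandard(in_gold))
        assert round(report.precision, 3) == 0.519
        assert round(100 * report.novelty, 1) == 80.6

    def test_all_cause_fully_known_gold(self):
        labels = self._labels(10, 0, 0)
        gold = GoldStandard(frozenset(labels.labels))
        report = curation_metrics(labels, gold)
        assert report.precision == 1.0 and report.novelty == 0.0

    def test_class_fractions_partition(self):
        report = curation_metrics(self._labels(5, 3, 2), GoldStandard(frozenset()))
        assert sum(report.class_fractions.values()) == pytest.approx(1.0)
        assert report.class_fractions["TREAT"] == pytest.approx(0.3)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValidationError):
            CurationLabels({("a", "x"): "MAYBE"})

    def test_empty_labels_rejected(self):
        with pytest.raises(ValidationError):
            curation_metrics(CurationLabels({}), GoldStandard(frozenset()))
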