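"""Challenge-style scoring: partial matching, P/R/F1, hand-scored fixture."""

import pytest

from famgraph.evaluation import (
    MatchCounts,
    evaluate_subtask1,
    evaluate_subtask2,
    match_items,
    observation_text_match,
    prf,
)
from famgraph.postprocess import (
    FamilyMemberResult as FM,
    LivingStatusRelation as LSR,
    ObservationRelation as OBR,
    ObservationResult as OB,
)


class TestPrf:
    def test_closed_form(self):
        assert prf(MatchCounts(tp=1, fp=1, fn=0)) == (0.5, 1.0, pytest.approx(2 / 3))

    def test_zero_convention(self):
        assert prf(MatchCounts(0, 0, 0)) == (0.0, 0.0, 0.0)
        assert prf(MatchCounts(0, 5, 0)) == (0.0, 0.0, 0.0)

    def test_f1_is_harmonic_mean(self, rng):
        for _ in range(100):
            c = MatchCounts(*[int(x) for x in rng.integers(0, 20, 3)])
            p, r, f1 = prf(c)
            expected = 2 * p * r / (p + r) if p + r else 0.0
            assert f1 == pytest.approx(expected)


class TestPartialMatching:
    def test_diabetes_example(self):
        """Predicted 'diabetes' vs gold 'type 2 diabetes' is a TP."""
        assert observation_text_match("diabetes", "type 2 diabetes")

    def test_contiguity_required(self):
        assert not observation_text_match("type diabetes", "type 2 diabetes")
        assert observation_text_match("type 2", "type 2 diabetes")

    def test_asymmetric_by_default(self):
        assert not observation_text_match("type 2 diabetes", "diabetes")
        assert observation_text_match("type 2 diabetes", "diabetes", symmetric=True)

    def test_case_insensitive(self):
        assert observation_text_match("Meniere Disease", "meniere disease")


class TestMatching:
    def test_identical_sets(self):
        gold = [FM("d1", "Father", "NA"), FM("d1", "Aunt", "Maternal")]
        c = match_items(gold, list(gold), lambda p, g: p == g)
        assert (c.tp, c.fp, c.fn) == (2, 0, 0)

    def test_counting(self):
        gold = [FM("d", "Father", "NA"), FM("d", "Mother", "NA")]
        pred = [FM("d", "Father", "NA"), FM("d", "Uncle", "NA")]
        c = match_items(gold, pred, lambda p, g: p == g)
        assert (c.tp, c.fp, c.fn) == (1, 1, 1)

    def test_duplicates_collapsed(self):
        gold = [OB("d", "cancer", "Non_Negated")]
        pred = [OB("d", "cancer", "Non_Negated")] * 3
        c = match_items(gold, pred, lambda p, g: p == g)
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_one_to_one_greedy(self):
        # one prediction cannot consume two gold items
        gold = [OB("d", "type 2 diabetes", ""), OB("d", "diabetes", "")]
        pred = [OB("d", "diabetes", "")]
        c = match_items(gold, pred, lambda p, g: observation_text_match(p.text, g.text))
        assert (c.tp, c.fp, c.fn) == (1, 0, 1)

    def test_exact_preferred_over_partial(self):
        """The exact gold item is consumed by the exact prediction; the
        partial prediction then matches the longer gold."""
        gold = [OB("d", "diabetes", ""), OB("d", "type 2 diabetes", "")]
        pred = [OB("d", "diabetes", ""), OB("d", "2 diabetes", "")]
        c = match_items(gold, pred, lambda p, g: observation_text_match(p.text, g.text))
        assert (c.tp, c.fp, c.fn) == (2, 0, 0)

    def test_invariant_totals(self, rng):
        for _ in range(50):
            gold = [FM("d", f"G{i}", "NA") for i in range(int(rng.integers(0, 6)))]
            pred = [FM("d", f"G{i}", "NA") for i in rng.integers(0, 8, int(rng.integers(0, 6)))]
            c = match_items(gold, pred, lambda p, g: p == g)
            assert c.tp + c.fn == len(gold)
            assert c.tp + c.fp == len(set(pred))


class TestReports:
    def test_gold_vs_gold_all_ones(self):
        fm = [FM("d1", "Father", "NA"), FM("d2", "Aunt", "Maternal")]
        ob = [OB("d1", "colon cancer", "Negated")]
        r = evaluate_subtask1(fm, ob, list(fm), list(ob))
        for name, row in r.categories.items():
            if row["tp"] + row["fn"] > 0:
                assert row["f1"] == 1.0, name
        ls = [LSR("d1", "Father", "NA", 4)]
        obr = [OBR("d1", "Father", "NA", "colon cancer", "Negated")]
        r2 = evaluate_subtask2(ls, obr, list(ls), list(obr))
        assert r2["Overall"]["f1"] == 1.0

    def test_empty_predictions(self):
        r = evaluate_subtask1([FM("d", "Father", "NA")], [], [], [])
        assert r["Overall"] == {
            "tp": 0, "fp": 0, "fn": 1, "precision": 0.0, "recall": 0.0, "f1": 0.0,
        }

    def test_monotonicity(self):
        gold_fm = [FM("d", "Father", "NA"), FM("d", "Mother", "NA")]
        pred = [FM("d", "Father", "NA"), FM("d", "Uncle", "NA")]
        base = evaluate_subtask1(gold_fm, [], pred, [])
        no_fp = evaluate_subtask1(gold_fm, [], pred[:1], [])
        assert no_fp["FM: overall"]["precision"] >= base["FM: overall"]["precision"]
        more_tp = evaluate_subtask1(gold_fm, [], pred + [FM("d", "Mother", "NA")], [])
        assert more_tp["FM: overall"]["recall"] >= base["FM: overall"]["recall"]

    def test_negation_flag_in_subtask1(self):
        gold = [OB("d", "cancer", "Negated")]
        pred = [OB("d", "cancer", "Non_Negated")]
        default = evaluate_subtask1([], gold, [], pred)
        strict = evaluate_subtask1([], gold, [], pred, ignore_negation=False)
        assert default["OB"]["tp"] == 1
        assert strict["OB"]["tp"] == 0

    def test_hand_scored_five_document_fixture(self):
        """Five documents with hand-computed tp/fp/fn per category."""
        gold_fm = [
            FM("d1", "Father", "NA"),
            FM("d1", "Grandmother", "Maternal"),
            FM("d2", "Uncle", "Paternal"),
            FM("d3", "Mother", "NA"),
            FM("d4", "Cousin", "NA"),
            FM("d5", "Aunt", "Maternal"),
        ]
        pred_fm = [
            FM("d1", "Father", "NA"),            # TP (NA)
            FM("d1", "Grandmother", "Paternal"),  # FP (Paternal), FN for gold Maternal
            FM("d2", "Uncle", "Paternal"),        # TP (Paternal)
            FM("d3", "Mother", "NA"),             # TP (NA)
            FM("d5", "Sister", "NA"),             # FP (NA); gold d4 Cousin missed
        ]                                          # gold d5 Aunt Maternal missed
        gold_ob = [
            OB("d1", "type 2 diabetes", "Non_Negated"),
            OB("d2", "colon cancer", "Negated"),
            OB("d3", "asthma", "Non_Negated"),
        ]
        pred_ob = [
            OB("d1", "diabetes", "Non_Negated"),  # TP by partial match
            OB("d2", "colon cancer", "Negated"),  # TP exact
            OB("d4", "gout", "Non_Negated"),      # FP; gold d3 asthma missed
        ]
        r = evaluate_subtask1(gold_fm, gold_ob, pred_fm, pred_ob)
        # FM overall: tp=3, fp=2, fn=3 -> P=3/5, R=3/6=0.5, F1=2*.6*.5/1.1
        assert (r["FM: overall"]["tp"], r["FM: overall"]["fp"], r["FM: overall"]["fn"]) == (3, 2, 3)
        assert r["FM: overall"]["precision"] == pytest.approx(0.6)
        assert r["FM: overall"]["recall"] == pytest.approx(0.5)
        assert r["FM: overall"]["f1"] == pytest.approx(2 * 0.6 * 0.5 / 1.1)
        assert (r["FM: NA"]["tp"], r["FM: NA"]["fp"], r["FM: NA"]["fn"]) == (2, 1, 1)
        assert (r["FM: Maternal"]["tp"], r["FM: Maternal"]["fp"], r["FM: Maternal"]["fn"]) == (0, 0, 2)
        assert (r["FM: Paternal"]["tp"], r["FM: Paternal"]["fp"], r["FM: Paternal"]["fn"]) == (1, 1, 0)
        # OB: tp=2, fp=1, fn=1
        assert (r["OB"]["tp"], r["OB"]["fp"], r["OB"]["fn"]) == (2, 1, 1)
        assert r["OB"]["precision"] == pytest.approx(2 / 3)
        assert r["OB"]["recall"] == pytest.approx(2 / 3)
        # Overall: tp=5, fp=3, fn=4
        assert (r["Overall"]["tp"], r["Overall"]["fp"], r["Overall"]["fn"]) == (5, 3, 4)
        assert r["Overall"]["precision"] == pytest.approx(5 / 8)
        assert r["Overall"]["recall"] == pytest.approx(5 / 9)

    def test_subtask2_relation_identity(self):
        gold = [OBR("d", "Father", "NA", "type 2 diabetes", "Non_Negated")]
        # partial observation + matching attributes -> TP
        assert evaluate_subtask2([], gold, [],
            [OBR("d", "Father", "NA", "diabetes", "Non_Negated")])["FM-OB: overall"]["tp"] == 1
        # negation mismatch -> no match
        assert evaluate_subtask2([], gold, [],
            [OBR("d", "Father", "NA", "diabetes", "Negated")])["FM-OB: overall"]["tp"] == 0
        # side mismatch -> no match
        assert evaluate_subtask2([], gold, [],
            [OBR("d", "Father", "Maternal", "diabetes", "Non_Negated")])["FM-OB: overall"]["tp"] == 0
        # living-status score is exact
        gls = [LSR("d", "Mother", "NA", 4)]
        assert evaluate_subtask2(gls, [], [LSR("d", "Mother", "NA", 4)], [])["FM-LS: overall"]["tp"] == 1
        assert evaluate_subtask2(gls, [], [LSR("d", "Mother", "NA", 2)], [])["FM-LS: overall"]["tp"] == 0
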