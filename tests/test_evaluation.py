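"""Two-task metrics: hand-counted fixtures, brute-force oracle equivalence,
aggregation, profiling, adjudication."""

import itertools
import random

import pytest

from mobex import (
    AnnotatedSection,
    ConfusionCounts,
    ImpairmentStatus,
    LabelSet,
    PredictionRecord,
    TAGS,
    aggregate,
    apply_adjudication,
    evaluate,
    micro_average,
    prf,
    profile_corpus,
    report,
    task1_counts,
    task2_counts,
)

from conftest import STATUSES, make_section, random_gold_preds, random_labelset

I, U, N = "Impaired", "Unimpaired", "NoMention"


def fixture(gold_statuses, pred_statuses, tag="WM"):
    gold, preds = [], []
    for i, (g, p) in enumerate(zip(gold_statuses, pred_statuses)):
        sec = make_section(i)
        gold.append(AnnotatedSection(sec, LabelSet.from_pairs(**{tag: g} if g != N else {})))
        preds.append(
            PredictionRecord(sec.section_id, LabelSet.from_pairs(**{tag: p} if p != N else {}),
                             "", "strict", "t")
        )
    return gold, preds


# Independent brute-force reference: plain loops over status strings,
# sharing no code with the implementation under test.
def brute_task1(gold, preds, tag):
    pred_by_id = {p.section_id: p for p in preds}
    tp = fp = fn = tn = 0
    for g in gold:
        gm = g.gold.to_dict()[tag] in ("Impaired", "Unimpaired")
        pm = pred_by_id[g.section_id].predicted.to_dict()[tag] in ("Impaired", "Unimpaired")
        tp += gm and pm
        fp += (not gm) and pm
        fn += gm and not pm
        tn += (not gm) and (not pm)
    return (tp, fp, fn, tn)


def brute_task2(gold, preds, tag, denominator="both"):
    pred_by_id = {p.section_id: p for p in preds}
    tp = fp = fn = tn = 0
    for g in gold:
        gs = g.gold.to_dict()[tag]
        ps = pred_by_id[g.section_id].predicted.to_dict()[tag]
        if gs == "NoMention":
            continue
        if denominator == "both" and ps == "NoMention":
            continue
        gi, pi = gs == "Impaired", ps == "Impaired"
        tp += gi and pi
        fp += (not gi) and pi
        fn += gi and not pi
        tn += (not gi) and (not pi)
    return (tp, fp, fn, tn)


class TestTask1Counts:
    def test_hand_counted_three_section_fixture(self):
        gold, preds = fixture([I, I, N], [I, N, I])
        c = task1_counts(gold, preds, "WM")
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 0)

    def test_perfect_prediction_no_errors(self):
        gold, preds = fixture([I, U, N, I], [I, U, N, I])
        c = task1_counts(gold, preds, "WM")
        assert c.fp == 0 and c.fn == 0

    def test_all_silent_on_all_mentioned(self):
        gold, preds = fixture([I, U, I], [N, N, N])
        c = task1_counts(gold, preds, "WM")
        assert (c.tp, c.fn) == (0, 3)

    def test_unmatched_section_ids_rejected(self):
        gold, preds = fixture([I, N], [I, N])
        with pytest.raises(ValueError, match="missing"):
            task1_counts(gold, preds[:1], "WM")


class TestTask2Counts:
    def test_hand_counted_restricted_subset(self):
        gold, preds = fixture([I, I, U], [I, U, U])
        c = task2_counts(gold, preds, "WM")
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 1, 1)

    def test_empty_restricted_subset_reports_zero_flagged(self):
        gold, preds = fixture([N, N], [N, N])
        c = task2_counts(gold, preds, "WM")
        m = prf(c)
        assert c.total == 0
        assert (m.precision, m.recall, m.f1) == (0, 0, 0)
        assert "precision" in m.degenerate

    def test_gold_denominator_counts_detection_misses(self):
        # predicted NoMention on a gold-Impaired section: excluded under the
        # default denominator, an FN under the gold denominator
        gold, preds = fixture([I, I], [I, N])
        both = task2_counts(gold, preds, "WM", "both")
        gonly = task2_counts(gold, preds, "WM", "gold")
        assert (both.tp, both.fn) == (1, 0)
        assert (gonly.tp, gonly.fn) == (1, 1)

    def test_perfect_subset_gives_f1_one(self):
        gold, preds = fixture([I, U, I], [I, U, I])
        assert prf(task2_counts(gold, preds, "WM")).f1 == 1.0


class TestPrf:
    def test_arithmetic_fixture(self):
        m = prf(ConfusionCounts(tp=2, fp=1, fn=2, tn=0))
        assert m.precision == pytest.approx(0.6667, abs=1e-4)
        assert m.recall == pytest.approx(0.5)
        assert m.f1 == pytest.approx(0.5714, abs=1e-4)

    def test_perfect_counts(self):
        m = prf(ConfusionCounts(tp=7))
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)


class TestMicroAverage:
    def test_identical_per_class_counts_pool_to_same_metrics(self):
        c = ConfusionCounts(tp=3, fp=1, fn=2, tn=4)
        row = micro_average({t: c for t in TAGS})
        m = prf(c)
        assert row.precision == pytest.approx(m.precision)
        assert row.f1 == pytest.approx(m.f1)
        assert row.counts.total == 5 * c.total

    def test_pooled_arithmetic_fixture(self):
        per = {t: ConfusionCounts() for t in TAGS}
        per["CB"] = ConfusionCounts(tp=1, fp=0, fn=1)
        per["CO"] = ConfusionCounts(tp=1, fp=1, fn=0)
        row = micro_average(per)
        assert row.precision == pytest.approx(2 / 3)
        assert row.recall == pytest.approx(2 / 3)
        assert row.f1 == pytest.approx(2 / 3)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            micro_average({"CB": ConfusionCounts()})


class TestOracleEquivalence:
    def test_counts_match_brute_force_on_seeded_fixtures(self):
        rng = random.Random(1234)
        for _ in range(50):
            gold, preds = random_gold_preds(rng, rng.randint(5, 30))
            for tag in TAGS:
                c1 = task1_counts(gold, preds, tag)
                assert (c1.tp, c1.fp, c1.fn, c1.tn) == brute_task1(gold, preds, tag)
                for den in ("both", "gold"):
                    c2 = task2_counts(gold, preds, tag, den)
                    assert (c2.tp, c2.fp, c2.fn, c2.tn) == brute_task2(gold, preds, tag, den)

    def test_conservation_at_every_level(self):
        rng = random.Random(7)
        gold, preds = random_gold_preds(rng, 24)
        rows = evaluate(gold, preds)
        for row in rows:
            if row.task == 1 and row.cls != "micro_average":
                n_units = {"section": 24, "note": 6, "patient": 3}[row.level]
                assert row.counts.total == n_units


class TestAggregate:
    def test_impairment_dominates(self):
        ls = [LabelSet.from_pairs(WM=I), LabelSet.all_no_mention(), LabelSet.from_pairs(WM=U)]
        assert aggregate(ls)["WM"] is ImpairmentStatus.IMPAIRED

    def test_all_silent_stays_silent(self):
        assert aggregate([LabelSet.all_no_mention()] * 3) == LabelSet.all_no_mention()

    def test_unimpaired_without_impairment(self):
        ls = [LabelSet.from_pairs(CB=U), LabelSet.from_pairs(CB=U)]
        assert aggregate(ls)["CB"] is ImpairmentStatus.UNIMPAIRED

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate([])

    def test_idempotence_and_singleton_identity(self, all_243_labelsets):
        for ls in all_243_labelsets:
            assert aggregate([ls]) == ls
        rng = random.Random(77)
        for _ in range(100):
            xs = [random_labelset(rng) for _ in range(rng.randint(1, 6))]
            once = aggregate(xs)
            assert aggregate([once]) == once

    def test_pairwise_dominance_rule(self):
        order = {N: 0, U: 1, I: 2}
        for a, b in itertools.product((I, U, N), repeat=2):
            la = LabelSet.from_pairs(**({"MT": a} if a != N else {}))
            lb = LabelSet.from_pairs(**({"MT": b} if b != N else {}))
            agg = aggregate([la, lb])
            expected = max(a, b, key=order.get)
            assert agg.to_dict()["MT"] == expected


class TestProfileCorpus:
    def test_silent_corpus_mass_on_empty_combination(self):
        gold = [AnnotatedSection(make_section(i), LabelSet.all_no_mention()) for i in range(9)]
        prof = profile_corpus(gold)
        assert prof.section_combinations[frozenset()] == 9
        assert prof.section_n_classes[0] == 9

    def test_full_combination_counted(self):
        full = LabelSet({t: ImpairmentStatus.IMPAIRED for t in TAGS})
        prof = profile_corpus([AnnotatedSection(make_section(0), full)])
        assert prof.section_combinations[frozenset(TAGS)] == 1
        assert prof.section_n_classes[5] == 1

    def test_matches_brute_force_subset_counting(self):
        rng = random.Random(31)
        gold = [AnnotatedSection(make_section(i), random_labelset(rng)) for i in range(100)]
        prof = profile_corpus(gold)
        # brute force: count mention subsets with plain dict arithmetic
        expected = {}
        for g in gold:
            combo = frozenset(
                t for t, s in g.gold.to_dict().items() if s != "NoMention"
            )
            expected[combo] = expected.get(combo, 0) + 1
        for combo, n in expected.items():
            assert prof.section_combinations[combo] == n
        assert sum(prof.section_combinations.values()) == 100
        frame = prof.to_frame("section")
        assert len(frame) == 32 and frame["count"].sum() == 100


class TestAdjudication:
    def test_empty_overrides_change_nothing(self):
        gold, preds = fixture([I, N], [I, I])
        adjusted, audit = apply_adjudication(gold, preds, [])
        assert [a.gold for a in adjusted] == [g.gold for g in gold]
        assert audit == []

    def test_accepting_the_single_fp_raises_precision(self):
        gold, preds = fixture([I, N, N], [I, I, N])
        before = prf(task1_counts(gold, preds, "WM"))
        adjusted, audit = apply_adjudication(
            gold, preds, [{"section_id": "s0001", "cls": "WM", "action": "accept_as_gold"}]
        )
        after = prf(task1_counts(adjusted, preds, "WM"))
        assert after.precision > before.precision
        assert after.recall >= before.recall
        assert audit[0]["changed"] is True

    def test_noop_override_logged(self):
        gold, preds = fixture([I], [I])
        adjusted, audit = apply_adjudication(
            gold, preds, [{"section_id": "s0000", "cls": "WM"}]
        )
        assert adjusted[0].gold == gold[0].gold
        assert audit[0]["changed"] is False

    def test_unknown_section_rejected(self):
        gold, preds = fixture([I], [I])
        with pytest.raises(KeyError, match="unknown section"):
            apply_adjudication(gold, preds, [{"section_id": "nope", "cls": "WM"}])


class TestReport:
    def test_shape_and_internal_consistency(self):
        rng = random.Random(5)
        gold, preds = random_gold_preds(rng, 20)
        rows = evaluate(gold, preds, site_id="site1", levels=("section",))
        frame = report(rows)
        assert list(frame["cls"]) == list(TAGS) + ["micro_average"]
        assert "site1_task1_F1" in frame.columns and "site1_task2_F1" in frame.columns
        # micro row equals pooling the per-class counts
        per = {r.cls: r.counts for r in rows if r.task == 1 and r.cls != "micro_average"}
        micro = micro_average(per, "site1", "section", 1)
        got = float(frame.loc[frame.cls == "micro_average", "site1_task1_F1"].iloc[0])
        assert got == pytest.approx(round(micro.f1, 4))

    def test_byte_identical_across_reruns(self, tmp_path):
        rng = random.Random(6)
        gold, preds = random_gold_preds(rng, 15)
        rows = evaluate(gold, preds)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        report(rows).to_csv(a, index=False)
        report(rows).to_csv(b, index=False)
        assert a.read_bytes() == b.read_bytes()
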