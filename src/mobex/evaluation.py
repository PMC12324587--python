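"""Two-task hierarchical evaluation of mobility-status predictions.

Task 1 (Mobility Extraction): per class, a section labelled Impaired or
Unimpaired counts as Mentioned; with Mentioned as the positive class,
precision/recall/F1 are computed against gold. Task 2 (Impairment
Classification) restricts to sections where the class is confirmed
Mentioned and scores Impaired-vs-Unimpaired with Impaired positive. The
default Task 2 denominator requires BOTH gold and prediction to mark the
class Mentioned, isolating status discrimination from detection; a
``denominator="gold"`` switch instead conditions on gold only, so
detection misses count as Task 2 errors.

Metrics are computed at section, note, and patient level; upper levels
aggregate label sets with an any-mention, impairment-dominates rule. The
micro-average pools confusion counts across the five classes (and, when
requested, across sites). 0/0 ratios are reported as 0 and flagged,
never NaN.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .taxonomy import (
    TAGS,
    AnnotatedSection,
    ClinicalNote,
    ImpairmentStatus,
    LabelSet,
    Mention,
    MobilityClass,
    PredictionRecord,
    mention_status,
)

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "MetricRow",
    "task1_counts",
    "task2_counts",
    "prf",
    "micro_average",
    "aggregate",
    "evaluate",
    "profile_corpus",
    "CorpusProfile",
    "apply_adjudication",
    "report",
]

LEVELS = ("section", "note", "patient")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float
    #: names of ratios whose denominator was 0 (value reported as 0)
    degenerate: tuple[str, ...] = ()


@dataclass(frozen=True)
class MetricRow:
    cls: str  # tag or "micro_average"
    site_id: str
    level: str
    task: int
    precision: float
    recall: float
    f1: float
    counts: ConfusionCounts
    degenerate: tuple[str, ...] = ()


def _tag(cls: MobilityClass | str) -> str:
    tag = cls.tag if isinstance(cls, MobilityClass) else cls
    if tag not in TAGS:
        raise KeyError(f"unknown mobility class {tag!r}; known: {TAGS}")
    return tag


def _pair_by_section(
    gold: Sequence[AnnotatedSection], preds: Sequence[PredictionRecord]
) -> list[tuple[AnnotatedSection, PredictionRecord]]:
    pred_by_id = {p.section_id: p for p in preds}
    gold_ids = {g.section_id for g in gold}
    missing = sorted(gold_ids - set(pred_by_id))
    extra = sorted(set(pred_by_id) - gold_ids)
    if missing or extra:
        raise ValueError(
            f"predictions do not cover gold sections exactly; "
            f"missing={missing[:5]}{'...' if len(missing) > 5 else ''} "
            f"extra={extra[:5]}{'...' if len(extra) > 5 else ''}"
        )
    return [(g, pred_by_id[g.section_id]) for g in gold]


def task1_counts(
    gold: Sequence[AnnotatedSection],
    preds: Sequence[PredictionRecord],
    cls: MobilityClass | str,
) -> ConfusionCounts:
    """Mention-detection confusion counts for one class, Mentioned positive."""
    tag = _tag(cls)
    tp = fp = fn = tn = 0
    for g, p in _pair_by_section(gold, preds):
        gm = mention_status(g.gold, tag) is Mention.MENTIONED
        pm = mention_status(p.predicted, tag) is Mention.MENTIONED
        if gm and pm:
            tp += 1
        elif pm:
            fp += 1
        elif gm:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def task2_counts(
    gold: Sequence[AnnotatedSection],
    preds: Sequence[PredictionRecord],
    cls: MobilityClass | str,
    denominator: str = "both",
) -> ConfusionCounts:
    """Impairment-classification counts for one class, Impaired positive.

    ``denominator="both"`` (default) restricts to sections where gold and
    prediction both mark the class Mentioned; ``"gold"`` conditions on gold
    mentions only, treating a detection miss as a status error (predicted
    NoMention on a gold-Impaired section counts as FN, on gold-Unimpaired
    as TN-side miss counted FP-free, i.e. as a negative prediction).
    """
    if denominator not in ("both", "gold"):
        raise ValueError("denominator must be 'both' or 'gold'")
    tag = _tag(cls)
    tp = fp = fn = tn = 0
    for g, p in _pair_by_section(gold, preds):
        gs = g.gold[tag]
        ps = p.predicted[tag]
        if gs is ImpairmentStatus.NO_MENTION:
            continue
        if denominator == "both" and ps is ImpairmentStatus.NO_MENTION:
            continue
        gi = gs is ImpairmentStatus.IMPAIRED
        # under the gold denominator a missed detection counts as a
        # negative (not-Impaired) prediction
        pi = ps is ImpairmentStatus.IMPAIRED
        if gi and pi:
            tp += 1
        elif pi:
            fp += 1
        elif gi:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def prf(counts: ConfusionCounts) -> Metrics:
    """Precision, recall, F1 from counts; 0/0 reported as 0 and flagged."""
    degenerate = []
    if counts.tp + counts.fp:
        precision = counts.tp / (counts.tp + counts.fp)
    else:
        precision = 0.0
        degenerate.append("precision")
    if counts.tp + counts.fn:
        recall = counts.tp / (counts.tp + counts.fn)
    else:
        recall = 0.0
        degenerate.append("recall")
    if precision + recall:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
        degenerate.append("f1")
    return Metrics(precision, recall, f1, tuple(degenerate))


def micro_average(
    per_class: Mapping[str, ConfusionCounts],
    site_id: str = "all",
    level: str = "section",
    task: int = 1,
) -> MetricRow:
    """Pool confusion counts across the five classes, then score the pool."""
    missing = [t for t in TAGS if t not in per_class]
    if missing:
        raise ValueError(f"micro_average needs counts for all classes; missing {missing}")
    pooled = ConfusionCounts()
    for t in TAGS:
        pooled = pooled + per_class[t]
    m = prf(pooled)
    return MetricRow(
        "micro_average", site_id, level, task, m.precision, m.recall, m.f1, pooled, m.degenerate
    )


def aggregate(labelsets: Sequence[LabelSet]) -> LabelSet:
    """Roll section labels up to a note or patient: per class, Impaired if
    any constituent is Impaired, else Unimpaired if any is Unimpaired, else
    NoMention. Impairment evidence anywhere dominates."""
    if not labelsets:
        raise ValueError("cannot aggregate an empty list of label sets")
    out: dict[str, ImpairmentStatus] = {}
    for tag in TAGS:
        statuses = {ls[tag] for ls in labelsets}
        if ImpairmentStatus.IMPAIRED in statuses:
            out[tag] = ImpairmentStatus.IMPAIRED
        elif ImpairmentStatus.UNIMPAIRED in statuses:
            out[tag] = ImpairmentStatus.UNIMPAIRED
        else:
            out[tag] = ImpairmentStatus.NO_MENTION
    return LabelSet(out)


def _rollup(
    gold: Sequence[AnnotatedSection],
    preds: Sequence[PredictionRecord],
    level: str,
) -> tuple[list[AnnotatedSection], list[PredictionRecord]]:
    """Aggregate gold and predictions to note/patient pseudo-sections."""
    if level == "section":
        return list(gold), list(preds)
    keyfn = (lambda s: s.note_id) if level == "note" else (lambda s: s.patient_id)
    pred_by_id = {p.section_id: p for p in preds}
    groups: dict[str, list[AnnotatedSection]] = {}
    for g in gold:
        groups.setdefault(keyfn(g.section), []).append(g)
    agg_gold, agg_preds = [], []
    for key in sorted(groups):
        members = groups[key]
        first = members[0].section
        pseudo = replace(
            first,
            section_id=f"{level}:{key}",
            name=level,
            order=0,
            text=" ".join(m.section.text for m in members) or level,
        )
        agg_gold.append(AnnotatedSection(pseudo, aggregate([m.gold for m in members])))
        agg_labels = aggregate([pred_by_id[m.section_id].predicted for m in members])
        strategy = pred_by_id[members[0].section_id].strategy_id
        agg_preds.append(
            PredictionRecord(
                section_id=f"{level}:{key}",
                predicted=agg_labels,
                raw_response="",
                parse_status="strict",
                strategy_id=strategy,
            )
        )
    return agg_gold, agg_preds


def evaluate(
    gold: Sequence[AnnotatedSection],
    preds: Sequence[PredictionRecord],
    site_id: str = "all",
    levels: Sequence[str] = LEVELS,
    task2_denominator: str = "both",
) -> list[MetricRow]:
    """Per-class and micro-average rows for both tasks at each level."""
    for level in levels:
        if level not in LEVELS:
            raise ValueError(f"unknown level {level!r}; known: {LEVELS}")
    rows: list[MetricRow] = []
    for level in levels:
        g, p = _rollup(gold, preds, level)
        for task in (1, 2):
            per_class: dict[str, ConfusionCounts] = {}
            for tag in TAGS:
                counts = (
                    task1_counts(g, p, tag)
                    if task == 1
                    else task2_counts(g, p, tag, task2_denominator)
                )
                per_class[tag] = counts
                m = prf(counts)
                rows.append(
                    MetricRow(tag, site_id, level, task, m.precision, m.recall, m.f1,
                              counts, m.degenerate)
                )
            rows.append(micro_average(per_class, site_id, level, task))
    return rows


# ---------------------------------------------------------------------------
# Corpus profiling
# ---------------------------------------------------------------------------

@dataclass
class CorpusProfile:
    """Counts per class-combination (all 32 subsets) and the distribution
    of number-of-classes-mentioned (0–5), at section and note level."""

    section_combinations: dict[frozenset, int]
    note_combinations: dict[frozenset, int]
    section_n_classes: dict[int, int]
    note_n_classes: dict[int, int]

    def to_frame(self, level: str = "section") -> pd.DataFrame:
        combos = self.section_combinations if level == "section" else self.note_combinations
        rows = []
        for r in range(6):
            for combo in itertools.combinations(TAGS, r):
                key = frozenset(combo)
                label = "+".join(t for t in TAGS if t in key) or "(none)"
                rows.append({"combination": label, "n_classes": r, "count": combos[key]})
        return pd.DataFrame(rows)


def profile_corpus(
    annotations: Sequence[AnnotatedSection],
    notes: Sequence[ClinicalNote] | None = None,
) -> CorpusProfile:
    """Tabulate which class combinations sections (and notes) mention."""
    all_combos = {
        frozenset(c) for r in range(6) for c in itertools.combinations(TAGS, r)
    }
    sec_comb = {c: 0 for c in all_combos}
    sec_n = {i: 0 for i in range(6)}
    for ann in annotations:
        combo = frozenset(ann.gold.mentioned_tags())
        sec_comb[combo] += 1
        sec_n[len(combo)] += 1

    note_comb = {c: 0 for c in all_combos}
    note_n = {i: 0 for i in range(6)}
    by_note: dict[str, list[LabelSet]] = {}
    for ann in annotations:
        by_note.setdefault(ann.section.note_id, []).append(ann.gold)
    for note_id in sorted(by_note):
        combo = frozenset(aggregate(by_note[note_id]).mentioned_tags())
        note_comb[combo] += 1
        note_n[len(combo)] += 1
    return CorpusProfile(sec_comb, note_comb, sec_n, note_n)


# ---------------------------------------------------------------------------
# Adjudication re-scoring
# ---------------------------------------------------------------------------

def apply_adjudication(
    gold: Sequence[AnnotatedSection],
    preds: Sequence[PredictionRecord],
    overrides: Sequence[Mapping],
) -> tuple[list[AnnotatedSection], list[dict]]:
    """Accept clinically reasonable model inferences as correct.

    Each override ``{section_id, cls, action: accept_as_gold}`` replaces
    the gold label for that (section, class) with the predicted label
    before re-scoring, so a former FP/FN becomes TP/TN. Returns the
    adjusted gold and an audit log of every change (no-ops included).
    """
    gold_by_id = {g.section_id: g for g in gold}
    pred_by_id = {p.section_id: p for p in preds}
    audit: list[dict] = []
    new_labels: dict[str, dict[str, ImpairmentStatus]] = {}
    for ov in overrides:
        action = ov.get("action", "accept_as_gold")
        if action != "accept_as_gold":
            raise ValueError(f"unknown adjudication action {action!r}")
        sid, tag = ov["section_id"], _tag(ov["cls"])
        if sid not in gold_by_id:
            raise KeyError(f"override references unknown section {sid!r}")
        if sid not in pred_by_id:
            raise KeyError(f"no prediction for section {sid!r}")
        old = gold_by_id[sid].gold[tag]
        new = pred_by_id[sid].predicted[tag]
        new_labels.setdefault(sid, dict(gold_by_id[sid].gold.labels))[tag] = new
        audit.append(
            {
                "section_id": sid,
                "cls": tag,
                "old_gold": old.value,
                "new_gold": new.value,
                "changed": old is not new,
            }
        )
    adjusted = [
        AnnotatedSection(g.section, LabelSet(new_labels[g.section_id]))
        if g.section_id in new_labels
        else g
        for g in gold
    ]
    return adjusted, audit


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

_ROW_ORDER = {t: i for i, t in enumerate(TAGS)} | {"micro_average": len(TAGS)}


def report(rows: Sequence[MetricRow]) -> pd.DataFrame:
    """Wide per-class table: one row per (class, level), per-site columns
    with Task 1 P/R/F1 and Task 2 F1; micro-average last. Deterministic
    column and row order, ready for ``to_csv``."""
    recs = []
    for r in rows:
        recs.append(
            {
                "cls": r.cls,
                "site_id": r.site_id,
                "level": r.level,
                "task": r.task,
                "precision": round(r.precision, 4),
                "recall": round(r.recall, 4),
                "f1": round(r.f1, 4),
            }
        )
    long = pd.DataFrame(recs)
    t1 = long[long.task == 1].pivot_table(
        index=["level", "cls"], columns="site_id",
        values=["precision", "recall", "f1"], sort=False,
    )
    t1.columns = [f"{site}_task1_{metric[0].upper() if metric != 'f1' else 'F1'}"
                  for metric, site in t1.columns]
    t2 = long[long.task == 2].pivot_table(
        index=["level", "cls"], columns="site_id", values=["f1"], sort=False
    )
    t2.columns = [f"{site}_task2_F1" for _, site in t2.columns]
    wide = t1.join(t2).reset_index()
    wide = wide.sort_values(
        ["level", "cls"],
        key=lambda s: s.map(lambda v: _ROW_ORDER.get(v, LEVELS.index(v) if v in LEVELS else 99)),
        kind="stable",
    ).reset_index(drop=True)
    ordered_cols = ["level", "cls"] + sorted(c for c in wide.columns if c not in ("level", "cls"))
    return wide[ordered_cols]
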