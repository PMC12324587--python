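import itertools
import random

import pytest

from mobex import (
    AnnotatedSection,
    ImpairmentStatus,
    LabelSet,
    PredictionRecord,
    Section,
    TAGS,
)
from mobex.parsing import canonical_format

STATUSES = (
    ImpairmentStatus.IMPAIRED,
    ImpairmentStatus.UNIMPAIRED,
    ImpairmentStatus.NO_MENTION,
)


def make_section(i: int, text: str = "Assessment:\nstable gait\n", **ids) -> Section:
    return Section(
        section_id=ids.get("section_id", f"s{i:04d}"),
        note_id=ids.get("note_id", f"n{i // 4:04d}"),
        patient_id=ids.get("patient_id", f"p{i // 8:04d}"),
        site_id=ids.get("site_id", "site1"),
        name="Assessment",
        order=i % 4,
        text=text,
    )


def make_labels(**kw) -> LabelSet:
    return LabelSet.from_pairs(**kw)


def random_labelset(rng: random.Random) -> LabelSet:
    return LabelSet({t: rng.choice(STATUSES) for t in TAGS})


def random_gold_preds(rng: random.Random, n: int):
    """Aligned random gold annotations and predictions on n sections."""
    gold, preds = [], []
    for i in range(n):
        sec = make_section(i)
        gold.append(AnnotatedSection(sec, random_labelset(rng)))
        labels = random_labelset(rng)
        preds.append(
            PredictionRecord(
                section_id=sec.section_id,
                predicted=labels,
                raw_response=canonical_format(labels),
                parse_status="strict",
                strategy_id="test",
            )
        )
    return gold, preds


@pytest.fixture(scope="session")
def all_243_labelsets():
    return [
        LabelSet(dict(zip(TAGS, combo)))
        for combo in itertools.product(STATUSES, repeat=5)
    ]
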