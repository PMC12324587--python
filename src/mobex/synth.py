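"""Synthetic sectioned clinical-note corpora with known gold labels.

Real PT/OT and clinic notes are protected health information and cannot
be shipped; this module generates structural stand-ins. Each section
draws, per mobility class independently, a mention with probability
``mention_prob`` and, given a mention, Impaired status with probability
``impaired_given_mention``. A realised (class, status) pair is rendered
as a sentence carrying a unique marker phrase, so a lexicon-driven mock
model can recover gold exactly; distractor sentences echo the classic
confusers (treatment-plan language, vague symptoms) without any marker.

``corrupt_gold`` applies the independent noisy-oracle corruption model to
gold labels, producing prediction records for backend-free validation of
the evaluation stack against closed-form expectations.

These fixtures are synthetic: they emulate corpus *structure* (sectioned
notes, multi-label sparsity, distractors), not clinical language.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .sectionize import DEFAULT_HEADERS
from .taxonomy import (
    TAGS,
    AnnotatedSection,
    ClinicalNote,
    ImpairmentStatus,
    LabelSet,
    PredictionRecord,
    Section,
)
from .parsing import canonical_format

__all__ = [
    "MARKER_PHRASES",
    "DISTRACTORS",
    "SynthConfig",
    "generate_corpus",
    "render_note",
    "corrupt_gold",
    "notes_to_jsonl",
    "gold_to_jsonl",
    "gold_from_jsonl",
]

#: Unique, unambiguous marker phrase per (class tag, status). The lexicon
#: mock backend detects exactly these substrings (case-insensitive).
MARKER_PHRASES: dict[tuple[str, ImpairmentStatus], str] = {
    ("CB", ImpairmentStatus.IMPAIRED): "unable to rise from the chair without assistance",
    ("CB", ImpairmentStatus.UNIMPAIRED): "transfers from bed to chair independently",
    ("CO", ImpairmentStatus.IMPAIRED): "cannot lift a grocery bag with the right arm",
    ("CO", ImpairmentStatus.UNIMPAIRED): "carries household objects without difficulty",
    ("WM", ImpairmentStatus.IMPAIRED): "has difficulty walking long distances",
    ("WM", ImpairmentStatus.UNIMPAIRED): "ambulates in the hallway without difficulty",
    ("MT", ImpairmentStatus.IMPAIRED): "requires a wheelchair for community mobility",
    ("MT", ImpairmentStatus.UNIMPAIRED): "drives and uses public transit independently",
    ("MU", ImpairmentStatus.IMPAIRED): "overall mobility has declined since the last visit",
    ("MU", ImpairmentStatus.UNIMPAIRED): "reports no overall mobility limitations",
}

#: Distractor sentences: treatment plans, recommendations, and vague
#: symptoms that must NOT be labelled. None contains a marker phrase.
DISTRACTORS: tuple[str, ...] = (
    "Patient will begin home exercise program next week.",
    "Recommend continued use of ice and rest as needed.",
    "Discussed goals for upcoming therapy sessions.",
    "Reports dizziness and occasional headaches.",
    "Reports general weakness and debility.",
    "Plan: continue current medications and follow up in four weeks.",
)

_FILLER = "No new concerns reported today."


def _as_per_class(p, name: str) -> dict[str, float]:
    if isinstance(p, Mapping):
        out = {t: float(p[t]) for t in TAGS}
    else:
        out = {t: float(p) for t in TAGS}
    for t, v in out.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}[{t}] = {v} is not a probability")
    return out


@dataclass
class SynthConfig:
    """Corpus-shape parameters.

    Defaults approximate a PT/OT-style corpus: 200 notes for one site,
    ~6 sections per note, per-class mention probability 0.1 (so just over
    half of sections mention no class at all), and 70% of mentions
    impaired.
    """

    n_patients: int = 200
    notes_per_patient: int = 1
    sections_per_note: int = 6
    mention_prob: float | Mapping[str, float] = 0.1
    impaired_given_mention: float | Mapping[str, float] = 0.7
    distractor_prob: float = 0.3
    seed: int = 0
    site_id: str = "site1"
    #: std-dev of a shared per-note logit shift on mention probabilities
    #: (correlation knob; 0 keeps classes/sections independent)
    note_severity_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.notes_per_patient, self.sections_per_note) < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.distractor_prob <= 1.0:
            raise ValueError("distractor_prob must be in [0, 1]")
        self.mention_prob = _as_per_class(self.mention_prob, "mention_prob")
        self.impaired_given_mention = _as_per_class(
            self.impaired_given_mention, "impaired_given_mention"
        )


def _shifted(p: float, shift: float) -> float:
    import math

    if shift == 0.0 or p in (0.0, 1.0):
        return p
    logit = math.log(p / (1 - p)) + shift
    return 1 / (1 + math.exp(-logit))


def generate_corpus(config: SynthConfig) -> tuple[list[ClinicalNote], list[AnnotatedSection]]:
    """Generate notes and aligned gold annotations, reproducible by seed.

    Section texts include their header line (``"<Header>:\\n<body>\\n"``) so
    that concatenating a note's section texts yields exactly the raw note
    the sectionizer would re-split into the same sections.
    """
    rng = random.Random(config.seed)
    notes: list[ClinicalNote] = []
    annotations: list[AnnotatedSection] = []
    for p in range(config.n_patients):
        patient_id = f"{config.site_id}-p{p:04d}"
        for n in range(config.notes_per_patient):
            note_id = f"{patient_id}-n{n:02d}"
            shift = rng.gauss(0.0, config.note_severity_sd) if config.note_severity_sd > 0 else 0.0
            k = config.sections_per_note
            if k <= len(DEFAULT_HEADERS):
                headers = rng.sample(DEFAULT_HEADERS, k)
            else:
                headers = [rng.choice(DEFAULT_HEADERS) for _ in range(k)]
            sections = []
            for order, header in enumerate(headers):
                labels: dict[str, ImpairmentStatus] = {}
                sentences: list[str] = []
                for tag in TAGS:
                    if rng.random() < _shifted(config.mention_prob[tag], shift):
                        status = (
                            ImpairmentStatus.IMPAIRED
                            if rng.random() < config.impaired_given_mention[tag]
                            else ImpairmentStatus.UNIMPAIRED
                        )
                        labels[tag] = status
                        sentences.append(f"Patient {MARKER_PHRASES[(tag, status)]}.")
                    else:
                        labels[tag] = ImpairmentStatus.NO_MENTION
                if rng.random() < config.distractor_prob:
                    sentences.append(rng.choice(DISTRACTORS))
                if not sentences:
                    sentences.append(_FILLER)
                rng.shuffle(sentences)
                body = "\n".join(sentences)
                section = Section(
                    section_id=f"{note_id}:{order:03d}",
                    note_id=note_id,
                    patient_id=patient_id,
                    site_id=config.site_id,
                    name=header,
                    order=order,
                    text=f"{header}:\n{body}\n",
                )
                sections.append(section)
                annotations.append(AnnotatedSection(section, LabelSet(labels)))
            notes.append(
                ClinicalNote(
                    note_id=note_id,
                    patient_id=patient_id,
                    site_id=config.site_id,
                    sections=tuple(sections),
                )
            )
    return notes, annotations


def render_note(note: ClinicalNote) -> str:
    """Raw note text; section texts already carry their header lines."""
    return "".join(s.text for s in sorted(note.sections, key=lambda s: s.order))


def corrupt_gold(
    gold: Sequence[AnnotatedSection],
    sensitivity: float,
    specificity: float,
    status_flip: float,
    seed: int,
    strategy_id: str = "noisy_oracle",
) -> list[PredictionRecord]:
    """Independent per-(section, class) corruption of gold labels.

    A gold-Mentioned class survives as Mentioned with probability
    ``sensitivity`` (its status flipped with probability ``status_flip``);
    a gold-NoMention class stays silent with probability ``specificity``,
    otherwise it becomes a false mention with a random status.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("status_flip", status_flip)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} = {v} is not a probability")
    rng = random.Random(seed)
    records = []
    for ann in gold:
        labels: dict[str, ImpairmentStatus] = {}
        for tag in TAGS:
            g = ann.gold[tag]
            if g is ImpairmentStatus.NO_MENTION:
                if rng.random() < specificity:
                    labels[tag] = ImpairmentStatus.NO_MENTION
                else:
                    labels[tag] = rng.choice(
                        (ImpairmentStatus.IMPAIRED, ImpairmentStatus.UNIMPAIRED)
                    )
            else:
                if rng.random() < sensitivity:
                    if rng.random() < status_flip:
                        labels[tag] = (
                            ImpairmentStatus.UNIMPAIRED
                            if g is ImpairmentStatus.IMPAIRED
                            else ImpairmentStatus.IMPAIRED
                        )
                    else:
                        labels[tag] = g
                else:
                    labels[tag] = ImpairmentStatus.NO_MENTION
        predicted = LabelSet(labels)
        records.append(
            PredictionRecord(
                section_id=ann.section_id,
                predicted=predicted,
                raw_response=canonical_format(predicted),
                parse_status="strict",
                strategy_id=strategy_id,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def notes_to_jsonl(notes: Sequence[ClinicalNote], fh) -> None:
    for note in notes:
        fh.write(
            json.dumps(
                {
                    "note_id": note.note_id,
                    "patient_id": note.patient_id,
                    "site_id": note.site_id,
                    "text": render_note(note),
                }
            )
            + "\n"
        )


def gold_to_jsonl(annotations: Sequence[AnnotatedSection], fh) -> None:
    for ann in annotations:
        rec = ann.section.to_dict()
        rec["gold"] = ann.gold.to_dict()
        fh.write(json.dumps(rec) + "\n")


def gold_from_jsonl(fh) -> list[AnnotatedSection]:
    out = []
    for line in fh:
        if not line.strip():
            continue
        rec = json.loads(line)
        out.append(AnnotatedSection(Section.from_dict(rec), LabelSet.from_dict(rec["gold"])))
    return out
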