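"""Core data model: the five-class ICF mobility taxonomy and note containers.

The unit of analysis is a named *section* of a clinical note. Each section
carries, per mobility class, a three-valued impairment status:

* ``Impaired``   — the section describes difficulties, limitations or
  potential issues in that class;
* ``Unimpaired`` — the section explicitly describes normal function;
* ``NoMention``  — the class is not referenced at all (the default).

Mention detection collapses the first two into ``Mentioned``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ImpairmentStatus",
    "Mention",
    "MobilityClass",
    "Taxonomy",
    "DEFAULT_TAXONOMY",
    "TAGS",
    "LabelSet",
    "Section",
    "ClinicalNote",
    "AnnotatedSection",
    "PredictionRecord",
    "mention_status",
    "load_taxonomy",
]


class ImpairmentStatus(str, Enum):
    """Three-valued per-class status. ``NoMention`` serialises as ``None``
    in model-facing text but is kept distinct from null in data files."""

    IMPAIRED = "Impaired"
    UNIMPAIRED = "Unimpaired"
    NO_MENTION = "NoMention"


class Mention(str, Enum):
    MENTIONED = "Mentioned"
    NOT_MENTIONED = "NotMentioned"


@dataclass(frozen=True)
class MobilityClass:
    """One of the five consolidated ICF d4 (Mobility) chapter classes.

    ``icf_codes`` and ``definition`` are configurable metadata used only
    inside prompts, never in computation.
    """

    tag: str
    display_name: str
    icf_codes: tuple[str, ...]
    definition: str


#: Fixed tag order used everywhere a canonical class ordering is needed.
TAGS: tuple[str, ...] = ("CB", "CO", "WM", "MT", "MU")

_DEFAULT_CLASSES = (
    MobilityClass(
        tag="CB",
        display_name="Changing and maintaining body position",
        icf_codes=tuple(f"d{c}" for c in range(410, 430)),
        definition=(
            "Changing or maintaining the body's position, such as getting "
            "up from a chair, transferring, bending, or remaining standing; "
            "includes postural control and falls."
        ),
    ),
    MobilityClass(
        tag="CO",
        display_name="Carrying, moving, and handling objects",
        icf_codes=tuple(f"d{c}" for c in range(430, 450)),
        definition=(
            "Lifting, carrying, moving or manipulating objects with the "
            "hands, arms or other body parts, such as carrying groceries "
            "or handling tools."
        ),
    ),
    MobilityClass(
        tag="WM",
        display_name="Walking and moving",
        icf_codes=tuple(f"d{c}" for c in range(450, 470)),
        definition=(
            "Walking and moving around from place to place, including "
            "walking distances, climbing stairs, and moving within the "
            "home or community on foot."
        ),
    ),
    MobilityClass(
        tag="MT",
        display_name="Moving around using transportation",
        icf_codes=tuple(f"d{c}" for c in range(470, 490)),
        definition=(
            "Using transportation or assistive conveyances to move around, "
            "such as driving a car, riding public transit, or using a "
            "wheelchair for community mobility."
        ),
    ),
    MobilityClass(
        tag="MU",
        display_name="Mobility, unspecified",
        icf_codes=("d498", "d499"),
        definition=(
            "General mobility not attributable to a specific class above, "
            "such as overall activity level, everyday activities, or "
            "exercise capacity."
        ),
    ),
)


@dataclass(frozen=True)
class Taxonomy:
    """The closed set of five mobility classes.

    Exactly five members with unique tags; the default carries the
    canonical display names. Definitions and ICF codes are overridable
    metadata (e.g. to substitute verbatim ICF text in prompts).
    """

    classes: tuple[MobilityClass, ...] = _DEFAULT_CLASSES

    def __post_init__(self) -> None:
        if len(self.classes) != 5:
            raise ValueError(f"taxonomy must have exactly 5 classes, got {len(self.classes)}")
        tags = [c.tag for c in self.classes]
        if len(set(tags)) != 5:
            raise ValueError(f"class tags must be unique, got {tags}")

    @property
    def tags(self) -> tuple[str, ...]:
        return tuple(c.tag for c in self.classes)

    def __iter__(self):
        return iter(self.classes)

    def __getitem__(self, tag: str) -> MobilityClass:
        for c in self.classes:
            if c.tag == tag:
                return c
        raise KeyError(f"unknown mobility class tag {tag!r}; known: {self.tags}")

    def by_display_name(self, name: str) -> MobilityClass:
        for c in self.classes:
            if c.display_name.lower() == name.lower():
                return c
        raise KeyError(f"unknown mobility class {name!r}")


DEFAULT_TAXONOMY = Taxonomy()


def load_taxonomy(path) -> Taxonomy:
    """Load a taxonomy from YAML, merging per-tag overrides onto defaults.

    YAML shape: ``classes: [{tag, display_name, icf_codes, definition}, ...]``.
    Entries are matched to defaults by tag; missing fields keep defaults.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    entries = {e["tag"]: e for e in doc.get("classes", [])}
    merged = []
    for cls in DEFAULT_TAXONOMY:
        e = entries.pop(cls.tag, {})
        merged.append(
            MobilityClass(
                tag=cls.tag,
                display_name=e.get("display_name", cls.display_name),
                icf_codes=tuple(e.get("icf_codes", cls.icf_codes)),
                definition=e.get("definition", cls.definition),
            )
        )
    if entries:
        raise ValueError(f"unknown tags in taxonomy config: {sorted(entries)}")
    return Taxonomy(tuple(merged))


@dataclass(frozen=True)
class LabelSet:
    """A total mapping from the five class tags to an impairment status."""

    labels: Mapping[str, ImpairmentStatus]

    def __post_init__(self) -> None:
        got = frozenset(self.labels)
        if got != frozenset(TAGS):
            raise ValueError(f"LabelSet must cover exactly {TAGS}, got {sorted(got)}")
        object.__setattr__(self, "labels", dict(self.labels))

    @classmethod
    def all_no_mention(cls) -> "LabelSet":
        return cls({t: ImpairmentStatus.NO_MENTION for t in TAGS})

    @classmethod
    def from_pairs(cls, **statuses) -> "LabelSet":
        """Build from keyword tags, unlisted classes defaulting to NoMention.

        ``LabelSet.from_pairs(WM="Impaired", CB=ImpairmentStatus.UNIMPAIRED)``
        """
        labels = {t: ImpairmentStatus.NO_MENTION for t in TAGS}
        for tag, status in statuses.items():
            if tag not in labels:
                raise KeyError(f"unknown mobility class tag {tag!r}")
            labels[tag] = ImpairmentStatus(status)
        return cls(labels)

    def __getitem__(self, tag: str) -> ImpairmentStatus:
        try:
            return self.labels[tag]
        except KeyError:
            raise KeyError(f"unknown mobility class tag {tag!r}; known: {TAGS}") from None

    def mentioned_tags(self) -> tuple[str, ...]:
        return tuple(t for t in TAGS if self.labels[t] is not ImpairmentStatus.NO_MENTION)

    def to_dict(self) -> dict[str, str]:
        return {t: self.labels[t].value for t in TAGS}

    @classmethod
    def from_dict(cls, d: Mapping[str, str]) -> "LabelSet":
        return cls({t: ImpairmentStatus(d[t]) for t in TAGS})

    def __eq__(self, other) -> bool:
        return isinstance(other, LabelSet) and self.to_dict() == other.to_dict()

    def __hash__(self) -> int:
        return hash(tuple(self.labels[t] for t in TAGS))


def mention_status(labels: LabelSet, cls: "MobilityClass | str") -> Mention:
    """Collapse a three-valued status into Mentioned / NotMentioned.

    A class labelled Impaired or Unimpaired counts as Mentioned; NoMention
    maps to NotMentioned. Unknown classes raise KeyError (taxonomy mismatch).
    """
    tag = cls.tag if isinstance(cls, MobilityClass) else cls
    status = labels[tag]
    if status is ImpairmentStatus.NO_MENTION:
        return Mention.NOT_MENTIONED
    return Mention.MENTIONED


@dataclass(frozen=True)
class Section:
    """A named subdivision of a clinical note; the pipeline's unit of analysis."""

    section_id: str
    note_id: str
    patient_id: str
    site_id: str
    name: str
    order: int
    text: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError(f"section {self.section_id!r} has empty text")
        if self.order < 0:
            raise ValueError("section order must be >= 0")

    def to_dict(self) -> dict:
        return {
            "section_id": self.section_id,
            "note_id": self.note_id,
            "patient_id": self.patient_id,
            "site_id": self.site_id,
            "name": self.name,
            "order": self.order,
            "text": self.text,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Section":
        return cls(**{k: d[k] for k in ("section_id", "note_id", "patient_id", "site_id", "name", "order", "text")})


@dataclass(frozen=True)
class ClinicalNote:
    note_id: str
    patient_id: str
    site_id: str
    sections: tuple[Section, ...]

    def __post_init__(self) -> None:
        if not self.sections:
            raise ValueError(f"note {self.note_id!r} has no sections")
        orders = [s.order for s in self.sections]
        if len(set(orders)) != len(orders):
            raise ValueError(f"note {self.note_id!r} has duplicate section orders")
        for s in self.sections:
            if (s.note_id, s.patient_id, s.site_id) != (self.note_id, self.patient_id, self.site_id):
                raise ValueError(
                    f"section {s.section_id!r} identifiers do not match note {self.note_id!r}"
                )


@dataclass(frozen=True)
class AnnotatedSection:
    """A section paired with its gold-standard label set."""

    section: Section
    gold: LabelSet

    @property
    def section_id(self) -> str:
        return self.section.section_id


PARSE_STATUSES = ("strict", "fallback", "failed")


@dataclass(frozen=True)
class PredictionRecord:
    """One model prediction for one section, with parsing provenance."""

    section_id: str
    predicted: LabelSet
    raw_response: str
    parse_status: str
    strategy_id: str

    def __post_init__(self) -> None:
        if self.parse_status not in PARSE_STATUSES:
            raise ValueError(f"parse_status must be one of {PARSE_STATUSES}")
        if self.parse_status == "failed" and self.predicted != LabelSet.all_no_mention():
            raise ValueError("a failed parse must carry an all-NoMention prediction")

    def to_dict(self) -> dict:
        return {
            "section_id": self.section_id,
            "strategy_id": self.strategy_id,
            "labels": self.predicted.to_dict(),
            "parse_status": self.parse_status,
        }
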