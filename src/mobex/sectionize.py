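"""Split raw clinical-note text into ordered named sections.

Header detection is heuristic and lexicon-driven: a line whose stripped
text (minus an optional trailing colon) matches a lexicon entry
case-insensitively starts a new section. Optionally, any short Title
Case / ALL CAPS line ending in a colon is also accepted. Text before the
first header becomes a preamble section.

Each produced section's ``text`` includes its header line, so that the
concatenation of section texts reconstructs the (newline-normalised)
input exactly — a property the tests rely on.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from .taxonomy import ClinicalNote, Section

__all__ = [
    "HeaderLexicon",
    "DEFAULT_LEXICON",
    "split_note",
    "notes_from_jsonl",
    "sections_to_jsonl",
    "sections_from_jsonl",
]

#: Section names seen in PT/OT and general clinic notes.
DEFAULT_HEADERS: tuple[str, ...] = (
    "History of Present Illness",
    "Past Medical/Surgical History",
    "Physical Examination",
    "Diagnosis",
    "Assessment",
    "Plan",
    "Subjective",
    "Objective",
    "Medications",
    "Social History",
    "Family History",
    "Review of Systems",
    "Chief Complaint",
    "Prior Level of Function",
    "Current Level of Function",
    "Functional Status",
    "Gait Assessment",
    "Therapy Progress",
    "Goals",
    "Interventions",
)


@dataclass(frozen=True)
class HeaderLexicon:
    headers: tuple[str, ...] = DEFAULT_HEADERS
    allow_unlisted_titlecase: bool = False
    preamble_name: str = "PREAMBLE"

    def __post_init__(self) -> None:
        if not self.headers:
            raise ValueError("header lexicon must not be empty")
        lowered = [h.lower() for h in self.headers]
        if len(set(lowered)) != len(lowered):
            raise ValueError("header names must be case-insensitively unique")

    def match(self, line: str) -> str | None:
        """Return the canonical header name if `line` is a header line."""
        stripped = line.strip()
        core = stripped[:-1].strip() if stripped.endswith(":") else stripped
        if not core:
            return None
        for h in self.headers:
            if core.lower() == h.lower():
                return h
        if self.allow_unlisted_titlecase and stripped.endswith(":"):
            words = core.split()
            if 0 < len(words) <= 8 and all(w[:1].isupper() or w.isupper() for w in words):
                return core
        return None


DEFAULT_LEXICON = HeaderLexicon()


def split_note(
    raw: str,
    lexicon: HeaderLexicon = DEFAULT_LEXICON,
    *,
    note_id: str,
    patient_id: str,
    site_id: str,
) -> ClinicalNote:
    """Partition a raw note into an ordered list of named sections.

    Line endings are normalised to ``\\n`` first. A note with no detected
    headers yields a single section named ``lexicon.preamble_name``, as
    does any free text before the first header.
    """
    if not raw or not raw.strip():
        raise ValueError("cannot sectionize empty or whitespace-only note text")
    text = raw.replace("\r\n", "\n").replace("\r", "\n")

    # (start_char, name) for every header line, in document order
    boundaries: list[tuple[int, str]] = []
    pos = 0
    for line in text.split("\n"):
        name = lexicon.match(line)
        if name is not None:
            boundaries.append((pos, name))
        pos += len(line) + 1  # +1 for the split newline

    spans: list[tuple[str, str]] = []  # (name, text incl. header line)
    if not boundaries or boundaries[0][0] > 0:
        end = boundaries[0][0] if boundaries else len(text)
        spans.append((lexicon.preamble_name, text[:end]))
    for i, (start, name) in enumerate(boundaries):
        end = boundaries[i + 1][0] if i + 1 < len(boundaries) else len(text)
        spans.append((name, text[start:end]))

    sections = tuple(
        Section(
            section_id=f"{note_id}:{order:03d}",
            note_id=note_id,
            patient_id=patient_id,
            site_id=site_id,
            name=name,
            order=order,
            text=span,
        )
        for order, (name, span) in enumerate(spans)
        if span.strip()
    )
    return ClinicalNote(note_id=note_id, patient_id=patient_id, site_id=site_id, sections=sections)


# ---------------------------------------------------------------------------
# File I/O: JSONL notes in, JSONL sections out
# ---------------------------------------------------------------------------

def notes_from_jsonl(fh: TextIO, lexicon: HeaderLexicon = DEFAULT_LEXICON) -> list[ClinicalNote]:
    """Read note records ``{note_id, patient_id, site_id, text}`` and split each."""
    notes = []
    for line in fh:
        if not line.strip():
            continue
        rec = json.loads(line)
        notes.append(
            split_note(
                rec["text"],
                lexicon,
                note_id=rec["note_id"],
                patient_id=rec["patient_id"],
                site_id=rec["site_id"],
            )
        )
    return notes


def sections_to_jsonl(sections: Iterable[Section], fh: TextIO) -> None:
    for s in sections:
        fh.write(json.dumps(s.to_dict()) + "\n")


def sections_from_jsonl(fh: TextIO) -> list[Section]:
    return [Section.from_dict(json.loads(line)) for line in fh if line.strip()]
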