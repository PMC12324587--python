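"""Convert generative model output into a structured :class:`LabelSet`.

The canonical grammar is line-oriented key–value, one line per class::

    Changing and maintaining body position: Impaired
    Carrying, moving, and handling objects: None
    ...

A strict pass requires every non-blank line to follow that grammar with
each class appearing exactly once. If the strict pass fails, a fallback
regex pass searches each line for a class name (or tag) followed by a
status token; classes never matched default to NoMention. ``parse`` is
total — it never raises on arbitrary text — and failures are encoded in
``parse_status``.

Status tokens accepted (case-insensitive): ``Impaired``, ``Unimpaired``,
``None``/``NoMention``/``Not mentioned``, and ``Mentioned``. The last is a
mention placeholder used by the extraction pass of the two-model task
decomposition: it preserves mentioned-ness (parsed as Impaired) while the
dedicated classification pass resolves the actual status. This keeps one
parser grammar covering every prompting strategy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .taxonomy import DEFAULT_TAXONOMY, ImpairmentStatus, LabelSet, Taxonomy, TAGS

__all__ = ["ParseResult", "parse", "canonical_format"]

_STATUS_TOKENS: dict[str, ImpairmentStatus | None] = {
    "unimpaired": ImpairmentStatus.UNIMPAIRED,
    "impaired": ImpairmentStatus.IMPAIRED,
    "mentioned": ImpairmentStatus.IMPAIRED,  # mention placeholder, see module docstring
    "none": ImpairmentStatus.NO_MENTION,
    "nomention": ImpairmentStatus.NO_MENTION,
    "no mention": ImpairmentStatus.NO_MENTION,
    "not mentioned": ImpairmentStatus.NO_MENTION,
    "notmentioned": ImpairmentStatus.NO_MENTION,
}
# longest-first so "unimpaired" / "not mentioned" win over their substrings
_TOKEN_ALT = "|".join(sorted((re.escape(t) for t in _STATUS_TOKENS), key=len, reverse=True))


@dataclass(frozen=True)
class ParseResult:
    """Parsed labels plus provenance; iterates as ``(labels, status)``."""

    labels: LabelSet
    status: str  # strict | fallback | failed
    conflict_tags: tuple[str, ...] = ()

    def __iter__(self):
        return iter((self.labels, self.status))


def _name_patterns(taxonomy: Taxonomy) -> list[tuple[str, re.Pattern, re.Pattern]]:
    pats = []
    for cls in taxonomy:
        name = re.escape(cls.display_name)
        strict = re.compile(
            rf"^\s*(?:{name}|{re.escape(cls.tag)})\s*:\s*({_TOKEN_ALT})\s*\.?\s*$",
            re.IGNORECASE,
        )
        # fallback: class name (case-insensitive) or bare tag (exact case, to
        # avoid matching ordinary words) followed by a status token on the line
        loose = re.compile(
            rf"(?:(?i:{name})|\b{re.escape(cls.tag)}\b)[^\n]*?\b(?i:({_TOKEN_ALT}))\b"
        )
        pats.append((cls.tag, strict, loose))
    return pats


def parse(raw: str, taxonomy: Taxonomy = DEFAULT_TAXONOMY) -> ParseResult:
    """Parse model output text into a LabelSet; total over arbitrary text."""
    if raw is None:
        raw = ""
    pats = _name_patterns(taxonomy)
    lines = [ln for ln in raw.replace("\r\n", "\n").split("\n") if ln.strip()]

    # --- strict pass -------------------------------------------------------
    strict_hits: dict[str, ImpairmentStatus] = {}
    strict_ok = bool(lines)
    for ln in lines:
        matched = False
        for tag, strict_pat, _ in pats:
            m = strict_pat.match(ln)
            if m:
                if tag in strict_hits:
                    strict_ok = False
                strict_hits[tag] = _STATUS_TOKENS[m.group(1).lower()]
                matched = True
                break
        if not matched:
            strict_ok = False
    if strict_ok and len(strict_hits) == 5:
        return ParseResult(LabelSet(strict_hits), "strict")

    # --- fallback pass -----------------------------------------------------
    labels = {t: ImpairmentStatus.NO_MENTION for t in TAGS}
    matched_any = False
    conflicts = []
    for tag, _, loose_pat in pats:
        seen: list[ImpairmentStatus] = []
        for ln in lines:
            for m in loose_pat.finditer(ln):
                seen.append(_STATUS_TOKENS[m.group(1).lower()])
        if seen:
            matched_any = True
            labels[tag] = seen[-1]  # recency heuristic: last occurrence wins
            if len(set(seen)) > 1:
                conflicts.append(tag)
    if not matched_any:
        return ParseResult(LabelSet.all_no_mention(), "failed")
    return ParseResult(LabelSet(labels), "fallback", tuple(conflicts))


def canonical_format(labels: LabelSet, taxonomy: Taxonomy = DEFAULT_TAXONOMY) -> str:
    """Emit the strict grammar: one ``<display_name>: <status>`` line per
    class in taxonomy order, with NoMention rendered as ``None``."""
    out = []
    for cls in taxonomy:
        status = labels[cls.tag]
        token = "None" if status is ImpairmentStatus.NO_MENTION else status.value
        out.append(f"{cls.display_name}: {token}")
    return "\n".join(out)
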