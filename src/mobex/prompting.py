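"""Prompt construction for every evaluated strategy.

Strategies: zero-shot; five-shot with random / k-means-error-cluster /
nearest-neighbour exemplar selection (the builder is selection-agnostic —
it takes the already-chosen exemplars); error-informed refinement
(inclusion/exclusion rules injected as numbered instructions); and two
task-decomposition modes (single chain-of-thought prompt, or an
extract + classify prompt pair for two specialised models).

Templates are plain-text files with ``$name`` placeholders shipped under
``mobex/templates/`` and fully user-replaceable; every strategy embeds
the identical output-format instruction so a single parser grammar covers
all of them. Rendering is pure: same inputs, identical prompt text.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from string import Template

import yaml

from .taxonomy import (
    DEFAULT_TAXONOMY,
    AnnotatedSection,
    ImpairmentStatus,
    LabelSet,
    MobilityClass,
    Section,
    Taxonomy,
)
from .parsing import canonical_format

__all__ = [
    "STRATEGY_IDS",
    "PromptTemplate",
    "Rule",
    "RuleSet",
    "DEFAULT_RULES",
    "load_rules",
    "build_zero_shot",
    "build_few_shot",
    "build_error_informed",
    "build_decomposed_single",
    "build_decomposed_extract",
    "build_decomposed_classify",
    "build_decomposed_pair",
]

STRATEGY_IDS = (
    "zero_shot",
    "few_shot_random",
    "few_shot_kmeans",
    "few_shot_knn",
    "error_informed",
    "decomposed_single",
    "decomposed_extract",
    "decomposed_classify",
)

TASK_DESCRIPTION = (
    "You are annotating a section of a clinical note for mobility "
    "functional status. For each of the five mobility classes defined "
    "below, decide whether the section indicates the patient is Impaired "
    "(difficulties, challenges, limitations, potential issues), Unimpaired "
    "(explicitly normal function or ability), or contains no information "
    "about that class (None)."
)

GENERAL_INSTRUCTION = (
    "Base your decision only on what the section states about the "
    "patient's own function. A single section may mention several "
    "mobility classes, one, or none at all."
)

OUTPUT_FORMAT = (
    "Answer with exactly five lines, one per mobility class, each of the "
    "form '<class name>: <status>' where <status> is Impaired, Unimpaired, "
    "or None."
)

FINAL_QUESTION = (
    "For each of the five mobility classes, what is the patient's "
    "impairment status in this section?"
)


def _load_template(name: str) -> str:
    return resources.files("mobex.templates").joinpath(f"{name}.txt").read_text()


@dataclass(frozen=True)
class PromptTemplate:
    """A strategy's template text with ``$name`` placeholders."""

    strategy_id: str
    template_text: str

    @classmethod
    def builtin(cls, strategy_id: str) -> "PromptTemplate":
        if strategy_id not in STRATEGY_IDS:
            raise ValueError(f"unknown strategy {strategy_id!r}; known: {STRATEGY_IDS}")
        name = strategy_id
        if strategy_id in ("few_shot_random", "few_shot_kmeans", "few_shot_knn"):
            name = "few_shot"
        return cls(strategy_id, _load_template(name))

    def render(self, **fields: str) -> str:
        # placeholder contract: the query section slot appears exactly once
        # (identical text may legitimately recur inside exemplar blocks)
        n_slots = self.template_text.count("$section_text") + self.template_text.count(
            "${section_text}"
        )
        if "section_text" in fields and n_slots != 1:
            raise ValueError(
                f"template {self.strategy_id!r} must embed the section text exactly once, "
                f"found {n_slots} slots"
            )
        text = Template(self.template_text).substitute(fields)
        if not text.strip():
            raise ValueError("rendered prompt is empty")
        return text


@dataclass(frozen=True)
class Rule:
    rule_id: str
    kind: str  # inclusion | exclusion
    text: str

    def __post_init__(self) -> None:
        if self.kind not in ("inclusion", "exclusion"):
            raise ValueError(f"rule kind must be inclusion or exclusion, got {self.kind!r}")
        if not self.text.strip():
            raise ValueError(f"rule {self.rule_id!r} has empty text")


@dataclass(frozen=True)
class RuleSet:
    """Ordered inclusion/exclusion instructions for error-informed prompts."""

    rules: tuple[Rule, ...]

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("RuleSet must contain at least one rule")
        ids = [r.rule_id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ValueError(f"rule_ids must be unique, got {ids}")

    def ordered(self) -> tuple[Rule, ...]:
        """Exclusions first, then inclusions, stable within kind."""
        return tuple(r for r in self.rules if r.kind == "exclusion") + tuple(
            r for r in self.rules if r.kind == "inclusion"
        )


#: Default rules distilled from the recurring zero-shot error themes:
#: treatment-plan text mistaken for current status, non-specific symptoms
#: over-generalised to "Mobility, unspecified", falls and wheelchair use
#: assigned to the wrong class, and standardised instrument scores
#: (FOTO, PSFS, TUG) not being read as impairment evidence.
DEFAULT_RULES = RuleSet(
    (
        Rule(
            "exclude_treatment_plans",
            "exclusion",
            "Ignore any text that describes a treatment plan, discussion, "
            "suggestion, instruction, recommendation, goal, or advice — for "
            "example 'patient will begin home exercise program' — unless it "
            "explicitly states the patient is expected to improve in a "
            "specific mobility class, which implies an existing impairment "
            "in that class.",
        ),
        Rule(
            "exclude_nonspecific_symptoms",
            "exclusion",
            "Do not treat non-specific general symptoms such as dizziness, "
            "headaches, vertigo, weakness, or debility as evidence for "
            "'Mobility, unspecified' impairment; such general symptoms are "
            "excluded unless a functional limitation is directly described.",
        ),
        Rule(
            "falls_are_body_position",
            "inclusion",
            "Repeated falls are classified under 'Changing and maintaining "
            "body position' (postural control), not 'Walking and moving'.",
        ),
        Rule(
            "wheelchair_is_transportation",
            "inclusion",
            "Wheelchair use is classified exclusively under 'Moving around "
            "using transportation'.",
        ),
        Rule(
            "instrument_scores_imply_impairment",
            "inclusion",
            "A low FOTO score, a low current PSFS score or an expectation of "
            "future PSFS improvement, and a poor Timed Up and Go (TUG) "
            "result each indicate impairment in 'Mobility, unspecified'.",
        ),
    )
)


def load_rules(path) -> RuleSet:
    """Load a RuleSet from YAML: ``rules: [{rule_id, kind, text}, ...]``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return RuleSet(tuple(Rule(r["rule_id"], r["kind"], r["text"]) for r in doc.get("rules", [])))


# ---------------------------------------------------------------------------
# Shared blocks
# ---------------------------------------------------------------------------

def _class_definitions(taxonomy: Taxonomy) -> str:
    lines = []
    for cls in taxonomy:
        if not cls.definition.strip():
            raise ValueError(f"class {cls.tag} has no definition for prompting")
        codes = ", ".join(cls.icf_codes[:3]) + ("..." if len(cls.icf_codes) > 3 else "")
        lines.append(f"- {cls.display_name} ({cls.tag}; ICF {codes}): {cls.definition}")
    return "\n".join(lines)


def _exemplar_block(idx: int, ex: AnnotatedSection, taxonomy: Taxonomy) -> str:
    """A worked example: text, canonical answer, auto-generated explanation."""
    expl_lines = []
    for cls in taxonomy:
        status = ex.gold[cls.tag]
        if status is not ImpairmentStatus.NO_MENTION:
            expl_lines.append(
                f"Labeled '{cls.display_name}' {status.value} because the text "
                f"mentions a {cls.display_name.lower()}-related expression."
            )
    if not expl_lines:
        expl_lines.append("No mobility classes are mentioned in this example.")
    return (
        f"Example {idx}:\n"
        f"Text:\n{ex.section.text}\n"
        f"Correct annotation:\n{canonical_format(ex.gold, taxonomy)}\n"
        f"Explanation: " + " ".join(expl_lines)
    )


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_zero_shot(section: Section, taxonomy: Taxonomy = DEFAULT_TAXONOMY) -> str:
    return PromptTemplate.builtin("zero_shot").render(
        task_description=TASK_DESCRIPTION,
        class_definitions=_class_definitions(taxonomy),
        general_instruction=GENERAL_INSTRUCTION,
        section_text=section.text,
        output_format=OUTPUT_FORMAT,
        final_question=FINAL_QUESTION,
    )


def build_few_shot(
    section: Section,
    exemplars: list[AnnotatedSection],
    taxonomy: Taxonomy = DEFAULT_TAXONOMY,
    strategy_id: str = "few_shot_random",
) -> str:
    if not exemplars:
        raise ValueError("few-shot prompting requires at least one exemplar")
    for ex in exemplars:
        if ex.section_id == section.section_id:
            raise ValueError(
                f"exemplar {ex.section_id!r} is the query section itself (leakage guard)"
            )
    blocks = "\n\n".join(
        _exemplar_block(i + 1, ex, taxonomy) for i, ex in enumerate(exemplars)
    )
    return PromptTemplate.builtin(strategy_id).render(
        task_description=TASK_DESCRIPTION,
        class_definitions=_class_definitions(taxonomy),
        general_instruction=GENERAL_INSTRUCTION,
        exemplars=blocks,
        section_text=section.text,
        output_format=OUTPUT_FORMAT,
        final_question=FINAL_QUESTION,
    )


def build_error_informed(
    section: Section, rules: RuleSet = DEFAULT_RULES, taxonomy: Taxonomy = DEFAULT_TAXONOMY
) -> str:
    numbered = "\n".join(f"{i + 1}. {r.text}" for i, r in enumerate(rules.ordered()))
    return PromptTemplate.builtin("error_informed").render(
        task_description=TASK_DESCRIPTION,
        class_definitions=_class_definitions(taxonomy),
        general_instruction=GENERAL_INSTRUCTION,
        rules=numbered,
        section_text=section.text,
        output_format=OUTPUT_FORMAT,
        final_question=FINAL_QUESTION,
    )


def build_decomposed_single(section: Section, taxonomy: Taxonomy = DEFAULT_TAXONOMY) -> str:
    """Chain-of-thought prompt: mention detection then impairment status,
    both inside one call."""
    return PromptTemplate.builtin("decomposed_single").render(
        task_description=TASK_DESCRIPTION,
        class_definitions=_class_definitions(taxonomy),
        general_instruction=GENERAL_INSTRUCTION,
        section_text=section.text,
        output_format=OUTPUT_FORMAT,
        final_question=FINAL_QUESTION,
    )


def build_decomposed_extract(section: Section, taxonomy: Taxonomy = DEFAULT_TAXONOMY) -> str:
    return PromptTemplate.builtin("decomposed_extract").render(
        task_description=TASK_DESCRIPTION,
        class_definitions=_class_definitions(taxonomy),
        general_instruction=GENERAL_INSTRUCTION,
        section_text=section.text,
        output_format=OUTPUT_FORMAT,
    )


def build_decomposed_classify(
    section: Section,
    mentioned: list[MobilityClass | str],
    taxonomy: Taxonomy = DEFAULT_TAXONOMY,
) -> str | None:
    """Second-pass prompt for the given mentioned classes; ``None`` signals
    the call can be skipped (nothing mentioned)."""
    if not mentioned:
        return None
    names = []
    for m in mentioned:
        cls = m if isinstance(m, MobilityClass) else taxonomy[m]
        names.append(f"- {cls.display_name}")
    return PromptTemplate.builtin("decomposed_classify").render(
        task_description=TASK_DESCRIPTION,
        class_definitions=_class_definitions(taxonomy),
        general_instruction=GENERAL_INSTRUCTION,
        mentioned_classes="\n".join(names),
        section_text=section.text,
        output_format=OUTPUT_FORMAT,
    )


def build_decomposed_pair(
    section: Section,
    mentioned: list[MobilityClass | str],
    taxonomy: Taxonomy = DEFAULT_TAXONOMY,
) -> tuple[str, str | None]:
    """(extract prompt, classify prompt) for the two-model decomposition;
    the classify member is ``None`` when no class was mentioned."""
    return (
        build_decomposed_extract(section, taxonomy),
        build_decomposed_classify(section, mentioned, taxonomy),
    )
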