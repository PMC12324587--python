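"""Wire the stages into a reproducible run: sectionize → (select) →
prompt → complete → parse → evaluate → report.

A run is driven by a YAML config and writes a self-contained directory:
sections, a prompt/response transcript, predictions, metrics, and a
manifest (config snapshot, seeds, prompt hashes, package version) from
which the run can be replayed byte-identically with mock backends.
Backend failures degrade per section — the affected section gets a
failed, all-NoMention prediction — and never abort a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import yaml

from . import __version__
from .backends import Backend, BackendConfig, BackendError, make_backend
from .evaluation import evaluate, report
from .exemplars import (
    ExemplarPool,
    select_error_clusters,
    select_nearest,
    select_random,
    selection_manifest,
)
from .parsing import parse
from .prompting import (
    DEFAULT_RULES,
    RuleSet,
    build_decomposed_classify,
    build_decomposed_extract,
    build_decomposed_single,
    build_error_informed,
    build_few_shot,
    build_zero_shot,
    load_rules,
)
from .sectionize import DEFAULT_LEXICON, notes_from_jsonl, sections_to_jsonl
from .synth import SynthConfig, generate_corpus, gold_from_jsonl, gold_to_jsonl
from .taxonomy import (
    DEFAULT_TAXONOMY,
    AnnotatedSection,
    ImpairmentStatus,
    LabelSet,
    PredictionRecord,
    Section,
    Taxonomy,
    load_taxonomy,
    mention_status,
    Mention,
    TAGS,
)

__all__ = ["RunConfig", "run_experiment", "annotate_sections", "dev_split"]

log = logging.getLogger(__name__)


def _prompt_hash(prompt: str) -> str:
    return hashlib.sha256(prompt.encode()).hexdigest()[:16]


@dataclass
class RunConfig:
    """Validated view of the run YAML. See ``from_yaml`` for the schema."""

    output_dir: Path
    strategy_id: str = "zero_shot"
    shots: int = 5
    seed: int = 0
    rules_path: Path | None = None
    pool_path: Path | None = None
    notes_path: Path | None = None
    sections_path: Path | None = None
    gold_path: Path | None = None
    generate: SynthConfig | None = None
    taxonomy_path: Path | None = None
    backend: BackendConfig = field(default_factory=BackendConfig)
    task2_denominator: str = "both"
    levels: tuple[str, ...] = ("section", "note", "patient")
    redact_text_from_logs: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        inputs = doc.get("inputs", {}) or {}
        strategy = doc.get("strategy", {}) or {}
        backend = doc.get("backend", {}) or {}
        ev = doc.get("evaluation", {}) or {}
        gen = doc.get("generate")
        cfg = cls(
            output_dir=Path(doc["output_dir"]),
            strategy_id=strategy.get("id", "zero_shot"),
            shots=int(strategy.get("shots", 5)),
            seed=int(strategy.get("seed", 0)),
            rules_path=Path(strategy["rules_path"]) if strategy.get("rules_path") else None,
            pool_path=Path(strategy["pool_path"]) if strategy.get("pool_path") else None,
            notes_path=Path(inputs["notes"]) if inputs.get("notes") else None,
            sections_path=Path(inputs["sections"]) if inputs.get("sections") else None,
            gold_path=Path(inputs["gold"]) if inputs.get("gold") else None,
            generate=SynthConfig(**gen) if gen else None,
            taxonomy_path=Path(doc["taxonomy"]) if doc.get("taxonomy") else None,
            backend=BackendConfig(**backend),
            task2_denominator=ev.get("task2_denominator", "both"),
            levels=tuple(ev.get("levels", ("section", "note", "patient"))),
            redact_text_from_logs=bool(doc.get("redact_text_from_logs", True)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        from .prompting import STRATEGY_IDS

        run_strategies = tuple(s for s in STRATEGY_IDS if s != "decomposed_classify") + (
            "decomposed_pair",
        )
        if self.strategy_id not in run_strategies:
            raise ValueError(
                f"unknown strategy {self.strategy_id!r}; known: {run_strategies}"
            )
        if self.generate is None and not (self.notes_path or self.sections_path):
            raise ValueError("config must provide inputs.notes, inputs.sections, or a generate block")
        for p in (self.notes_path, self.sections_path, self.gold_path,
                  self.pool_path, self.rules_path, self.taxonomy_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        if self.strategy_id in ("few_shot_random", "few_shot_kmeans") and self.pool_path is None and self.generate is None:
            raise ValueError(f"strategy {self.strategy_id} needs strategy.pool_path")


def dev_split(
    annotations: Sequence[AnnotatedSection], n: int = 200, seed: int = 0,
    site_id: str | None = None,
) -> tuple[list[AnnotatedSection], list[AnnotatedSection]]:
    """Seeded random draw of ``n`` sections (optionally from one site) as a
    development pool; everything else is the test set."""
    eligible = [a for a in annotations if site_id is None or a.section.site_id == site_id]
    if len(eligible) < n:
        raise ValueError(f"only {len(eligible)} eligible sections for a {n}-section pool")
    chosen = set(
        a.section_id for a in random.Random(seed).sample(eligible, n)
    )
    pool = [a for a in annotations if a.section_id in chosen]
    rest = [a for a in annotations if a.section_id not in chosen]
    return pool, rest


def annotate_sections(
    sections: Sequence[Section],
    prompt_for: Callable[[Section], str],
    backend: Backend,
    strategy_id: str,
    taxonomy: Taxonomy = DEFAULT_TAXONOMY,
    transcript: list | None = None,
) -> list[PredictionRecord]:
    """One prediction per section, regardless of backend failures."""
    records = []
    for section in sections:
        prompt = prompt_for(section)
        try:
            response = backend.complete(prompt, section_id=section.section_id)
        except BackendError as exc:
            log.warning("section=%s strategy=%s backend failure: %s",
                        section.section_id, strategy_id, exc)
            records.append(
                PredictionRecord(
                    section_id=section.section_id,
                    predicted=LabelSet.all_no_mention(),
                    raw_response="",
                    parse_status="failed",
                    strategy_id=strategy_id,
                )
            )
            continue
        result = parse(response, taxonomy)
        if transcript is not None:
            transcript.append(
                {
                    "section_id": section.section_id,
                    "strategy_id": strategy_id,
                    "prompt_hash": _prompt_hash(prompt),
                    "response": response,
                }
            )
        log.info("section=%s strategy=%s parse_status=%s",
                 section.section_id, strategy_id, result.status)
        records.append(
            PredictionRecord(
                section_id=section.section_id,
                predicted=result.labels,
                raw_response=response,
                parse_status=result.status,
                strategy_id=strategy_id,
            )
        )
    return records


def _annotate_decomposed_pair(
    sections: Sequence[Section],
    backend: Backend,
    taxonomy: Taxonomy,
    transcript: list | None,
) -> list[PredictionRecord]:
    """Extraction pass first; its mentions feed the classification pass."""
    extract_records = annotate_sections(
        sections, lambda s: build_decomposed_extract(s, taxonomy), backend,
        "decomposed_extract", taxonomy, transcript,
    )
    by_id = {s.section_id: s for s in sections}
    merged = []
    for rec in extract_records:
        mentioned = list(rec.predicted.mentioned_tags())
        if not mentioned or rec.parse_status == "failed":
            merged.append(
                PredictionRecord(rec.section_id, LabelSet.all_no_mention(),
                                 rec.raw_response, rec.parse_status, "decomposed_pair")
            )
            continue
        section = by_id[rec.section_id]
        prompt = build_decomposed_classify(section, mentioned, taxonomy)
        sub = annotate_sections(
            [section], lambda s: prompt, backend, "decomposed_classify", taxonomy, transcript
        )[0]
        labels = {t: ImpairmentStatus.NO_MENTION for t in TAGS}
        for t in mentioned:
            status = sub.predicted[t]
            # a mentioned class whose status the classify pass left silent
            # keeps the extraction pass's placeholder status
            labels[t] = status if status is not ImpairmentStatus.NO_MENTION else rec.predicted[t]
        merged.append(
            PredictionRecord(rec.section_id, LabelSet(labels), sub.raw_response,
                             sub.parse_status if sub.parse_status != "failed" else "fallback",
                             "decomposed_pair")
        )
    return merged


def _select_exemplars(cfg: RunConfig, pool: ExemplarPool):
    if cfg.strategy_id == "few_shot_random":
        return select_random(pool, cfg.shots, cfg.seed)
    if cfg.strategy_id == "few_shot_kmeans":
        if not any(pool.zero_shot_error_flags):
            raise ValueError(
                "few_shot_kmeans needs a pool with zero-shot error flags; "
                "run a zero-shot pass on the pool and record its errors first"
            )
        return select_error_clusters(pool, cfg.shots, cfg.seed)
    return None  # few_shot_knn selects per query


def run_experiment(config: "RunConfig | str | Path") -> Path:
    """Execute a full run and return its output directory."""
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_yaml(config)
    cfg.validate()
    taxonomy = load_taxonomy(cfg.taxonomy_path) if cfg.taxonomy_path else DEFAULT_TAXONOMY
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs ------------------------------------------------------------
    gold: list[AnnotatedSection] | None = None
    if cfg.generate is not None:
        notes, gold = generate_corpus(cfg.generate)
        sections = [s for n in notes for s in n.sections]
        with open(out / "gold.jsonl", "w") as fh:
            gold_to_jsonl(gold, fh)
    elif cfg.sections_path is not None:
        from .sectionize import sections_from_jsonl

        with open(cfg.sections_path) as fh:
            sections = sections_from_jsonl(fh)
    else:
        with open(cfg.notes_path) as fh:
            notes = notes_from_jsonl(fh, DEFAULT_LEXICON)
        sections = [s for n in notes for s in n.sections]
    if cfg.gold_path is not None:
        with open(cfg.gold_path) as fh:
            gold = gold_from_jsonl(fh)
    with open(out / "sections.jsonl", "w") as fh:
        sections_to_jsonl(sections, fh)

    # --- backend -----------------------------------------------------------
    gold_by_section = {g.section_id: g.gold for g in gold} if gold else None
    backend = make_backend(cfg.backend, gold_by_section)

    # --- exemplar selection --------------------------------------------------
    pool: ExemplarPool | None = None
    exemplars = None
    if cfg.strategy_id in ("few_shot_random", "few_shot_kmeans", "few_shot_knn"):
        if cfg.pool_path is not None:
            with open(cfg.pool_path) as fh:
                pool = ExemplarPool.from_jsonl(fh)
        elif gold is not None:
            pool_items, _ = dev_split(gold, n=min(len(gold) // 2, 200), seed=cfg.seed)
            pool = ExemplarPool.build(pool_items)
        else:
            raise ValueError("few-shot strategies need strategy.pool_path or generated gold")
        exemplars = _select_exemplars(cfg, pool)
        if exemplars is not None:
            (out / "selection.json").write_text(
                json.dumps(selection_manifest(cfg.strategy_id, cfg.seed, exemplars), indent=2)
            )
        # few-shot pools must not leak into the evaluated set
        if gold is not None:
            pool_ids = {it.section_id for it in pool.items}
            gold = [g for g in gold if g.section_id not in pool_ids]
            sections = [s for s in sections if s.section_id not in pool_ids]

    # --- prompts + backend + parse -----------------------------------------
    rules = load_rules(cfg.rules_path) if cfg.rules_path else DEFAULT_RULES
    transcript: list = []
    if cfg.strategy_id == "decomposed_pair":
        predictions = _annotate_decomposed_pair(sections, backend, taxonomy, transcript)
    else:
        builders: dict[str, Callable[[Section], str]] = {
            "zero_shot": lambda s: build_zero_shot(s, taxonomy),
            "few_shot_random": lambda s: build_few_shot(s, exemplars, taxonomy, cfg.strategy_id),
            "few_shot_kmeans": lambda s: build_few_shot(s, exemplars, taxonomy, cfg.strategy_id),
            "few_shot_knn": lambda s: build_few_shot(
                s, select_nearest(pool, s, cfg.shots), taxonomy, cfg.strategy_id
            ),
            "error_informed": lambda s: build_error_informed(s, rules, taxonomy),
            "decomposed_single": lambda s: build_decomposed_single(s, taxonomy),
            "decomposed_extract": lambda s: build_decomposed_extract(s, taxonomy),
        }
        predictions = annotate_sections(
            sections, builders[cfg.strategy_id], backend, cfg.strategy_id, taxonomy, transcript
        )

    with open(out / "transcript.jsonl", "w") as fh:
        for rec in transcript:
            fh.write(json.dumps(rec) + "\n")
    with open(out / "predictions.jsonl", "w") as fh:
        for rec in predictions:
            fh.write(json.dumps(rec.to_dict()) + "\n")

    # --- evaluation ---------------------------------------------------------
    if gold is not None:
        rows = evaluate(
            gold, predictions, site_id=sections[0].site_id if sections else "all",
            levels=cfg.levels, task2_denominator=cfg.task2_denominator,
        )
        report(rows).to_csv(out / "metrics.csv", index=False)

    manifest = {
        "package_version": __version__,
        "strategy_id": cfg.strategy_id,
        "seed": cfg.seed,
        "shots": cfg.shots,
        "backend": {
            "kind": cfg.backend.backend_kind,
            "model_name": cfg.backend.model_name,
            "temperature": cfg.backend.temperature,
            "seed": cfg.backend.seed,
        },
        "generate": None if cfg.generate is None else {
            k: (v if not isinstance(v, dict) else dict(v))
            for k, v in vars(cfg.generate).items()
        },
        "n_sections": len(sections),
        "prompt_hashes_digest": hashlib.sha256(
            "".join(sorted(t["prompt_hash"] for t in transcript)).encode()
        ).hexdigest()[:16],
        "task2_denominator": cfg.task2_denominator,
        "levels": list(cfg.levels),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
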