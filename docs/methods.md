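# Methods

This note documents the models, conventions, and design choices behind
`mobex`, and what its synthetic experiments do and do not demonstrate.

## Task and label semantics

The unit of analysis is a named note *section*. Sections are preferred
over whole notes because they fit model context windows, are
semantically coherent, and align with how clinicians read notes. Each
section carries a total mapping from the five ICF-grounded mobility
classes (CB, CO, WM, MT, MU) to a three-valued status: Impaired,
Unimpaired, or NoMention. "NoMention" is the serialisation-safe name for
the "None" status in model-facing text; the parser maps between the two.
ICF codes and class definitions are prompt metadata only — they are
configurable (YAML) and never used in computation. The default codes are
the standard ICF d4 chapter blocks (d410–429, d430–449, d450–469,
d470–489, d498–499); substitute verbatim ICF text via the taxonomy
config if needed.

Evaluation is hierarchical and two-task:

* **Task 1 (Mobility Extraction)** — per class, Impaired/Unimpaired
  collapse to Mentioned; Mentioned is the positive class.
* **Task 2 (Impairment Classification)** — restricted to mentioned
  sections, Impaired positive.

**Task 2 denominator.** "Restricted to mentioned sections" is ambiguous
when detection itself errs. The default conditions on sections where
*both* gold and prediction mark the class Mentioned, so Task 2 measures
status discrimination uncontaminated by detection errors. A
`task2_denominator="gold"` switch conditions on gold mentions only, so
detection misses count against Task 2 — useful as a sensitivity
analysis; the two coincide under perfect detection.

**Aggregation.** Note- and patient-level labels are the class-wise roll-up
of section labels: Impaired if any constituent section is Impaired, else
Unimpaired if any is Unimpaired, else NoMention. Rationale: impairment
evidence anywhere in a note is clinically meaningful, and the rule makes
perfect section predictions propagate to perfect upper-level metrics. It
is idempotent and order-independent.

**Degenerate ratios.** Any 0/0 (e.g. a class never mentioned in a small
corpus) is reported as 0 with a `degenerate` flag, never NaN. This means
the perfect-prediction⇒F1=1 invariant requires every class to have
positive support at the evaluated level; tiny corpora can legitimately
show flagged zeros under perfect predictions.

**Micro-average.** Confusion counts are pooled across the five classes
within a site/level, then scored; cross-site aggregates pool across
sites as well. This is pooling, not support-weighted averaging of
per-class scores.

## Sectionizer

No standard exists for splitting clinical notes; the implementation is a
deliberate, configurable heuristic. A line whose stripped text (minus an
optional trailing colon) case-insensitively equals a lexicon entry opens
a section; optionally any ≤8-word Title Case/ALL CAPS line ending in a
colon does too. Text before the first header becomes a `PREAMBLE`
section. Section texts *include* their header line, so concatenating a
note's section texts reconstructs the newline-normalised input exactly —
the partition property the tests enforce. The shipped lexicon covers
common PT/OT and clinic headers and is fully replaceable.

## Prompting

Templates are plain-text files with `$name` placeholders
(`string.Template`; `str.format` braces would collide with braces in
clinical text). Every strategy embeds the identical output-format
instruction, so one parser grammar covers all strategies. The query
section is delimited by `BEGIN SECTION`/`END SECTION` lines, which also
lets the lexicon mock identify the query inside few-shot prompts whose
exemplar blocks contain other section texts.

Few-shot exemplar explanations are auto-generated from gold labels
("labeled X because the text mentions an X-related expression"); users
wanting richer rationales can edit the template. The leakage guard
rejects an exemplar whose `section_id` equals the query's; textual
coincidence between distinct sections is allowed (synthetic corpora
produce legitimately identical filler sections).

The default error-informed rule set encodes the recurring zero-shot
error themes: excluding treatment-plan/recommendation text unless
expected improvement is stated; excluding non-specific symptoms
(dizziness, weakness, debility) from "Mobility, unspecified"; assigning
repeated falls to body position rather than walking; consolidating
wheelchair use under transportation; and reading low FOTO/PSFS scores
and poor TUG results as impairment evidence. Rules render exclusions
first, then inclusions, numbered, in declaration order.

**Task decomposition.** The single-prompt mode asks for two explicit
steps (mention detection, then status) in one call. The two-model mode
issues an extraction prompt whose answers use a `Mentioned` status
token, then a classification prompt listing only the mentioned classes.
To keep one parser grammar, `Mentioned` parses as a mention placeholder
(internally Impaired) whose status the classification pass overwrites;
if the second pass stays silent on a listed class, the placeholder
stands rather than dropping a detected mention.

## Backends and determinism

`BackendConfig` rejects any non-zero temperature: deterministic decoding
is part of the reliability contract, and all seeded components
(selection, mocks, generator) are reproducible byte-for-byte. The HTTP
adapter targets a locally hosted endpoint and refuses non-localhost
hosts unless `allow_remote=True`, so note text cannot leave the machine
by misconfiguration. Backend failures after `retries+1` attempts become
a per-section failed prediction (all-NoMention, `parse_status=failed`);
a batch of n sections always yields exactly n prediction records.

The noisy-oracle mock corrupts gold labels independently per
(section, class): a true mention survives with probability *s*
(sensitivity), its status flipped with probability `status_flip`; a true
negative stays silent with probability *p* (specificity), else becomes a
false mention with a coin-flip status. Independence is the simplest
model that yields closed forms: Task 1 recall → *s* and precision →
sπ/(sπ+(1−p)(1−π)) at mention prevalence π; Task 2 recall under a flip
rate f → 1−f. The per-section RNG is derived from (seed, section_id) via
CRC32, so results are independent of call order.

## Exemplar selection

The text representation is lowercased word-unigram TF-IDF with cosine
similarity — deterministic, dependency-light, and hand-checkable; the
vectorizer is pluggable (any `transform` producing row-aligned vectors,
e.g. a sentence-embedding adapter). K-means error clustering runs on the
zero-shot error cases with k = shot count (default 5), seeded
initialisation, 10 restarts, max 300 iterations, tolerance 1e-4;
"representative of a cluster" means the real item nearest the centroid
by cosine distance (centroids are not text). Ties break to the lowest
item index everywhere. With fewer than k error cases, all of them are
returned plus a seeded random fill from the non-error pool; with
duplicate-point degeneracies, unused lowest-index errors fill empty
clusters. Selection k, like everything else, is configuration.

## Synthetic corpus

The generator emulates corpus *structure*, not clinical language: per
section and class independently, a mention occurs with `mention_prob`
(default 0.1, making ~59 % of sections mention nothing — a sparsity in
the neighbourhood of real sectioned PT/OT corpora) and is Impaired with
`impaired_given_mention` (default 0.7, matching the impaired-heavy skew
of mobility documentation). Mentions render as sentences carrying unique
marker phrases; distractors (treatment-plan language, vague symptoms)
appear with `distractor_prob` 0.3 and carry no marker. A correlation
knob (`note_severity_sd`, a shared per-note logit shift) exists but is
off by default so the closed-form expectations hold. Default scale is
200 notes of 6 sections for one site, echoing a per-site annotation
effort of a few hundred notes and a few thousand sections; tests and the
acceptance script scale n up or down per experiment (600 notes for the
perfect-prediction check, 5,000 sections for noise recovery) — sizes
chosen so binomial standard errors are well inside the asserted
tolerances.

Because markers are unambiguous by construction, the lexicon mock
recovers gold exactly; a passing end-to-end run therefore demonstrates
the *plumbing* (sectionization → prompts → parsing → evaluation) is
lossless, not that any model understands clinical text. Conversely the
noisy-oracle experiments validate the *evaluator* against analytic
truth. Neither says anything about real-EHR performance, which depends
on language phenomena (negation, hedging, temporal scope, cross-section
coreference) the generator deliberately does not model.

## Parser

Strict pass: every non-blank line must match
`<display_name or tag>: <status>` with each class exactly once
(order-insensitive, case-insensitive statuses). Fallback: per class,
regex search for the display name (case-insensitive) or the bare tag
(exact case, to avoid matching ordinary words) followed by a status
token on the same line; the last occurrence wins on contradiction and
the record is flagged. No class matched on a non-empty response ⇒
`failed`, which forces an all-NoMention prediction. `parse` never
raises: arbitrary bytes are at worst `failed`.

## Known limitations

* The sectionizer is heuristic; notes whose headers are absent from the
  lexicon collapse into a preamble unless the Title Case heuristic is
  enabled.
* TF-IDF similarity ignores word order and negation; similarity-based
  selection may retrieve superficially similar exemplars.
* The gold-denominator Task 2 variant makes FN/TN attribution for missed
  detections a convention (miss = negative prediction).
* Adjudication re-scoring accepts overrides as given; it implements the
  bookkeeping, not the clinical judgement.
* Mock-validated metrics bound plumbing correctness only; real-model
  performance must be measured on real annotated notes.
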