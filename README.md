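# mobex

Extracting **mobility functional status** from clinical notes with large
language models — and measuring how well it works.

Clinicians document how well patients move (transfers, walking, carrying,
use of transportation) in free text, not in coded fields. `mobex`
implements an LLM-based annotation pipeline that turns a clinical note
into structured per-section labels over five mobility classes grounded in
the WHO ICF d4 (Mobility) chapter:

| tag | class |
|-----|-------|
| CB  | Changing and maintaining body position |
| CO  | Carrying, moving, and handling objects |
| WM  | Walking and moving |
| MT  | Moving around using transportation |
| MU  | Mobility, unspecified |

Each section receives, per class, one of three statuses: **Impaired**
(difficulty or limitation described), **Unimpaired** (explicitly normal
function), or **None** (class not referenced). The pipeline is:

```
note ──sectionize──► sections ──prompt──► LLM ──parse──► LabelSet ──evaluate──► metrics
```

It is intended for clinical-NLP researchers and informatics teams who
want to (a) run prompt-engineering experiments for functional-status
extraction against a local model, and (b) rigorously evaluate the
results. Because real EHR text is protected, the package ships a
synthetic note generator with known gold labels and two deterministic
mock backends, so the entire pipeline — including every metric — is
exercisable and testable without any model or any patient data.

## What it implements

* **Sectionizer** — lexicon-driven splitting of raw notes into named
  sections (the unit of analysis), with an exact partition guarantee.
* **Prompt strategies** — zero-shot; five-shot with three exemplar
  selectors (random; k-means clustering of zero-shot *error* cases with
  one representative per cluster; per-query k-nearest-neighbour over
  TF-IDF/cosine); error-informed refinement (curated inclusion/exclusion
  rules injected into the prompt, e.g. *ignore treatment-plan text*,
  *classify falls under body position*, *wheelchair use under
  transportation*); and two task decompositions (single chain-of-thought
  prompt, or an extract→classify prompt pair for two specialised models).
* **Backends** — a uniform `complete(prompt)` contract at temperature 0
  (deterministic decoding is enforced), a local-HTTP adapter that refuses
  remote endpoints by default, and the two mocks described above.
* **Parser** — a line-oriented canonical grammar
  (`<class name>: Impaired|Unimpaired|None`) with a strict pass, a regex
  fallback, and a total never-raise contract.
* **Two-task evaluation** — Task 1 *Mobility Extraction* (Mentioned vs
  Not Mentioned, per class) and Task 2 *Impairment Classification*
  (Impaired vs Unimpaired on mentioned sections, Impaired positive):

  P = TP/(TP+FP),  R = TP/(TP+FN),  F1 = 2PR/(P+R)

  per class and micro-averaged (counts pooled over classes), at section,
  note, and patient level (labels roll up by an any-mention,
  impairment-dominates rule), plus corpus profiling (class-combination
  counts) and adjudication re-scoring (accepting clinically reasonable
  inferences as correct).

## Worked example

Generate a 50-note synthetic corpus, annotate it with the error-informed
strategy against a noisy-oracle backend (sensitivity 0.85, specificity
0.95 — a stand-in model that detects 85 % of true mentions and stays
silent on 95 % of true negatives), and score it:

```python
from pathlib import Path
import pandas as pd
from mobex import RunConfig, BackendConfig, run_experiment
from mobex.synth import SynthConfig

cfg = RunConfig(
    output_dir=Path("runs/demo"),
    strategy_id="error_informed",
    generate=SynthConfig(n_patients=50, sections_per_note=6, seed=11),
    backend=BackendConfig(backend_kind="noisy_oracle_mock",
                          sensitivity=0.85, specificity=0.95, seed=11),
)
out = run_experiment(cfg)
df = pd.read_csv(out / "metrics.csv")
print(df[df.level == "section"].to_string(index=False))
```

prints

```
  level           cls  site1_task1_F1  site1_task1_P  site1_task1_R  site1_task2_F1
section            CB          0.7246         0.6098         0.8929             1.0
section            CO          0.6761         0.5714         0.8276             1.0
section            WM          0.7458         0.5946         1.0000             1.0
section            MT          0.7742         0.6667         0.9231             1.0
section            MU          0.7143         0.6250         0.8333             1.0
section micro_average          0.7251         0.6122         0.8889             1.0
```

Task 1 recall sits near the backend's sensitivity (0.85); precision is
lower because at a 0.1 per-class mention prevalence even a 5 %
false-mention rate produces many false positives — exactly the analytic
expectation sπ/(sπ+(1−p)(1−π)) ≈ 0.65 at this prevalence, plus sampling
noise on 300 sections. Task 2 is perfect because this backend flips no
statuses (`status_flip=0`). The run directory also contains the
sections, a prompt/response transcript, predictions, and a manifest that
replays the run byte-identically.

The same pipeline is scriptable from the shell:

```bash
mobex generate --n-patients 50 --out corpus/
mobex sectionize corpus/notes.jsonl --out corpus/sections.jsonl
mobex run --config run.yaml
mobex evaluate corpus/gold.jsonl runs/demo/predictions.jsonl --out metrics.csv
```

To target a real model, point `backend` at a locally served
completion endpoint (`backend_kind: http_endpoint`); remote hosts are
refused unless explicitly overridden, and temperature must be 0.

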