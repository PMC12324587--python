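"""Uniform text-completion contract plus fully deterministic mock backends.

The real deployment target is a locally hosted model served with greedy
decoding (temperature 0), so repeated queries yield identical output and
no protected health information leaves the local environment. Remote
endpoints are refused unless explicitly overridden.

Two mocks make the entire pipeline testable without any model:

* ``lexicon_mock`` — scans the query section for the synthetic
  generator's marker phrases and emits canonical labels for every
  detected (class, status) pair;
* ``noisy_oracle_mock`` — emits a seeded corruption of the gold labels
  under an independence model (per-class sensitivity / specificity /
  status flip), so evaluator output can be checked against closed-form
  expectations.
"""

from __future__ import annotations

import json
import logging
import random
import re
import time
import urllib.request
import zlib
from dataclasses import dataclass, field
from typing import Mapping
from urllib.parse import urlparse

from .taxonomy import TAGS, ImpairmentStatus, LabelSet
from .parsing import canonical_format
from .synth import MARKER_PHRASES

__all__ = [
    "BackendConfig",
    "BackendError",
    "Backend",
    "LexiconMockBackend",
    "NoisyOracleBackend",
    "HttpEndpointBackend",
    "make_backend",
    "lexicon_mock_respond",
    "noisy_oracle_respond",
]

log = logging.getLogger(__name__)

BACKEND_KINDS = ("http_endpoint", "local_process", "lexicon_mock", "noisy_oracle_mock")

_LOCAL_HOSTS = ("localhost", "127.0.0.1", "::1")


@dataclass(frozen=True)
class BackendConfig:
    backend_kind: str = "lexicon_mock"
    model_name: str = ""
    temperature: float = 0.0
    max_output_tokens: int = 512
    timeout_s: float = 30.0
    retries: int = 2
    seed: int = 0  # mocks only
    endpoint_url: str = "http://localhost:11434/api/generate"
    allow_remote: bool = False
    # noisy oracle knobs
    sensitivity: float = 1.0
    specificity: float = 1.0
    status_flip: float = 0.0

    def __post_init__(self) -> None:
        if self.backend_kind not in BACKEND_KINDS:
            raise ValueError(f"backend_kind must be one of {BACKEND_KINDS}")
        if self.temperature != 0:
            raise ValueError(
                "temperature must be 0: deterministic decoding is part of the "
                "reliability contract"
            )
        if self.retries < 0:
            raise ValueError("retries must be >= 0")


class BackendError(RuntimeError):
    """Raised by a backend after exhausting its retries. Batch drivers catch
    this and record a failed prediction; it never aborts a run."""


class Backend:
    """Contract: ``complete`` returns the model's text for a prompt; same
    prompt (and section) with the same config must return the same text."""

    config: BackendConfig

    def complete(self, prompt: str, section_id: str | None = None) -> str:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# Lexicon mock
# ---------------------------------------------------------------------------

_SECTION_RE = re.compile(r"BEGIN SECTION\n(.*?)\nEND SECTION", re.DOTALL)


def _extract_section(prompt: str) -> str:
    """The query section is the last BEGIN/END SECTION block; prompts that
    carry no block (direct section text) are scanned whole."""
    blocks = _SECTION_RE.findall(prompt)
    return blocks[-1] if blocks else prompt


def lexicon_mock_respond(section_text: str) -> str:
    """Canonical labels for every marker phrase found in the text."""
    low = section_text.lower()
    labels = {t: ImpairmentStatus.NO_MENTION for t in TAGS}
    for (tag, status), phrase in MARKER_PHRASES.items():
        if phrase.lower() in low:
            labels[tag] = status
    return canonical_format(LabelSet(labels))


class LexiconMockBackend(Backend):
    def __init__(self, config: BackendConfig | None = None) -> None:
        self.config = config or BackendConfig(backend_kind="lexicon_mock")

    def complete(self, prompt: str, section_id: str | None = None) -> str:
        if not prompt:
            raise BackendError("empty prompt")
        return lexicon_mock_respond(_extract_section(prompt))


# ---------------------------------------------------------------------------
# Noisy oracle mock
# ---------------------------------------------------------------------------

def noisy_oracle_respond(
    gold: LabelSet,
    sensitivity: float,
    specificity: float,
    status_flip: float,
    seed: int,
) -> str:
    """Seeded single-labelset corruption, canonical-format output.

    Per class independently: a gold-Mentioned class is emitted as Mentioned
    with probability ``sensitivity`` (else None); a gold-NoMention class is
    emitted as None with probability ``specificity`` (else Mentioned with a
    random status); an emitted Mentioned status equals gold except flipped
    with probability ``status_flip``.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("status_flip", status_flip)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} = {v} is not a probability")
    rng = random.Random(seed)
    labels: dict[str, ImpairmentStatus] = {}
    for tag in TAGS:
        g = gold[tag]
        if g is ImpairmentStatus.NO_MENTION:
            if rng.random() < specificity:
                labels[tag] = ImpairmentStatus.NO_MENTION
            else:
                labels[tag] = rng.choice((ImpairmentStatus.IMPAIRED, ImpairmentStatus.UNIMPAIRED))
        elif rng.random() < sensitivity:
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
    return canonical_format(LabelSet(labels))


class NoisyOracleBackend(Backend):
    """Corrupts gold labels looked up by section_id; the per-section RNG is
    derived from (config seed, section_id), so results are deterministic and
    independent of call order."""

    def __init__(self, gold_by_section: Mapping[str, LabelSet], config: BackendConfig) -> None:
        self.gold_by_section = dict(gold_by_section)
        self.config = config

    def complete(self, prompt: str, section_id: str | None = None) -> str:
        if section_id is None or section_id not in self.gold_by_section:
            raise BackendError(f"noisy oracle has no gold for section {section_id!r}")
        sub_seed = (self.config.seed * 2654435761 + zlib.crc32(section_id.encode())) % (2**31)
        return noisy_oracle_respond(
            self.gold_by_section[section_id],
            self.config.sensitivity,
            self.config.specificity,
            self.config.status_flip,
            sub_seed,
        )


# ---------------------------------------------------------------------------
# Real backends
# ---------------------------------------------------------------------------

class HttpEndpointBackend(Backend):
    """Minimal JSON-over-HTTP completion client (ollama-style API shape).

    Local-only by default: non-localhost endpoints are refused unless
    ``allow_remote`` is set, so section text cannot leave the machine by
    misconfiguration.
    """

    def __init__(self, config: BackendConfig) -> None:
        host = urlparse(config.endpoint_url).hostname or ""
        if host not in _LOCAL_HOSTS and not config.allow_remote:
            raise ValueError(
                f"endpoint host {host!r} is not local; set allow_remote=True "
                "only if no protected text is involved"
            )
        self.config = config

    def complete(self, prompt: str, section_id: str | None = None) -> str:
        payload = json.dumps(
            {
                "model": self.config.model_name,
                "prompt": prompt,
                "stream": False,
                "options": {
                    "temperature": 0,
                    "num_predict": self.config.max_output_tokens,
                    "seed": self.config.seed,
                },
            }
        ).encode()
        last_err: Exception | None = None
        for attempt in range(self.config.retries + 1):
            try:
                req = urllib.request.Request(
                    self.config.endpoint_url,
                    data=payload,
                    headers={"Content-Type": "application/json"},
                )
                with urllib.request.urlopen(req, timeout=self.config.timeout_s) as resp:
                    doc = json.loads(resp.read().decode())
                return doc.get("response") or doc.get("text") or ""
            except Exception as exc:  # noqa: BLE001 - any transport failure retries
                last_err = exc
                log.warning("backend attempt %d/%d failed: %s",
                            attempt + 1, self.config.retries + 1, exc)
                if attempt < self.config.retries:
                    time.sleep(min(2.0**attempt * 0.1, 2.0))
        raise BackendError(
            f"endpoint failed after {self.config.retries + 1} attempts: {last_err}"
        )


class LocalProcessBackend(Backend):
    """Pipe the prompt to a local command (``model_name`` is the argv string)
    and return its stdout."""

    def __init__(self, config: BackendConfig) -> None:
        if not config.model_name:
            raise ValueError("local_process backend needs model_name as the command line")
        self.config = config

    def complete(self, prompt: str, section_id: str | None = None) -> str:
        import shlex
        import subprocess

        last_err: Exception | None = None
        for attempt in range(self.config.retries + 1):
            try:
                proc = subprocess.run(
                    shlex.split(self.config.model_name),
                    input=prompt,
                    capture_output=True,
                    text=True,
                    timeout=self.config.timeout_s,
                    check=True,
                )
                return proc.stdout
            except Exception as exc:  # noqa: BLE001
                last_err = exc
        raise BackendError(
            f"local process failed after {self.config.retries + 1} attempts: {last_err}"
        )


def make_backend(
    config: BackendConfig, gold_by_section: Mapping[str, LabelSet] | None = None
) -> Backend:
    if config.backend_kind == "lexicon_mock":
        return LexiconMockBackend(config)
    if config.backend_kind == "noisy_oracle_mock":
        if gold_by_section is None:
            raise ValueError("noisy_oracle_mock needs gold labels keyed by section_id")
        return NoisyOracleBackend(gold_by_section, config)
    if config.backend_kind == "http_endpoint":
        return HttpEndpointBackend(config)
    return LocalProcessBackend(config)
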