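"""Few-shot exemplar selection over a pool of annotated training sections.

Three strategies are offered, all returning exactly ``k`` distinct pool
items and all deterministic under their inputs (and seed, where one
applies):

* random     — uniform without replacement;
* error clustering — k-means over the text vectors of sections the
  zero-shot run mislabeled, one representative (the real item nearest
  each centroid by cosine distance) per cluster;
* nearest neighbour — per-query top-k by cosine similarity.

Text is represented by lowercased word-unigram TF-IDF with cosine as the
associated metric; the representation is pluggable (any object exposing
``transform`` producing row-aligned vectors can replace it).
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics.pairwise import cosine_similarity

from .taxonomy import AnnotatedSection, LabelSet, Section

__all__ = ["TextVectors", "ExemplarPool", "vectorize", "select_random",
           "select_error_clusters", "select_nearest", "selection_manifest"]

DEFAULT_SHOTS = 5  # five-shot configuration


@dataclass
class TextVectors:
    """Row-aligned TF-IDF vectors plus the fitted vocabulary's identity."""

    matrix: np.ndarray  # dense, rows l2-normalised by the vectorizer
    vocab_id: str
    _vectorizer: TfidfVectorizer | None = field(default=None, repr=False)

    def transform(self, texts: Sequence[str]) -> np.ndarray:
        if self._vectorizer is None:
            raise ValueError("these vectors carry no fitted vectorizer")
        return np.asarray(self._vectorizer.transform(list(texts)).todense())


def vectorize(texts: Sequence[str]) -> TextVectors:
    """Deterministic lowercased word-unigram TF-IDF representation."""
    texts = list(texts)
    if not texts or all(not t.strip() for t in texts):
        raise ValueError("cannot vectorize an empty corpus")
    vec = TfidfVectorizer(lowercase=True)
    matrix = np.asarray(vec.fit_transform(texts).todense())
    vocab = sorted(vec.vocabulary_)
    vocab_id = hashlib.sha1("\x00".join(vocab).encode()).hexdigest()[:16]
    return TextVectors(matrix=matrix, vocab_id=vocab_id, _vectorizer=vec)


@dataclass
class ExemplarPool:
    """Annotated training sections with zero-shot error flags and vectors."""

    items: list[AnnotatedSection]
    zero_shot_error_flags: list[bool]
    vectors: TextVectors | None = None

    def __post_init__(self) -> None:
        if len(self.items) != len(self.zero_shot_error_flags):
            raise ValueError("error flags must align 1:1 with pool items")
        if self.vectors is not None and self.vectors.matrix.shape[0] != len(self.items):
            raise ValueError("vectors must align 1:1 with pool items")

    @classmethod
    def build(cls, items: list[AnnotatedSection], flags: list[bool] | None = None) -> "ExemplarPool":
        flags = [False] * len(items) if flags is None else list(flags)
        pool = cls(items, flags)
        pool.vectors = vectorize([it.section.text for it in items])
        return pool

    @classmethod
    def from_jsonl(cls, fh) -> "ExemplarPool":
        """Records: section fields + ``gold`` mapping + ``is_zero_shot_error``."""
        items, flags = [], []
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            items.append(AnnotatedSection(Section.from_dict(rec), LabelSet.from_dict(rec["gold"])))
            flags.append(bool(rec.get("is_zero_shot_error", False)))
        return cls.build(items, flags)

    def __len__(self) -> int:
        return len(self.items)


def select_random(pool: ExemplarPool, k: int = DEFAULT_SHOTS, seed: int = 0) -> list[AnnotatedSection]:
    """k distinct items, uniform without replacement, reproducible by seed."""
    if len(pool) < k:
        raise ValueError(f"pool has {len(pool)} items, cannot select {k}")
    idx = random.Random(seed).sample(range(len(pool)), k)
    return [pool.items[i] for i in idx]


def _require_vectors(pool: ExemplarPool) -> TextVectors:
    if pool.vectors is None:
        raise ValueError("pool has no text vectors; build it with ExemplarPool.build")
    return pool.vectors


def select_error_clusters(
    pool: ExemplarPool, k: int = DEFAULT_SHOTS, seed: int = 0
) -> list[AnnotatedSection]:
    """K-means error clustering: cluster the zero-shot error cases into k
    groups and take, per cluster, the real item nearest the centroid.

    With fewer than k error cases, all of them are returned plus a seeded
    random fill from the non-error pool. Ties go to the lowest item index.
    """
    vectors = _require_vectors(pool)
    err_idx = [i for i, f in enumerate(pool.zero_shot_error_flags) if f]
    if not err_idx:
        raise ValueError(
            "no zero-shot error cases in the pool; run a zero-shot pass and "
            "flag its errors before using error-cluster selection"
        )
    if len(err_idx) <= k:
        if len(err_idx) == k:
            return [pool.items[i] for i in err_idx]
        non_err = [i for i in range(len(pool)) if i not in set(err_idx)]
        fill_n = min(k - len(err_idx), len(non_err))
        fill = random.Random(seed).sample(non_err, fill_n)
        return [pool.items[i] for i in err_idx + fill]

    X = vectors.matrix[err_idx]
    km = KMeans(n_clusters=k, random_state=seed, n_init=10, max_iter=300, tol=1e-4)
    assignments = km.fit_predict(X)
    chosen: list[int] = []
    taken: set[int] = set()
    for c in range(k):
        members = [j for j, a in enumerate(assignments) if a == c and j not in taken]
        if not members:  # degenerate (duplicate points): take lowest unused error
            members = [j for j in range(len(err_idx)) if j not in taken]
        sims = cosine_similarity(X[members], km.cluster_centers_[c][None, :]).ravel()
        # nearest to centroid = highest cosine similarity; ties -> lowest index
        best = members[int(np.lexsort((members, -sims))[0])]
        taken.add(best)
        chosen.append(err_idx[best])
    return [pool.items[i] for i in chosen]


def select_nearest(
    pool: ExemplarPool, query: Section | str, k: int = DEFAULT_SHOTS
) -> list[AnnotatedSection]:
    """Top-k pool items by cosine similarity to the query, descending;
    ties broken by lowest item index. No randomness."""
    if len(pool) < k:
        raise ValueError(f"pool has {len(pool)} items, cannot select {k}")
    vectors = _require_vectors(pool)
    text = query.text if isinstance(query, Section) else query
    q = vectors.transform([text])
    sims = cosine_similarity(vectors.matrix, q).ravel()
    order = np.lexsort((np.arange(len(pool)), -sims))
    return [pool.items[int(i)] for i in order[:k]]


def selection_manifest(
    strategy: str, seed: int | None, chosen: list[AnnotatedSection]
) -> dict:
    """JSON-serialisable record of a selection, for reproducibility audits."""
    return {
        "strategy": strategy,
        "seed": seed,
        "section_ids": [c.section_id for c in chosen],
    }
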