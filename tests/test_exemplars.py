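"""Exemplar selection: TF-IDF vectors, the three strategies, determinism."""

import math

import numpy as np
import pytest

from mobex import AnnotatedSection, ExemplarPool, LabelSet
from mobex.exemplars import select_error_clusters, select_nearest, select_random, vectorize

from conftest import make_section


def build_pool(texts, flags=None):
    items = [
        AnnotatedSection(make_section(i, text=t), LabelSet.all_no_mention())
        for i, t in enumerate(texts)
    ]
    return ExemplarPool.build(items, flags)


def hand_tfidf_cosine(docs):
    """Independent brute-force TF-IDF (smoothed idf = ln((1+n)/(1+df)) + 1,
    raw counts, l2 norm) and its pairwise cosine matrix."""
    tokenised = [[w for w in d.lower().split() if len(w) > 1] for d in docs]
    vocab = sorted({w for doc in tokenised for w in doc})
    n = len(docs)
    df = {w: sum(w in doc for doc in tokenised) for w in vocab}
    idf = {w: math.log((1 + n) / (1 + df[w])) + 1 for w in vocab}
    rows = []
    for doc in tokenised:
        v = np.array([doc.count(w) * idf[w] for w in vocab], dtype=float)
        norm = np.linalg.norm(v)
        rows.append(v / norm if norm else v)
    X = np.array(rows)
    return X @ X.T


class TestVectorize:
    def test_identical_texts_similarity_one(self):
        vs = vectorize(["patient walks daily", "patient walks daily"])
        sim = float(vs.matrix[0] @ vs.matrix[1])
        assert sim == pytest.approx(1.0)

    def test_disjoint_vocabulary_similarity_zero(self):
        vs = vectorize(["alpha bravo charlie", "delta echo foxtrot"])
        assert float(vs.matrix[0] @ vs.matrix[1]) == pytest.approx(0.0)

    def test_matches_hand_computed_tfidf_on_tiny_corpus(self):
        docs = [
            "gait steady today",
            "gait unsteady with walker",
            "walker used for gait",
            "steady transfers today",
            "transfers need assist",
        ]
        vs = vectorize(docs)
        got = vs.matrix @ vs.matrix.T
        expected = hand_tfidf_cosine(docs)
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            vectorize([])


class TestSelectRandom:
    def test_pool_of_exactly_k_returns_everything(self):
        pool = build_pool([f"text number {i}" for i in range(5)])
        chosen = select_random(pool, k=5, seed=7)
        assert {c.section_id for c in chosen} == {it.section_id for it in pool.items}

    def test_seed_reproducibility(self):
        pool = build_pool([f"text number {i}" for i in range(20)])
        a = [c.section_id for c in select_random(pool, 5, seed=42)]
        b = [c.section_id for c in select_random(pool, 5, seed=42)]
        assert a == b

    def test_pool_too_small_rejected(self):
        pool = build_pool(["only text here"])
        with pytest.raises(ValueError, match="cannot select"):
            select_random(pool, k=5, seed=0)

    def test_uniform_inclusion_frequency(self):
        # each of 10 items should appear in a k=5 draw about half the time
        pool = build_pool([f"text number {i}" for i in range(10)])
        n_rep = 10_000
        hits = np.zeros(10)
        for rep in range(n_rep):
            for c in select_random(pool, 5, seed=rep):
                hits[int(c.section_id[1:])] += 1
        freq = hits / n_rep
        se = math.sqrt(0.5 * 0.5 / n_rep)
        assert np.all(np.abs(freq - 0.5) < 3 * se)


class TestSelectErrorClusters:
    def test_exactly_k_errors_all_returned(self):
        words = ["ambulation", "transfers", "stairs", "driving", "carrying", "balance", "endurance", "posture"]
        texts = [f"note about {words[i]} and {words[i]} status" for i in range(8)]
        flags = [i < 5 for i in range(8)]
        pool = build_pool(texts, flags)
        chosen = select_error_clusters(pool, k=5, seed=0)
        assert sorted(c.section_id for c in chosen) == [f"s{i:04d}" for i in range(5)]

    def test_duplicated_errors_collapse_to_distinct_texts(self):
        # 5 well-separated error texts duplicated 10x each: k-means must pick
        # exactly the 5 distinct texts (one representative per cluster)
        base = [
            "alpha alpha alpha", "bravo bravo bravo", "charlie charlie charlie",
            "delta delta delta", "echo echo echo",
        ]
        texts = [t for t in base for _ in range(10)]
        pool = build_pool(texts, [True] * len(texts))
        chosen = select_error_clusters(pool, k=5, seed=1)
        assert sorted(c.section.text for c in chosen) == sorted(base)

    def test_fewer_errors_than_k_filled_from_non_errors(self):
        texts = [f"sample text number {i}" for i in range(10)]
        flags = [i < 3 for i in range(10)]
        pool = build_pool(texts, flags)
        chosen = select_error_clusters(pool, k=5, seed=3)
        ids = [c.section_id for c in chosen]
        assert len(ids) == 5 and len(set(ids)) == 5
        assert set(ids[:3]) == {"s0000", "s0001", "s0002"}

    def test_no_errors_is_actionable_error(self):
        pool = build_pool(["text one here", "text two here"], [False, False])
        with pytest.raises(ValueError, match="zero-shot"):
            select_error_clusters(pool, k=1, seed=0)

    def test_byte_identical_across_reruns(self):
        texts = [f"varied clinical sample {i} with words {i % 3}" for i in range(30)]
        flags = [i % 2 == 0 for i in range(30)]
        pool = build_pool(texts, flags)
        a = [c.section_id for c in select_error_clusters(pool, 5, seed=11)]
        b = [c.section_id for c in select_error_clusters(pool, 5, seed=11)]
        assert a == b
        assert all(pool.zero_shot_error_flags[int(i[1:])] for i in a)


class TestSelectNearest:
    def test_exact_duplicate_ranked_first(self):
        texts = ["walks with cane", "uses wheelchair daily", "independent transfers"]
        pool = build_pool(texts)
        chosen = select_nearest(pool, "walks with cane", k=2)
        assert chosen[0].section_id == "s0000"

    def test_hand_computed_ranking(self):
        docs = [
            "gait steady today",
            "gait unsteady with walker",
            "walker used for gait",
            "steady transfers today",
            "transfers need assist",
            "unrelated cardiology words",
        ]
        pool = build_pool(docs)
        query = "gait steady with walker"
        qv = pool.vectors.transform([query])[0]
        sims = pool.vectors.matrix @ qv
        expected = [f"s{i:04d}" for i in np.lexsort((np.arange(6), -sims))[:3]]
        got = [c.section_id for c in select_nearest(pool, query, k=3)]
        assert got == expected

    def test_deterministic_no_randomness(self):
        pool = build_pool([f"some words {i} appear here" for i in range(12)])
        a = [c.section_id for c in select_nearest(pool, "some words appear", 5)]
        b = [c.section_id for c in select_nearest(pool, "some words appear", 5)]
        assert a == b


class TestCommonContracts:
    @pytest.mark.parametrize("strategy", ["random", "kmeans", "nearest"])
    def test_k_distinct_items_from_pool(self, strategy):
        texts = [f"clinical sample number {i} variant {i % 4}" for i in range(25)]
        pool = build_pool(texts, [i % 3 == 0 for i in range(25)])
        if strategy == "random":
            chosen = select_random(pool, 5, seed=2)
        elif strategy == "kmeans":
            chosen = select_error_clusters(pool, 5, seed=2)
        else:
            chosen = select_nearest(pool, "clinical sample variant", 5)
        ids = [c.section_id for c in chosen]
        assert len(ids) == 5 and len(set(ids)) == 5
        pool_ids = {it.section_id for it in pool.items}
        assert set(ids) <= pool_ids
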