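"""Shared fixtures and independent reference implementations.

The reference implementations here (positional pair enumerator, set-based
similarity) are deliberately naive O(n²) code paths kept independent of the
production modules, used as oracles in equivalence tests.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

from gold.corpus import CleanCorpus, RawCorpus, compute_stats, preprocess
from gold.graph import CooccurrenceGraph, build_graph


def make_clean(paragraphs: list[list[str]]) -> CleanCorpus:
    """Wrap explicit token lists as a CleanCorpus without filtering."""
    vocab = {t for p in paragraphs for t in p}
    return CleanCorpus(paragraphs=paragraphs, vocabulary=vocab)


def naive_pair_counts(paragraphs, window):
    """O(n²) positional-pair enumerator: the graph-builder oracle."""
    counts = Counter()
    for para in paragraphs:
        n = len(para)
        if n < 2:
            continue
        for i in range(n):
            for j in range(i + 1, n):
                if window != "paragraph" and j - i > window:
                    continue
                a, b = para[i], para[j]
                if a == b:
                    continue
                counts[(min(a, b), max(a, b))] += 1
    return dict(counts)


def graph_edge_dict(g: CooccurrenceGraph) -> dict:
    return {(u, v): w for u, v, w in g.edges()}


def naive_similarity(g, w1, w2, method, norm):
    """Set-and-sum reference for the five similarity methods."""
    s = g.stats

    def nval(u, v, w):
        from gold.normalize import NormalizationDomainError, normalized_value

        v_ = normalized_value(
            w, s.f[u], s.f[v], s.df[u], s.df[v], s.idf[u], s.idf[v], g.n_docs, norm
        )
        return max(v_, 0.0)

    nb1 = {n: w for n, w in g.neighbors(w1).items() if n not in (w1, w2)}
    nb2 = {n: w for n, w in g.neighbors(w2).items() if n not in (w1, w2)}
    vo = sorted(set(nb1) & set(nb2))
    vn1 = sorted(set(nb1) - set(nb2))
    vn2 = sorted(set(nb2) - set(nb1))

    ov_pairs = [(nval(w1, n, nb1[n]), nval(w2, n, nb2[n])) for n in vo]
    non = sum(nval(w1, n, nb1[n]) for n in vn1) + sum(nval(w2, n, nb2[n]) for n in vn2)

    def scale(a, b):
        if a <= 0 or b <= 0:
            return 0.0
        return (a + b) / (max(a, b) / min(a, b))

    if method in (1, 2):
        overlap = sum(a + b for a, b in ov_pairs)
    else:
        overlap = sum(scale(a, b) for a, b in ov_pairs)

    if method == 5:
        return overlap / len(vo) if vo else 0.0
    if method in (2, 4):
        overlap = overlap / len(vo) if vo else 0.0
        nn = len(vn1) + len(vn2)
        non = non / nn if nn else 0.0
    total = overlap + non
    if total == 0:
        return 0.0
    return (overlap - non) / total


def random_corpus(rng: np.random.Generator, max_paragraphs=50, max_len=10, vocab=None):
    """Small random corpus for oracle-equivalence tests."""
    vocab = vocab or [f"t{i}" for i in range(12)]
    n_para = int(rng.integers(1, max_paragraphs + 1))
    paragraphs = []
    for _ in range(n_para):
        L = int(rng.integers(1, max_len + 1))
        paragraphs.append([vocab[i] for i in rng.integers(0, len(vocab), size=L)])
    return make_clean(paragraphs)


def random_graph(rng: np.random.Generator, max_nodes=30) -> CooccurrenceGraph:
    """Random small graph with self-consistent corpus statistics."""
    n_types = int(rng.integers(4, max_nodes + 1))
    vocab = [f"t{i}" for i in range(n_types)]
    while True:
        clean = random_corpus(rng, max_paragraphs=25, max_len=8, vocab=vocab)
        if len(clean.vocabulary) >= 2:
            return build_graph(clean, "paragraph")


@pytest.fixture
def toy_graph() -> CooccurrenceGraph:
    """5-node graph: edges a–c, b–c, a–d, b–e (for pair (a, b): Vo={c})."""
    clean = make_clean([["a", "c"], ["b", "c"], ["a", "d"], ["b", "e"]] * 2)
    return build_graph(clean, "paragraph")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
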