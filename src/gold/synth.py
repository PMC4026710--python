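"""Synthetic paragraph corpora with planted word-pair relations.

The generator emulates the statistical shape of a cleaned web-forum corpus
— Zipf-distributed type frequencies and short, skewed paragraph lengths
(mean ≈ 10.5, median ≈ 7 tokens) — and plants labeled word pairs of three
relation types on top of a topic-mixture base text:

* **associated** pairs are co-inserted into the same paragraphs (adjacent
  positions), drawn from *different* topics, so they acquire a strong
  direct edge but little shared context;
* **similar** pairs are synonyms of one topic: each word is inserted into
  its own disjoint set of paragraphs of that topic, so they share context
  (overlap) while direct co-occurrence is suppressed exactly — planted
  words never appear outside their insertions;
* **both** pairs get both mechanisms (half the insertions joint, half
  separate within the shared topic);
* **unrelated** pairs are sampled from the base vocabulary across topics.

The planted words live outside the Zipf base sample, so every structural
property above is a construction guarantee, not a probabilistic one.
Regeneration from the same (spec, seed) is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .corpus import RawCorpus

__all__ = ["SynthSpec", "SynthCorpusBundle", "generate"]


@dataclass(frozen=True)
class SynthSpec:
    """Generation parameters.

    Defaults describe the reference desk-scale corpus: 500 base types over
    10 topics, 200 paragraphs with lognormal lengths matching a cleaned
    forum corpus (mean ≈ 10.5, median ≈ 7), Zipf exponent 1.0, and 20
    planted pairs per relation class at strength 0.8.
    """

    vocab_size: int = 500
    n_topics: int = 10
    n_paragraphs: int = 200
    mean_paragraph_len: float = 10.5
    median_paragraph_len: float = 7.0
    zipf_exponent: float = 1.0
    n_pairs_per_class: int = 20
    n_unrelated_pairs: int = 20
    strength: float = 0.8
    background_mix: float = 0.2  # probability a token is drawn corpus-wide

    def __post_init__(self):
        if not (0 < self.strength <= 1):
            raise ValueError("strength must be in (0, 1]")
        if self.mean_paragraph_len <= self.median_paragraph_len:
            raise ValueError("mean paragraph length must exceed the median")
        if self.n_topics < 2:
            raise ValueError("need at least 2 topics")
        if self.vocab_size < 2 * self.n_topics:
            raise ValueError("vocabulary too small for the topic count")
        need = 2 * self.n_unrelated_pairs
        if self.vocab_size < need:
            raise ValueError(
                f"vocabulary size {self.vocab_size} cannot host "
                f"{self.n_unrelated_pairs} unrelated pairs"
            )


@dataclass
class SynthCorpusBundle:
    """Generated corpus + ground-truth labels + provenance log."""

    raw: RawCorpus
    pairs: pd.DataFrame  # columns: word1, word2, label
    log: dict = field(default_factory=dict)


def _paragraph_lengths(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    # lognormal parameterized from the target median and mean
    mu = math.log(spec.median_paragraph_len)
    sigma = math.sqrt(2 * math.log(spec.mean_paragraph_len / spec.median_paragraph_len))
    lens = np.rint(rng.lognormal(mu, sigma, size=spec.n_paragraphs)).astype(int)
    return np.clip(lens, 1, None)


def _insertions_per_word(spec: SynthSpec) -> int:
    # how many paragraphs each planted word is inserted into
    return max(2, round(spec.strength * 12))


def _alpha(i: int, width: int = 3) -> str:
    # purely alphabetic index so tokens survive any text round-trip
    s = ""
    for _ in range(width):
        s = chr(ord("a") + i % 26) + s
        i //= 26
    return s


def generate(spec: SynthSpec, seed: int = 0) -> SynthCorpusBundle:
    """Draw one corpus bundle; bit-identical for identical (spec, seed)."""
    rng = np.random.default_rng(seed)

    base = [f"w{_alpha(i)}" for i in range(spec.vocab_size)]
    topic_of = {w: i % spec.n_topics for i, w in enumerate(base)}
    topics = [[w for w in base if topic_of[w] == t] for t in range(spec.n_topics)]

    # Zipf weights over base vocabulary (rank = index)
    zipf = 1.0 / np.arange(1, spec.vocab_size + 1) ** spec.zipf_exponent
    p_global = zipf / zipf.sum()
    base_index = {w: i for i, w in enumerate(base)}
    p_topic = []
    for t in range(spec.n_topics):
        ids = np.array([base_index[w] for w in topics[t]])
        pw = zipf[ids] / zipf[ids].sum()
        p_topic.append((ids, pw))

    lens = _paragraph_lengths(spec, rng)
    para_topic = rng.integers(0, spec.n_topics, size=spec.n_paragraphs)
    paragraphs: list[list[str]] = []
    for L, t in zip(lens, para_topic):
        ids, pw = p_topic[t]
        use_bg = rng.random(L) < spec.background_mix
        tok_ids = np.where(
            use_bg,
            rng.choice(spec.vocab_size, size=L, p=p_global),
            rng.choice(ids, size=L, p=pw),
        )
        paragraphs.append([base[i] for i in tok_ids])

    occ = _insertions_per_word(spec)
    pairs_rows: list[dict] = []
    by_topic = [
        [i for i in range(spec.n_paragraphs) if para_topic[i] == t]
        for t in range(spec.n_topics)
    ]

    def insert(pi: int, tokens: list[str]) -> None:
        pos = int(rng.integers(0, len(paragraphs[pi]) + 1))
        paragraphs[pi][pos:pos] = tokens

    k = 0  # planted-word counter
    for j in range(spec.n_pairs_per_class):
        w1, w2 = f"assoc{_alpha(k)}a", f"assoc{_alpha(k)}b"
        k += 1
        # co-insert into occ random paragraphs, adjacent, any topic
        chosen = rng.choice(spec.n_paragraphs, size=occ, replace=False)
        for pi in chosen:
            insert(int(pi), [w1, w2])
        pairs_rows.append({"word1": w1, "word2": w2, "label": "associated"})

    for j in range(spec.n_pairs_per_class):
        w1, w2 = f"simil{_alpha(k)}a", f"simil{_alpha(k)}b"
        k += 1
        t = j % spec.n_topics
        pool = by_topic[t]
        take = min(2 * occ, len(pool))
        chosen = rng.choice(pool, size=take, replace=False)
        half = take // 2
        for pi in chosen[:half]:
            insert(int(pi), [w1])
        for pi in chosen[half:]:
            insert(int(pi), [w2])
        pairs_rows.append({"word1": w1, "word2": w2, "label": "similar"})

    for j in range(spec.n_pairs_per_class):
        w1, w2 = f"bothp{_alpha(k)}a", f"bothp{_alpha(k)}b"
        k += 1
        t = j % spec.n_topics
        pool = by_topic[t]
        n_joint = max(1, occ // 2)
        n_sep = occ - n_joint
        take = min(n_joint + 2 * n_sep, len(pool))
        chosen = rng.choice(pool, size=take, replace=False)
        for pi in chosen[:n_joint]:
            insert(int(pi), [w1, w2])
        rest = chosen[n_joint:]
        half = len(rest) // 2
        for pi in rest[:half]:
            insert(int(pi), [w1])
        for pi in rest[half:]:
            insert(int(pi), [w2])
        pairs_rows.append({"word1": w1, "word2": w2, "label": "both"})

    # unrelated pairs: base words from different topics that occur >= 2
    # times in the realized corpus, so they survive hapax removal
    counts: dict[str, int] = {}
    for p in paragraphs:
        for t in p:
            counts[t] = counts.get(t, 0) + 1
    candidates = [w for w in base[: 8 * spec.n_unrelated_pairs] if counts.get(w, 0) >= 2]
    perm = rng.permutation(len(candidates))
    used: set[str] = set()
    for i in range(0, len(perm) - 1):
        if len([r for r in pairs_rows if r["label"] == "unrelated"]) >= spec.n_unrelated_pairs:
            break
        a, b = candidates[perm[i]], candidates[perm[(i + 1) % len(perm)]]
        if a in used or b in used or topic_of[a] == topic_of[b]:
            continue
        used.update((a, b))
        pairs_rows.append({"word1": a, "word2": b, "label": "unrelated"})

    pairs = pd.DataFrame(pairs_rows, columns=["word1", "word2", "label"])
    raw = RawCorpus(documents=[paragraphs])
    return SynthCorpusBundle(
        raw=raw, pairs=pairs, log={"seed": seed, "spec": asdict(spec)}
    )
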