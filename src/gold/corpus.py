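"""Corpus parsing, cleaning, and per-type statistics.

A corpus is an ordered list of documents, each an ordered list of paragraphs,
each an ordered list of lowercase token strings.  The *paragraph* is the
fundamental context unit throughout the package: it is the co-occurrence
window of the paragraph-mode graph and the "document" over which document
frequency (and hence IDF and PMI) is counted.

Cleaning applies three filters, in a fixed order:

1. stoplist removal — closed-class function words are dropped;
2. wordlist filtering (optional) — token types absent from a dictionary
   wordlist are dropped, removing typos and non-words;
3. hapax removal — types whose corpus-wide frequency (counted *after* the
   first two filters) falls below ``min_count`` (default 2) are dropped in a
   single pass.

Removing a type never changes the counts of other types, so a second
application of :func:`preprocess` with the same lists is a no-op.
"""

from __future__ import annotations

import json
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "RawCorpus",
    "CleanCorpus",
    "CorpusStats",
    "EmptyVocabularyError",
    "tokenize",
    "preprocess",
    "compute_stats",
    "default_stoplist",
    "load_wordfile",
    "read_corpus_file",
    "write_clean_corpus",
    "read_clean_corpus",
]

# Lowercase alphabetic runs, keeping internal apostrophes ("don't" -> don't).
_TOKEN_RE = re.compile(r"[a-z]+(?:'[a-z]+)*")


class EmptyVocabularyError(ValueError):
    """Raised when preprocessing leaves no vocabulary at all."""


@dataclass
class RawCorpus:
    """Tokenized corpus before any filtering.

    ``documents[d][p]`` is the token list of paragraph ``p`` of document
    ``d``; both orderings are preserved from the source text.
    """

    documents: list[list[list[str]]] = field(default_factory=list)

    @property
    def paragraphs(self) -> list[list[str]]:
        """All paragraphs in corpus order, ignoring document boundaries."""
        return [p for doc in self.documents for p in doc]

    @property
    def n_tokens(self) -> int:
        return sum(len(p) for doc in self.documents for p in doc)


@dataclass
class CleanCorpus:
    """Filtered corpus: flat paragraph list plus the retained vocabulary.

    ``removal_log`` maps each filter stage to ``{"tokens": n, "types": n}``;
    token counts across stages plus retained tokens reconstruct the input
    token count exactly.
    """

    paragraphs: list[list[str]]
    vocabulary: set[str]
    removal_log: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def n_tokens(self) -> int:
        return sum(len(p) for p in self.paragraphs)

    @property
    def singleton_paragraphs(self) -> list[int]:
        """Indices of length-1 paragraphs (kept here, skipped by the graph)."""
        return [i for i, p in enumerate(self.paragraphs) if len(p) == 1]


@dataclass
class CorpusStats:
    """Per-type token frequency f, document frequency df, and idf.

    ``n_docs`` is the number of paragraphs — the "document" unit for df and
    PMI.  ``idf(w) = log10(n_docs / df(w))``, so a type present in every
    paragraph has idf 0.
    """

    n_docs: int
    f: dict[str, int]
    df: dict[str, int]
    idf: dict[str, float]


def tokenize(raw_text: str, paragraph_delimiter: str = r"\n\s*\n") -> RawCorpus:
    """Split text into one document of paragraphs of lowercase tokens.

    Paragraph boundaries are matches of the ``paragraph_delimiter`` regex
    (default: blank line).  Tokens are maximal lowercase alphabetic runs with
    internal apostrophes kept; everything else is stripped.  Empty paragraphs
    are dropped.

    Parameters
    ----------
    raw_text:
        Decoded text.  (Byte input must be decoded by the caller; file
        readers in this module report the offending byte offset on failure.)
    paragraph_delimiter:
        Regular expression marking paragraph breaks.
    """
    paragraphs = []
    for chunk in re.split(paragraph_delimiter, raw_text):
        tokens = _TOKEN_RE.findall(chunk.lower())
        if tokens:
            paragraphs.append(tokens)
    return RawCorpus(documents=[paragraphs] if paragraphs else [])


def default_stoplist() -> set[str]:
    """The bundled 127-word English function-word stoplist."""
    text = resources.files("gold.data").joinpath("stoplist_en.txt").read_text("utf-8")
    return {w for w in text.split() if w}


def load_wordfile(path: str | Path) -> set[str]:
    """Read a one-word-per-line file (stoplist or dictionary wordlist)."""
    p = Path(path)
    try:
        text = p.read_text("utf-8")
    except UnicodeDecodeError as e:  # pragma: no cover - depends on input file
        raise ValueError(
            f"{p}: cannot decode as UTF-8 at byte offset {e.start}"
        ) from e
    return {line.strip().lower() for line in text.splitlines() if line.strip()}


def preprocess(
    raw: RawCorpus,
    stoplist: Iterable[str],
    wordlist: Iterable[str] | None = None,
    min_count: int = 2,
) -> CleanCorpus:
    """Apply stoplist → wordlist → hapax filtering, in that order.

    Hapax removal is a single pass over frequencies counted on the
    post-wordlist corpus: types with frequency < ``min_count`` are dropped.
    Because removing one type never alters another type's count, no
    cascading re-check is needed and the operation is idempotent.

    Length-1 paragraphs are retained (see
    :attr:`CleanCorpus.singleton_paragraphs`); the graph builder ignores
    them.

    Raises
    ------
    EmptyVocabularyError
        If no types survive all three filters.
    """
    stopset = {w.lower() for w in stoplist}
    wordset = {w.lower() for w in wordlist} if wordlist is not None else None

    log: dict[str, dict[str, int]] = {}
    paragraphs = raw.paragraphs

    def _filter(paras, keep, stage):
        kept, removed_tokens, removed_types = [], 0, set()
        for p in paras:
            q = []
            for t in p:
                if keep(t):
                    q.append(t)
                else:
                    removed_tokens += 1
                    removed_types.add(t)
            if q:
                kept.append(q)
        log[stage] = {"tokens": removed_tokens, "types": len(removed_types)}
        return kept

    paragraphs = _filter(paragraphs, lambda t: t not in stopset, "stoplist")
    if wordset is not None:
        paragraphs = _filter(paragraphs, lambda t: t in wordset, "wordlist")
    else:
        log["wordlist"] = {"tokens": 0, "types": 0}

    counts = Counter(t for p in paragraphs for t in p)
    rare = {w for w, c in counts.items() if c < min_count}
    paragraphs = _filter(paragraphs, lambda t: t not in rare, "hapax")

    vocabulary = {t for p in paragraphs for t in p}
    if not vocabulary:
        raise EmptyVocabularyError(
            "no vocabulary remains after stoplist/wordlist/hapax filtering"
        )
    return CleanCorpus(paragraphs=paragraphs, vocabulary=vocabulary, removal_log=log)


def compute_stats(clean: CleanCorpus) -> CorpusStats:
    """Token frequency, paragraph-level document frequency, and idf.

    ``n_docs`` counts every paragraph in the cleaned corpus, including
    length-1 paragraphs (which carry df information even though they
    contribute no edges).
    """
    if not clean.paragraphs:
        raise ValueError("cannot compute statistics of an empty corpus")
    f: Counter[str] = Counter()
    df: Counter[str] = Counter()
    for p in clean.paragraphs:
        f.update(p)
        df.update(set(p))
    n_docs = len(clean.paragraphs)
    idf = {w: math.log10(n_docs / d) for w, d in df.items()}
    return CorpusStats(n_docs=n_docs, f=dict(f), df=dict(df), idf=idf)


# ---------------------------------------------------------------------------
# file I/O


def read_corpus_file(path: str | Path, paragraph_delimiter: str = r"\n\s*\n") -> RawCorpus:
    """Read a corpus from UTF-8 plain text or JSON-lines.

    JSON-lines records look like ``{"doc_id": ..., "paragraphs": [...]}``,
    one document per line; anything else is treated as plain text with the
    given paragraph delimiter.
    """
    p = Path(path)
    data = p.read_bytes()
    try:
        text = data.decode("utf-8")
    except UnicodeDecodeError as e:
        raise ValueError(f"{p}: cannot decode as UTF-8 at byte offset {e.start}") from e
    stripped = text.lstrip()
    if stripped.startswith("{"):
        documents = []
        for i, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as e:
                raise ValueError(f"{p}:{i}: invalid JSON record: {e}") from e
            doc = []
            for para in rec["paragraphs"]:
                if isinstance(para, list):  # pre-tokenized record
                    tokens = [str(t).lower() for t in para]
                else:
                    tokens = _TOKEN_RE.findall(str(para).lower())
                if tokens:
                    doc.append(tokens)
            documents.append(doc)
        return RawCorpus(documents=documents)
    return tokenize(text, paragraph_delimiter)


def write_clean_corpus(clean: CleanCorpus, path: str | Path) -> None:
    """Serialize as JSON-lines: one token array per paragraph."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in clean.paragraphs:
            fh.write(json.dumps(p) + "\n")


def read_clean_corpus(path: str | Path) -> CleanCorpus:
    paragraphs = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                paragraphs.append([str(t) for t in json.loads(line)])
            except json.JSONDecodeError as e:
                raise ValueError(f"{path}:{i}: invalid JSON: {e}") from e
    vocab = {t for p in paragraphs for t in p}
    if not vocab:
        raise EmptyVocabularyError(f"{path}: empty corpus")
    return CleanCorpus(paragraphs=paragraphs, vocabulary=vocab)
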