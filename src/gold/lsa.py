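"""Latent semantic analysis baseline.

A term-by-paragraph count matrix over the cleaned corpus is factored by
truncated SVD; word vectors are the left singular vectors scaled by the
singular values (so dot products approximate term-term co-occurrence
structure), and word pairs are scored by cosine.  The default
dimensionality is 300, configurable down for small corpora and tests.

Raw counts are used by default; a log-entropy transform is available via
``weighting="log_entropy"`` for users who want the classical LSA weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds

from .corpus import CleanCorpus

__all__ = ["LsaSpace", "RankError", "fit_lsa", "lsa_cosine", "lsa_feature_table"]

_DENSE_LIMIT = 400  # below this min-dimension, use exact LAPACK SVD


class RankError(ValueError):
    """Requested dimensionality exceeds the matrix rank."""


@dataclass
class LsaSpace:
    """k-dimensional latent space: one row of ``vectors`` per vocabulary word."""

    vocabulary: list[str]
    vectors: np.ndarray  # shape (n_words, k)
    singular_values: np.ndarray
    index: dict[str, int]

    @property
    def k(self) -> int:
        return self.vectors.shape[1]


def _count_matrix(clean: CleanCorpus) -> tuple[sp.csr_matrix, list[str]]:
    vocab = sorted(clean.vocabulary)
    index = {w: i for i, w in enumerate(vocab)}
    rows, cols, data = [], [], []
    for j, para in enumerate(clean.paragraphs):
        for t in para:
            rows.append(index[t])
            cols.append(j)
            data.append(1.0)
    M = sp.coo_matrix(
        (data, (rows, cols)), shape=(len(vocab), len(clean.paragraphs))
    ).tocsr()
    M.sum_duplicates()
    return M, vocab


def _log_entropy(M: sp.csr_matrix) -> sp.csr_matrix:
    n_docs = M.shape[1]
    gf = np.asarray(M.sum(axis=1)).ravel()
    H = np.zeros(M.shape[0])
    C = M.tocoo()
    p = C.data / gf[C.row]
    np.add.at(H, C.row, p * np.log(p))
    g = 1.0 + H / np.log(n_docs) if n_docs > 1 else np.ones(M.shape[0])
    out = M.tocoo()
    out.data = g[out.row] * np.log1p(out.data)
    return out.tocsr()


def fit_lsa(clean: CleanCorpus, k: int = 300, weighting: str = "raw") -> LsaSpace:
    """Fit the latent space from the term-by-paragraph count matrix.

    Raises
    ------
    RankError
        If ``k`` exceeds the (numerical) rank of the matrix.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    M, vocab = _count_matrix(clean)
    if weighting == "log_entropy":
        M = _log_entropy(M)
    elif weighting != "raw":
        raise ValueError(f"unknown weighting: {weighting!r}")

    min_dim = min(M.shape)
    if k > min_dim:
        raise RankError(f"k={k} exceeds min(matrix shape)={min_dim}")

    if min_dim <= _DENSE_LIMIT:
        U, s, _ = np.linalg.svd(M.toarray(), full_matrices=False)
        tol = max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
        rank = int((s > tol).sum())
        if k > rank:
            raise RankError(f"k={k} exceeds matrix rank {rank}")
        U, s = U[:, :k], s[:k]
    else:
        if k >= min_dim:
            raise RankError(f"k={k} must be < min(matrix shape)={min_dim} for sparse SVD")
        U, s, _ = svds(M, k=k, v0=np.ones(min(M.shape)))
        order = np.argsort(s)[::-1]
        U, s = U[:, order], s[order]
        if s[-1] <= max(M.shape) * np.finfo(float).eps * s[0]:
            raise RankError(f"k={k} exceeds numerical rank of the matrix")

    vectors = U * s
    return LsaSpace(
        vocabulary=vocab,
        vectors=vectors,
        singular_values=s,
        index={w: i for i, w in enumerate(vocab)},
    )


def lsa_cosine(space: LsaSpace, word1: str, word2: str) -> float:
    """Cosine of the two word vectors, in [−1, 1]; 0 (with a warning) for a
    numerically zero vector."""
    for w in (word1, word2):
        if w not in space.index:
            raise KeyError(f"word not in LSA vocabulary: {w!r}")
    u = space.vectors[space.index[word1]]
    v = space.vectors[space.index[word2]]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        warnings.warn(f"zero LSA vector for {word1!r} or {word2!r}; cosine set to 0")
        return 0.0
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def lsa_feature_table(space: LsaSpace, pairs: list[tuple[str, str]]):
    """One-column cosine feature table, protocol-compatible."""
    import pandas as pd

    idx = pd.MultiIndex.from_tuples(pairs, names=["word1", "word2"])
    return pd.DataFrame(
        {"lsa_cosine": [lsa_cosine(space, a, b) for a, b in pairs]}, index=idx
    )


def save_space(space: LsaSpace, out_dir: str | Path) -> None:
    """Persist vectors (text matrix) + vocabulary index."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "vectors.tsv", space.vectors, delimiter="\t")
    np.savetxt(out / "singular_values.tsv", space.singular_values, delimiter="\t")
    (out / "vocabulary.txt").write_text("\n".join(space.vocabulary) + "\n", "utf-8")


def load_space(in_dir: str | Path) -> LsaSpace:
    src = Path(in_dir)
    vectors = np.atleast_2d(np.loadtxt(src / "vectors.tsv", delimiter="\t"))
    s = np.atleast_1d(np.loadtxt(src / "singular_values.tsv", delimiter="\t"))
    vocab = (src / "vocabulary.txt").read_text("utf-8").split()
    return LsaSpace(
        vocabulary=vocab,
        vectors=vectors,
        singular_values=s,
        index={w: i for i, w in enumerate(vocab)},
    )
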