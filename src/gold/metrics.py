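"""Word-pair association and similarity metrics.

Association is carried by the *direct* edge between the two words — how
often they co-occur — either as the normalized raw weight or as pointwise
mutual information:

    PMI = log10(w · n_docs / (df1 · df2))

Similarity is carried by the two words' *shared context*: their neighbor
sets are decomposed into the overlap set Vo (nodes adjacent to both) and
the non-overlap sets Vn1/Vn2 (nodes adjacent to exactly one), and five
methods compare summed edge weights to the two regions:

* Method 1 — (overlap − nonoverlap) / total, in [−1, 1];
* Method 2 — as Method 1 with each sum divided by its set size (|Vo|, and
  the joint |Vn| = |Vn1| + |Vn2|);
* Method 3 — overlap weights first pass through the magnitude-difference
  transform (w1+w2)/(max/min), which rewards balanced weight pairs; the
  rest as Method 1;
* Method 4 — magnitude-scaled overlap, both sums size-normalized;
* Method 5 — magnitude-scaled overlap mean only, ≥ 0, unbounded above.

Every metric exists in 15 normalization flavours (see
:mod:`gold.normalize`), giving 30 association + 75 similarity = 105 named
features per word pair.

Composition conventions (the pair counts above require them):

* ``assoc`` with calc ``raw``: the normalization is applied to the direct
  edge weight — under scheme 2 this *is* the PMI of the edge.
* ``assoc`` with calc ``pmi``: PMI is computed from the raw weight, then the
  scheme's multiplicative frequency factor rescales the PMI value.  Scheme 2
  has no such factor (it is the PMI transform itself), so ``assoc_pmi_n02``
  equals plain PMI (= ``assoc_pmi_n01``).  Both names are kept so that the
  2 × 15 feature grid is complete.
* inside similarity sums each per-node weight is normalized with its own
  edge's endpoint statistics, then floored at 0: scheme 2 can go negative
  on small corpora, and a negative "weight" has no place in a proportion —
  a sub-chance edge simply contributes no evidence.  A floored-to-zero
  overlap weight contributes 0 to the magnitude-scaled sum (the magnitude
  ratio is undefined at zero).

Absent-edge sentinels: direct-weight association of a missing edge is 0
("no relationship"); PMI of a missing edge is −10 with the feature's mask
bit set.  A pair with no weight anywhere (isolated words) gets similarity 0
with the mask bit set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .graph import CooccurrenceGraph
from .normalize import (
    NormalizationDomainError,
    frequency_factor,
    normalized_value,
)

__all__ = [
    "OverlapDecomposition",
    "PairFeatureVector",
    "MissingWordError",
    "PMI_SENTINEL",
    "FEATURE_NAMES",
    "ASSOCIATION_FEATURES",
    "SIMILARITY_FEATURES",
    "decompose",
    "pmi",
    "association_metric",
    "magnitude_scale",
    "similarity",
    "feature_vector",
    "feature_table",
]

PMI_SENTINEL = -10.0

ASSOCIATION_FEATURES = [
    f"assoc_{calc}_n{m:02d}" for calc in ("raw", "pmi") for m in range(1, 16)
]
SIMILARITY_FEATURES = [
    f"sim_m{k}_n{m:02d}" for k in range(1, 6) for m in range(1, 16)
]
#: Stable, enumerable order of the 105 feature names (30 assoc + 75 sim).
FEATURE_NAMES = ASSOCIATION_FEATURES + SIMILARITY_FEATURES


class MissingWordError(KeyError):
    """A queried word is not in the graph vocabulary."""

    def __init__(self, word: str):
        super().__init__(word)
        self.word = word

    def __str__(self) -> str:
        return f"word not in graph vocabulary: {self.word!r}"


@dataclass
class OverlapDecomposition:
    """Neighborhood decomposition of a word pair.

    ``vo`` maps each overlap node to its raw weight pair (w1n, w2n);
    ``vn1``/``vn2`` map each exclusive neighbor to its single raw weight.
    The endpoints themselves are excluded from all three sets.
    """

    word1: str
    word2: str
    vo: dict[str, tuple[int, int]] = field(default_factory=dict)
    vn1: dict[str, int] = field(default_factory=dict)
    vn2: dict[str, int] = field(default_factory=dict)

    @property
    def n_overlap(self) -> int:
        return len(self.vo)

    @property
    def n_nonoverlap(self) -> int:
        return len(self.vn1) + len(self.vn2)


def _require(graph: CooccurrenceGraph, word: str) -> None:
    if word not in graph.stats.f:
        raise MissingWordError(word)


def decompose(graph: CooccurrenceGraph, word1: str, word2: str) -> OverlapDecomposition:
    """Split the two words' neighborhoods into overlap / exclusive sets."""
    _require(graph, word1)
    _require(graph, word2)
    nb1 = graph.neighbors(word1)
    nb2 = graph.neighbors(word2)
    exclude = {word1, word2}
    vo, vn1, vn2 = {}, {}, {}
    for n, w1n in nb1.items():
        if n in exclude:
            continue
        if n in nb2:
            vo[n] = (w1n, nb2[n])
        else:
            vn1[n] = w1n
    for n, w2n in nb2.items():
        if n in exclude or n in nb1:
            continue
        vn2[n] = w2n
    return OverlapDecomposition(word1=word1, word2=word2, vo=vo, vn1=vn1, vn2=vn2)


def pmi(graph: CooccurrenceGraph, word1: str, word2: str) -> float:
    """PMI of the direct edge; ``PMI_SENTINEL`` (−10) when there is none."""
    _require(graph, word1)
    _require(graph, word2)
    w = graph.edge_weight(word1, word2)
    if w == 0:
        return PMI_SENTINEL
    s = graph.stats
    return math.log10(w * graph.n_docs / (s.df[word1] * s.df[word2]))


def _edge_stats(graph: CooccurrenceGraph, u: str, v: str):
    s = graph.stats
    return s.f[u], s.f[v], s.df[u], s.df[v], s.idf[u], s.idf[v]


def association_metric(
    graph: CooccurrenceGraph, word1: str, word2: str, calc: str = "raw", norm: int = 1
) -> tuple[float, bool]:
    """One association feature: (value, masked).

    ``calc="raw"``: normalization scheme applied to the direct edge weight,
    0 for an absent edge.  ``calc="pmi"``: PMI rescaled by the scheme's
    frequency factor, −10 (masked) for an absent edge.
    """
    _require(graph, word1)
    _require(graph, word2)
    w = graph.edge_weight(word1, word2)
    st = _edge_stats(graph, word1, word2)
    if calc == "raw":
        if w == 0:
            return 0.0, False
        try:
            return normalized_value(w, *st, graph.n_docs, norm), False
        except NormalizationDomainError:
            return float("nan"), True
    if calc == "pmi":
        if w == 0:
            return PMI_SENTINEL, True
        p = pmi(graph, word1, word2)
        try:
            return p * frequency_factor(*st, norm), False
        except NormalizationDomainError:
            return float("nan"), True
    raise ValueError(f"unknown association calc: {calc!r}")


def magnitude_scale(w1n: float, w2n: float) -> float:
    """Magnitude-difference transform (w1n + w2n) / (max/min).

    Balanced weight pairs pass through almost untouched (equal weights pass
    through exactly: scale(w, w) = 2w); wildly unbalanced pairs are
    shrunk toward the geometric middle.  Output is ≤ w1n + w2n with
    equality iff w1n = w2n.
    """
    if w1n <= 0 or w2n <= 0:
        raise ValueError(f"magnitude_scale requires positive weights, got ({w1n}, {w2n})")
    return (w1n + w2n) / (max(w1n, w2n) / min(w1n, w2n))


def _normalized_weight(graph, u, v, w, norm) -> float:
    """Per-edge normalized weight for similarity sums, floored at 0."""
    val = normalized_value(w, *_edge_stats(graph, u, v), graph.n_docs, norm)
    return max(val, 0.0)


def similarity(
    graph: CooccurrenceGraph,
    word1: str,
    word2: str,
    method: int,
    norm: int = 1,
    decomp: OverlapDecomposition | None = None,
) -> tuple[float, bool]:
    """One similarity feature: (value, masked).

    ``method`` is 1-5 (see module docstring); ``norm`` is the normalization
    scheme applied to every per-node weight before summation.  An isolated
    pair (all sums zero) returns (0.0, True).
    """
    if method not in (1, 2, 3, 4, 5):
        raise ValueError(f"unknown similarity method: {method}")
    d = decomp if decomp is not None else decompose(graph, word1, word2)

    try:
        ov_pairs = [
            (
                _normalized_weight(graph, d.word1, n, w1n, norm),
                _normalized_weight(graph, d.word2, n, w2n, norm),
            )
            for n, (w1n, w2n) in d.vo.items()
        ]
        non = sum(
            _normalized_weight(graph, d.word1, n, w, norm) for n, w in d.vn1.items()
        ) + sum(
            _normalized_weight(graph, d.word2, n, w, norm) for n, w in d.vn2.items()
        )
    except NormalizationDomainError:
        return float("nan"), True

    if method in (1, 2):
        overlap = sum(a + b for a, b in ov_pairs)
    else:
        # magnitude-difference transform; a floored-zero weight contributes 0
        overlap = sum(
            magnitude_scale(a, b) if a > 0 and b > 0 else 0.0 for a, b in ov_pairs
        )

    if method == 5:
        if d.n_overlap == 0:
            return 0.0, False
        return overlap / d.n_overlap, False

    if method in (2, 4):
        overlap = overlap / d.n_overlap if d.n_overlap else 0.0
        non = non / d.n_nonoverlap if d.n_nonoverlap else 0.0

    total = overlap + non
    if total == 0:
        return 0.0, True
    return (overlap - non) / total, False


@dataclass
class PairFeatureVector:
    """The 105 named features of one word pair, with a missing-value mask."""

    word1: str
    word2: str
    values: dict[str, float]
    mask: dict[str, bool]

    def __post_init__(self):
        assert list(self.values) == FEATURE_NAMES and list(self.mask) == FEATURE_NAMES

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=(self.word1, self.word2))


def feature_vector(graph: CooccurrenceGraph, word1: str, word2: str) -> PairFeatureVector:
    """All 105 (calc × norm) features for one word pair.

    Identical-word pairs are rejected: self-similarity is undefined by the
    overlap construction.
    """
    if word1 == word2:
        raise ValueError(f"identical word pair is invalid: ({word1!r}, {word2!r})")
    _require(graph, word1)
    _require(graph, word2)
    d = decompose(graph, word1, word2)
    values: dict[str, float] = {}
    mask: dict[str, bool] = {}
    for calc in ("raw", "pmi"):
        for m in range(1, 16):
            v, mk = association_metric(graph, word1, word2, calc, m)
            name = f"assoc_{calc}_n{m:02d}"
            values[name], mask[name] = v, mk
    for k in range(1, 6):
        for m in range(1, 16):
            v, mk = similarity(graph, word1, word2, k, m, decomp=d)
            name = f"sim_m{k}_n{m:02d}"
            values[name], mask[name] = v, mk
    return PairFeatureVector(word1=word1, word2=word2, values=values, mask=mask)


def feature_table(
    graph: CooccurrenceGraph, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Feature matrix for many pairs: 105 value columns + 105 mask columns.

    Index is a two-level (word1, word2) MultiIndex in input order.
    """
    rows, masks, index = [], [], []
    for w1, w2 in pairs:
        fv = feature_vector(graph, w1, w2)
        rows.append(fv.values)
        masks.append({f"{k}__mask": v for k, v in fv.mask.items()})
        index.append((w1, w2))
    idx = pd.MultiIndex.from_tuples(index, names=["word1", "word2"])
    return pd.concat(
        [pd.DataFrame(rows, index=idx), pd.DataFrame(masks, index=idx)], axis=1
    )
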