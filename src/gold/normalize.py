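"""The 15 graph-wide edge-weight normalization schemes.

High-frequency words accumulate heavy edge weights purely as a product of
their frequency.  Each scheme rescales a raw co-occurrence weight using the
endpoint words' token frequency (f), paragraph-level document frequency
(df), or inverse document frequency (idf = log10(n_docs/df)), combined by
sum or product, optionally log-transformed:

====  ==========================================  =============================
id    name                                        normalized weight
====  ==========================================  =============================
1     raw                                         w
2     pmi                                         log10(w·n_docs / (df1·df2))
3     sum of idfs                                 (idf1 + idf2) · w
4     product of idfs                             (idf1 · idf2) · w
5     sum of dfs                                  (df1 + df2) · w
6     product of dfs                              (df1 · df2) · w
7     inverse sum of idfs                         w / (idf1 + idf2)
8     inverse product of idfs                     w / (idf1 · idf2)
9     inverse sum of dfs                          w / (df1 + df2)
10    inverse product of dfs                      w / (df1 · df2)
11    sum of frequencies                          (f1 + f2) · w
12    sum freq × log sum freq                     w / ((f1+f2)·log10(f1+f2))
13    prod freq × log prod freq                   w / ((f1·f2)·log10(f1·f2))
14    sum freq / log sum freq                     w / ((f1+f2)/log10(f1+f2))
15    prod freq / log prod freq                   w / ((f1·f2)/log10(f1·f2))
====  ==========================================  =============================

Every scheme is symmetric in the two endpoints.  All schemes are linear in
the raw weight except PMI (id 2), which is logarithmic and may be negative.
Degenerate inputs (idf = 0 feeding a denominator, a log factor ≤ 0) raise
:class:`NormalizationDomainError` rather than clamping silently — they
signal corpus pathologies worth surfacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

__all__ = [
    "NormalizationMethod",
    "NormalizationDomainError",
    "METHODS",
    "METHOD_NAMES",
    "normalized_value",
    "normalize_weight",
    "frequency_factor",
]


class NormalizationDomainError(ArithmeticError):
    """A normalization formula was evaluated outside its domain."""


@dataclass(frozen=True)
class NormalizationMethod:
    id: int
    name: str
    # formula(w, f1, f2, df1, df2, idf1, idf2, n_docs) -> float
    formula: Callable[..., float]


def _log_factor(x: float, method: str) -> float:
    lf = math.log10(x)
    if lf <= 0:
        raise NormalizationDomainError(
            f"{method}: log10({x}) = {lf:.4g} <= 0; frequencies too small"
        )
    return lf


def _m2(w, f1, f2, df1, df2, idf1, idf2, n):
    if w <= 0:
        raise NormalizationDomainError("pmi: weight must be positive")
    return math.log10(w * n / (df1 * df2))


def _m7(w, f1, f2, df1, df2, idf1, idf2, n):
    if idf1 + idf2 == 0:
        raise NormalizationDomainError("inverse sum of idfs: idf1 + idf2 = 0")
    return w / (idf1 + idf2)


def _m8(w, f1, f2, df1, df2, idf1, idf2, n):
    if idf1 * idf2 == 0:
        raise NormalizationDomainError("inverse product of idfs: idf1 * idf2 = 0")
    return w / (idf1 * idf2)


METHODS: dict[int, NormalizationMethod] = {
    m.id: m
    for m in [
        NormalizationMethod(1, "raw", lambda w, *a: float(w)),
        NormalizationMethod(2, "pmi", _m2),
        NormalizationMethod(
            3, "sum_idf", lambda w, f1, f2, d1, d2, i1, i2, n: (i1 + i2) * w
        ),
        NormalizationMethod(
            4, "prod_idf", lambda w, f1, f2, d1, d2, i1, i2, n: (i1 * i2) * w
        ),
        NormalizationMethod(
            5, "sum_df", lambda w, f1, f2, d1, d2, i1, i2, n: (d1 + d2) * w
        ),
        NormalizationMethod(
            6, "prod_df", lambda w, f1, f2, d1, d2, i1, i2, n: (d1 * d2) * w
        ),
        NormalizationMethod(7, "inv_sum_idf", _m7),
        NormalizationMethod(8, "inv_prod_idf", _m8),
        NormalizationMethod(
            9, "inv_sum_df", lambda w, f1, f2, d1, d2, i1, i2, n: w / (d1 + d2)
        ),
        NormalizationMethod(
            10, "inv_prod_df", lambda w, f1, f2, d1, d2, i1, i2, n: w / (d1 * d2)
        ),
        NormalizationMethod(
            11, "sum_f", lambda w, f1, f2, d1, d2, i1, i2, n: (f1 + f2) * w
        ),
        NormalizationMethod(
            12,
            "sumf_x_logsumf",
            lambda w, f1, f2, d1, d2, i1, i2, n: w
            / ((f1 + f2) * _log_factor(f1 + f2, "sumf_x_logsumf")),
        ),
        NormalizationMethod(
            13,
            "prodf_x_logprodf",
            lambda w, f1, f2, d1, d2, i1, i2, n: w
            / ((f1 * f2) * _log_factor(f1 * f2, "prodf_x_logprodf")),
        ),
        NormalizationMethod(
            14,
            "sumf_div_logsumf",
            lambda w, f1, f2, d1, d2, i1, i2, n: w
            / ((f1 + f2) / _log_factor(f1 + f2, "sumf_div_logsumf")),
        ),
        NormalizationMethod(
            15,
            "prodf_div_logprodf",
            lambda w, f1, f2, d1, d2, i1, i2, n: w
            / ((f1 * f2) / _log_factor(f1 * f2, "prodf_div_logprodf")),
        ),
    ]
}

METHOD_NAMES = {m.id: m.name for m in METHODS.values()}


def normalized_value(
    weight: float,
    f1: float,
    f2: float,
    df1: float,
    df2: float,
    idf1: float,
    idf2: float,
    n_docs: int,
    method: int,
) -> float:
    """Evaluate scheme ``method`` (1-15) on explicit edge statistics."""
    if method not in METHODS:
        raise ValueError(f"unknown normalization method id: {method}")
    return METHODS[method].formula(weight, f1, f2, df1, df2, idf1, idf2, n_docs)


def normalize_weight(graph, u: str, v: str, method: int) -> float:
    """Normalized weight of the existing edge u–v under scheme ``method``.

    Raises
    ------
    KeyError
        If the edge does not exist (absent-edge semantics belong to the pair
        metrics, which define sentinels).
    NormalizationDomainError
        On degenerate statistics (see module docstring).
    """
    w = graph.edge_weight(u, v)
    if w == 0:
        raise KeyError(f"no edge between {u!r} and {v!r}")
    s = graph.stats
    return normalized_value(
        w, s.f[u], s.f[v], s.df[u], s.df[v], s.idf[u], s.idf[v], graph.n_docs, method
    )


def frequency_factor(
    f1: float, f2: float, df1: float, df2: float, idf1: float, idf2: float, method: int
) -> float:
    """Multiplicative frequency factor of a linear scheme (value / weight).

    Defined for every scheme except PMI (id 2), whose transform is not a
    multiplicative factor; callers composing PMI with other schemes use this
    to rescale a PMI value, and scheme 2 returns 1.0 there by convention.
    """
    if method == 2:
        return 1.0
    return normalized_value(1.0, f1, f2, df1, df2, idf1, idf2, 1, method)
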