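"""Overlap decomposition, association/similarity metrics, feature vectors."""

import math

import numpy as np
import pytest

from gold.graph import build_graph
from gold.metrics import (
    FEATURE_NAMES,
    PMI_SENTINEL,
    MissingWordError,
    association_metric,
    decompose,
    feature_table,
    feature_vector,
    magnitude_scale,
    pmi,
    similarity,
)

from conftest import make_clean, naive_similarity, random_graph


# ---------------------------------------------------------------------------
# decomposition


def test_decompose_toy_graph(toy_graph):
    d = decompose(toy_graph, "a", "b")
    assert set(d.vo) == {"c"}
    assert set(d.vn1) == {"d"}
    assert set(d.vn2) == {"e"}


def test_decompose_identical_neighborhoods():
    clean = make_clean([["a", "c"], ["a", "d"], ["b", "c"], ["b", "d"]])
    d = decompose(build_graph(clean, "paragraph"), "a", "b")
    assert d.n_nonoverlap == 0
    assert d.n_overlap == 2


def test_decompose_disjoint_neighborhoods():
    clean = make_clean([["a", "c"], ["b", "d"]])
    d = decompose(build_graph(clean, "paragraph"), "a", "b")
    assert d.n_overlap == 0
    assert set(d.vn1) == {"c"} and set(d.vn2) == {"d"}


def test_decompose_excludes_endpoints():
    clean = make_clean([["a", "b", "c"]])
    d = decompose(build_graph(clean, "paragraph"), "a", "b")
    assert "a" not in d.vo and "b" not in d.vo
    assert set(d.vo) == {"c"}


def test_missing_word_error_names_word(toy_graph):
    with pytest.raises(MissingWordError, match="zzz"):
        decompose(toy_graph, "a", "zzz")


# ---------------------------------------------------------------------------
# association


def test_absent_edge_raw_association_is_zero(toy_graph):
    for norm in range(1, 16):
        v, masked = association_metric(toy_graph, "a", "b", "raw", norm)
        assert v == 0.0 and not masked


def test_absent_edge_pmi_is_masked_sentinel(toy_graph):
    v, masked = association_metric(toy_graph, "a", "b", "pmi", 1)
    assert v == PMI_SENTINEL and masked


def test_pmi_independence_point():
    # construct df1*df2 == w * n_docs: w=2, n_docs=4, df=2,4
    clean = make_clean([["a", "b"], ["a", "b"], ["b", "x"], ["b", "x"]])
    g = build_graph(clean, "paragraph")
    assert pmi(g, "a", "b") == pytest.approx(0.0)


def test_pmi_formula_direct_value():
    # log10(w * n_docs / (df1*df2)) with w=10, n_docs=1000, dfs=100
    val = math.log10(10 * 1000 / (100 * 100))
    assert val == pytest.approx(0.0)
    clean = [["a", "b"]] * 10 + [["a", "x"]] * 90 + [["b", "x"]] * 90 + [["x", "y"]] * 810
    g = build_graph(make_clean(clean), "paragraph")
    assert g.n_docs == 1000
    assert g.stats.df["a"] == g.stats.df["b"] == 100
    assert pmi(g, "a", "b") == pytest.approx(0.0)


def test_pmi_composition_with_frequency_factor(toy_graph):
    # assoc_pmi under a linear scheme = factor * PMI; scheme 2 = plain PMI
    clean = make_clean([["a", "b", "c"], ["a", "b"], ["a", "c"]])
    g = build_graph(clean, "paragraph")
    p = pmi(g, "a", "b")
    v3, _ = association_metric(g, "a", "b", "pmi", 3)
    s = g.stats
    assert v3 == pytest.approx((s.idf["a"] + s.idf["b"]) * p)
    v2, _ = association_metric(g, "a", "b", "pmi", 2)
    v1, _ = association_metric(g, "a", "b", "pmi", 1)
    assert v1 == pytest.approx(p) and v2 == pytest.approx(p)


# ---------------------------------------------------------------------------
# magnitude-difference transform


@pytest.mark.parametrize(
    "w1, w2, expected",
    [(9, 52, 10.56), (2, 3, 3.33), (5, 5, 10.0)],
)
def test_magnitude_scale_worked_examples(w1, w2, expected):
    assert round(magnitude_scale(w1, w2), 2) == expected


def test_magnitude_scale_symmetric_and_bounded(rng):
    for _ in range(100):
        a, b = rng.integers(1, 1000, size=2)
        s = magnitude_scale(a, b)
        assert s == pytest.approx(magnitude_scale(b, a))
        assert s <= a + b + 1e-12
        if a != b:
            assert s < a + b
        else:
            assert s == pytest.approx(a + b)


def test_magnitude_scale_rejects_nonpositive():
    with pytest.raises(ValueError):
        magnitude_scale(0, 5)
    with pytest.raises(ValueError):
        magnitude_scale(3, -1)


# ---------------------------------------------------------------------------
# similarity methods


def _star_graph(ov_pairs, non1, non2):
    """Graph whose pair (x, y) has exactly the given overlap/non-overlap
    weights (norm 1 = raw weights)."""
    paragraphs = []
    for i, (w1, w2) in enumerate(ov_pairs):
        paragraphs += [["x", f"ov{i}"]] * w1 + [["y", f"ov{i}"]] * w2
    for i, w in enumerate(non1):
        paragraphs += [["x", f"na{i}"]] * w
    for i, w in enumerate(non2):
        paragraphs += [["y", f"nb{i}"]] * w
    return build_graph(make_clean(paragraphs), "paragraph")


def test_method1_boundary_identities():
    g_all_overlap = _star_graph([(3, 4), (2, 2)], [], [])
    v, masked = similarity(g_all_overlap, "x", "y", 1, 1)
    assert v == pytest.approx(1.0) and not masked

    g_no_overlap = _star_graph([], [5, 2], [7])
    v, masked = similarity(g_no_overlap, "x", "y", 1, 1)
    assert v == pytest.approx(-1.0) and not masked


def test_method1_worked_figure_example():
    # overlap weights (9,52) and (2,3); non-overlap 4 (word1) and 6 (word2)
    g = _star_graph([(9, 52), (2, 3)], [4], [6])
    v, _ = similarity(g, "x", "y", 1, 1)
    assert v == pytest.approx((66 - 10) / 76)


def test_method5_values():
    g = _star_graph([(9, 52), (2, 3)], [4], [6])
    v, _ = similarity(g, "x", "y", 5, 1)
    assert v == pytest.approx((10.557692307692308 + 10 / 3) / 2, rel=1e-9)
    assert round(v, 4) == 6.9455

    g2 = _star_graph([(7, 7)], [1], [])
    v2, _ = similarity(g2, "x", "y", 5, 1)
    assert v2 == pytest.approx(14.0)  # single equal-weight node -> 2w

    g3 = _star_graph([], [2], [3])
    v3, masked = similarity(g3, "x", "y", 5, 1)
    assert v3 == 0.0 and not masked  # empty overlap is a defined 0


def test_method2_size_normalization():
    # one overlap node (2,2), two non-overlap nodes of weight 2 each:
    # M1: (4-4)/8 = 0;  M2: (4/1 - 4/2)/(4/1 + 4/2) = 1/3
    g = _star_graph([(2, 2)], [2], [2])
    v1, _ = similarity(g, "x", "y", 1, 1)
    v2, _ = similarity(g, "x", "y", 2, 1)
    assert v1 == pytest.approx(0.0)
    assert v2 == pytest.approx(1 / 3)


def test_method1_monotone_in_overlap_mass():
    # moving weight from non-overlap to overlap never decreases Method 1
    prev = -2.0
    for ov in range(1, 8):
        g = _star_graph([(ov, 5)], [8 - ov], [3])
        v, _ = similarity(g, "x", "y", 1, 1)
        assert v >= prev - 1e-12
        prev = v


def test_isolated_pair_sentinel():
    clean = make_clean([["x", "y"], ["a", "b"]])
    g = build_graph(clean, "paragraph")
    v, masked = similarity(g, "x", "y", 1, 1)
    assert v == 0.0 and masked


def test_similarity_oracle_equivalence_and_ranges(rng):
    """All five methods agree with the naive set-and-sum reference, stay in
    range, and are symmetric, over random small graphs and all norms."""
    for _ in range(30):
        g = random_graph(rng, max_nodes=30)
        vocab = sorted(g.vocabulary)
        w1, w2 = [vocab[i] for i in rng.choice(len(vocab), size=2, replace=False)]
        for method in range(1, 6):
            for norm in range(1, 16):
                v, masked = similarity(g, w1, w2, method, norm)
                if masked:
                    continue
                ref = naive_similarity(g, w1, w2, method, norm)
                assert v == pytest.approx(ref, rel=1e-9, abs=1e-12)
                if method <= 4:
                    assert -1.0 - 1e-9 <= v <= 1.0 + 1e-9
                else:
                    assert v >= 0.0
                v_swap, _ = similarity(g, w2, w1, method, norm)
                assert v == pytest.approx(v_swap)


# ---------------------------------------------------------------------------
# feature vectors


def test_feature_vector_shape_and_names(toy_graph):
    fv = feature_vector(toy_graph, "a", "b")
    assert list(fv.values) == FEATURE_NAMES
    assert len(fv.values) == 105
    assert all(np.isfinite(v) or fv.mask[k] for k, v in fv.values.items())


def test_feature_vector_rejects_identical_pair(toy_graph):
    with pytest.raises(ValueError, match="identical"):
        feature_vector(toy_graph, "a", "a")


def test_feature_vector_swap_symmetry(rng):
    for _ in range(10):
        g = random_graph(rng, max_nodes=20)
        vocab = sorted(g.vocabulary)
        w1, w2 = [vocab[i] for i in rng.choice(len(vocab), size=2, replace=False)]
        fv = feature_vector(g, w1, w2)
        fw = feature_vector(g, w2, w1)
        for name in FEATURE_NAMES:
            a, b = fv.values[name], fw.values[name]
            assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b), name
            assert fv.mask[name] == fw.mask[name]


def test_feature_table_layout(toy_graph):
    t = feature_table(toy_graph, [("a", "b"), ("c", "d")])
    assert t.shape == (2, 210)
    assert list(t.columns[:105]) == FEATURE_NAMES
    assert t.index.tolist() == [("a", "b"), ("c", "d")]
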