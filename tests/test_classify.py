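"""The repeated-split MLP protocol, feature ablation, and group comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gold.classify import (
    LabeledPairSet,
    feature_ablation,
    grouped_metric_comparison,
    run_protocol,
    svm_feature_selection,
)
from gold.metrics import ASSOCIATION_FEATURES, FEATURE_NAMES, SIMILARITY_FEATURES


def _pairs(n):
    return [(f"u{i}", f"v{i}") for i in range(n)]


def _frame(X, columns=None):
    X = np.asarray(X, dtype=float)
    cols = columns or [f"f{j}" for j in range(X.shape[1])]
    return pd.DataFrame(X, columns=cols)


def test_labeled_pair_set_rejects_duplicates_and_bad_labels():
    with pytest.raises(ValueError, match="duplicate"):
        LabeledPairSet(pairs=[("a", "b"), ("b", "a")], labels=["x", "y"])
    with pytest.raises(ValueError, match="schema"):
        LabeledPairSet(pairs=[("a", "b")], labels=["q"], schema=("x", "y"))


def test_perfectly_separable_feature_reaches_full_accuracy(rng):
    y = ["pos"] * 20 + ["neg"] * 20
    X = _frame(np.concatenate([np.ones(20), -np.ones(20)])[:, None]
               + rng.normal(0, 0.01, (40, 1)))
    report = run_protocol(X, y, iterations=3, seed=7)
    assert report.mean_accuracy == 1.0


def test_protocol_is_deterministic():
    rng = np.random.default_rng(3)
    X = _frame(rng.normal(size=(30, 5)))
    y = ["a"] * 15 + ["b"] * 15
    r1 = run_protocol(X, y, iterations=4, seed=11)
    r2 = run_protocol(X, y, iterations=4, seed=11)
    assert r1.accuracies == r2.accuracies
    assert r1.confusion.equals(r2.confusion)
    assert r1.to_dict() == r2.to_dict()


def test_confusion_matrix_conservation():
    rng = np.random.default_rng(4)
    X = _frame(rng.normal(size=(40, 3)))
    y = ["a"] * 14 + ["b"] * 13 + ["c"] * 13
    r = run_protocol(X, y, iterations=5, seed=1)
    assert r.confusion.values.sum() == sum(r.test_sizes)
    assert 0.0 <= r.mean_accuracy <= 1.0


def test_shuffled_labels_score_at_chance():
    """Label-permuted features give ~50% on two balanced classes."""
    rng = np.random.default_rng(5)
    X = _frame(rng.normal(size=(40, 4)))
    accs = []
    for rep in range(60):
        y = list(rng.permutation(["a"] * 20 + ["b"] * 20))
        accs.append(run_protocol(X, y, iterations=2, seed=rep).mean_accuracy)
    assert abs(np.mean(accs) - 0.5) < 0.06


def test_stratification_error_on_tiny_class():
    X = _frame(np.zeros((5, 2)))
    y = ["a", "a", "a", "a", "b"]
    with pytest.raises(ValueError, match="stratified|member"):
        run_protocol(X, y, iterations=2, seed=0)


def test_missing_values_are_min_imputed():
    # one separating feature with NaNs in the low class: imputation to the
    # training minimum keeps the classes separable
    y = ["lo"] * 16 + ["hi"] * 16
    col = np.array([0.0] * 16 + [5.0] * 16)
    col[[1, 3]] = np.nan
    X = _frame(col[:, None])
    r = run_protocol(X, y, iterations=3, seed=2)
    assert r.mean_accuracy > 0.9


def test_ablation_finds_planted_feature():
    rng = np.random.default_rng(6)
    n = 36
    y = ["a"] * 18 + ["b"] * 18
    X = rng.normal(size=(n, 6))
    X[:, 3] = np.where(np.array(y) == "a", 1.0, -1.0) + rng.normal(0, 0.05, n)
    r1, r2 = feature_ablation(_frame(X), y, round1_keep=3, iterations=2, seed=0)
    assert r1.iloc[0]["feature"] == "f3"
    assert len(r2) == 3  # C(3, 2)


def test_complementary_features_outrank_singletons():
    """Two XOR-style half-features beat either alone when paired."""
    rng = np.random.default_rng(7)
    n = 48
    a = np.repeat([0, 0, 1, 1], n // 4)
    b = np.repeat([0, 1, 0, 1], n // 4)
    y = np.where(a ^ b, "odd", "even").tolist()
    X = np.column_stack([
        a + rng.normal(0, 0.05, n),
        b + rng.normal(0, 0.05, n),
        rng.normal(size=n),
    ])
    r1, r2 = feature_ablation(_frame(X), y, round1_keep=3, iterations=3, seed=1)
    single = {row["feature"]: row["accuracy"] for _, row in r1.iterrows()}
    mask = {frozenset((a, b)) for a, b in [("f0", "f1")]}.pop()
    sel = r2[[frozenset((a, b)) == mask
              for a, b in zip(r2["feature_1"], r2["feature_2"])]]
    pair_acc = sel["accuracy"].iloc[0]
    assert pair_acc > single["f0"]
    assert pair_acc > single["f1"]


def test_round2_row_count_is_choose_2():
    """Round 2 enumerates exactly C(round1_keep, 2) feature pairs."""
    X = _frame(np.zeros((8, 10)))
    y = ["a"] * 4 + ["b"] * 4
    calls = []

    def stub_scorer(cols):
        calls.append(tuple(cols))
        return 0.5

    r1, r2 = feature_ablation(X, y, round1_keep=6, scorer=stub_scorer)
    assert len(r1) == 10
    assert len(r2) == 15  # C(6, 2)
    assert len([c for c in calls if len(c) == 2]) == 15


def test_grouped_comparison_partitions_and_signal():
    rng = np.random.default_rng(8)
    n = 40
    y = ["a"] * 20 + ["b"] * 20
    X = pd.DataFrame(
        rng.normal(size=(n, 105)), columns=FEATURE_NAMES
    )
    # plant signal only in association columns
    for c in ASSOCIATION_FEATURES:
        X[c] += np.where(np.array(y) == "a", 1.5, -1.5)
    reports = grouped_metric_comparison(X, y, iterations=3, seed=0)
    assert len(reports["association"].feature_names) == 30
    assert len(reports["similarity"].feature_names) == 75
    assert reports["association"].mean_accuracy > reports["similarity"].mean_accuracy


def test_grouped_comparison_deterministic():
    rng = np.random.default_rng(9)
    X = pd.DataFrame(rng.normal(size=(24, 105)), columns=FEATURE_NAMES)
    y = ["a"] * 12 + ["b"] * 12
    a = grouped_metric_comparison(X, y, iterations=2, seed=5)
    b = grouped_metric_comparison(X, y, iterations=2, seed=5)
    for k in a:
        assert a[k].accuracies == b[k].accuracies


def test_svm_selection_prefers_informative_features():
    rng = np.random.default_rng(10)
    n = 60
    y = ["a"] * 30 + ["b"] * 30
    X = rng.normal(size=(n, 8))
    X[:, 2] += np.where(np.array(y) == "a", 2.0, -2.0)
    X[:, 5] += np.where(np.array(y) == "a", -1.5, 1.5)
    top = svm_feature_selection(_frame(X), y, n_keep=2, seed=0)
    assert set(top) == {"f2", "f5"}
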