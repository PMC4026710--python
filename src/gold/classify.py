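"""Word-pair relation classification and feature analysis.

The evaluation protocol is repeated random-split training of a small
multilayer perceptron: a single hidden layer of 20 neurons, L2 penalty 1.0,
at most 300 optimizer iterations.  Each of the (default 10) iterations draws
a fresh stratified 70/30 train/test split, deterministically re-seeded from
the master seed, and accuracy plus the confusion matrix are accumulated over
iterations.

Preprocessing inside each split: mask-flagged missing values (NaN) are
imputed with the training-split column minimum — a masked feature means
"less related than anything observed" — then features are z-scored with
statistics fit on the training split only.

Feature analysis mirrors the one-/two-feature sweep: round 1 scores every
feature alone, keeps the top ``round1_keep``; round 2 scores every unordered
pair from the kept set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

from .metrics import ASSOCIATION_FEATURES, SIMILARITY_FEATURES

__all__ = [
    "LabeledPairSet",
    "ClassificationReport",
    "run_protocol",
    "feature_ablation",
    "grouped_metric_comparison",
    "svm_feature_selection",
]


@dataclass
class LabeledPairSet:
    """Word pairs with labels from a declared schema.

    Typical schemas: {related, unrelated} for the two-way task, and
    {associated, similar, both} for the relation-type task.
    """

    pairs: list[tuple[str, str]]
    labels: list[str]
    schema: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels must have equal length")
        seen = set()
        for w1, w2 in self.pairs:
            key = (w1, w2) if w1 < w2 else (w2, w1)
            if key in seen:
                raise ValueError(f"duplicate unordered pair: {key}")
            seen.add(key)
        if self.schema:
            bad = set(self.labels) - set(self.schema)
            if bad:
                raise ValueError(f"labels outside declared schema: {sorted(bad)}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledPairSet":
        """Build from a (word1, word2, label) DataFrame."""
        return cls(
            pairs=list(zip(df["word1"], df["word2"])),
            labels=list(df["label"]),
            schema=tuple(sorted(set(df["label"]))),
        )


@dataclass
class ClassificationReport:
    """Aggregated result of the repeated-split protocol.

    ``confusion`` is summed over iterations (rows = true labels, columns =
    predicted), so its cells sum to the total number of test predictions.
    """

    accuracies: list[float]
    labels: list[str]
    confusion: pd.DataFrame
    feature_names: list[str]
    seed: int
    test_sizes: list[int] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "accuracies": self.accuracies,
            "labels": self.labels,
            "confusion": self.confusion.values.tolist(),
            "feature_names": self.feature_names,
            "seed": self.seed,
            "test_sizes": self.test_sizes,
        }

    def __str__(self) -> str:
        lines = [f"mean accuracy: {self.mean_accuracy:.4f} over "
                 f"{len(self.accuracies)} iterations"]
        lines.append("confusion (rows=true, cols=predicted, summed):")
        lines.append(self.confusion.to_string())
        return "\n".join(lines)


def _iteration_seeds(seed: int, n: int) -> np.ndarray:
    # independent per-iteration seeds, kept below 2**31 for sklearn
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _prepare(X_train: np.ndarray, X_test: np.ndarray):
    """Min-impute NaNs and z-score, both fit on the training split only."""
    col_min = np.nanmin(
        np.where(np.isfinite(X_train), X_train, np.nan), axis=0, initial=np.inf
    )
    col_min = np.where(np.isfinite(col_min), col_min, 0.0)
    X_train = np.where(np.isnan(X_train), col_min, X_train)
    X_test = np.where(np.isnan(X_test), col_min, X_test)
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    return (X_train - mu) / sd, (X_test - mu) / sd


def _make_mlp(random_state: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(20,),
        alpha=1.0,
        max_iter=300,
        random_state=int(random_state),
    )


def run_protocol(
    features: pd.DataFrame,
    labels: LabeledPairSet | list[str],
    iterations: int = 10,
    test_size: float = 0.30,
    seed: int = 0,
) -> ClassificationReport:
    """Repeated stratified 70/30 split evaluation of the MLP.

    ``features`` holds one row per labeled pair; mask columns (``*__mask``)
    are dropped automatically, with mask-flagged NaN values min-imputed.
    The report is a pure function of (features, labels, seed).

    Raises
    ------
    ValueError
        If any label has fewer than 2 members (stratification impossible).
    """
    y = np.asarray(labels.labels if isinstance(labels, LabeledPairSet) else labels)
    value_cols = [c for c in features.columns if not str(c).endswith("__mask")]
    X = features[value_cols].to_numpy(dtype=float)
    if len(X) != len(y):
        raise ValueError("feature rows and labels differ in length")
    label_names, counts = np.unique(y, return_counts=True)
    if len(label_names) < 2:
        raise ValueError("need at least 2 distinct labels")
    if counts.min() < 2:
        small = label_names[counts.argmin()]
        raise ValueError(
            f"label {small!r} has {counts.min()} member(s); "
            "stratified splitting needs at least 2 per label"
        )

    accuracies, test_sizes = [], []
    conf = np.zeros((len(label_names), len(label_names)), dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for it_seed in _iteration_seeds(seed, iterations):
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, test_size=test_size, stratify=y, random_state=int(it_seed)
            )
            X_tr, X_te = _prepare(X_tr, X_te)
            clf = _make_mlp(it_seed)
            clf.fit(X_tr, y_tr)
            pred = clf.predict(X_te)
            accuracies.append(float((pred == y_te).mean()))
            test_sizes.append(len(y_te))
            conf += confusion_matrix(y_te, pred, labels=label_names)

    return ClassificationReport(
        accuracies=accuracies,
        labels=list(label_names),
        confusion=pd.DataFrame(conf, index=label_names, columns=label_names),
        feature_names=[str(c) for c in value_cols],
        seed=seed,
        test_sizes=test_sizes,
    )


def _default_scorer(features, labels, iterations, seed):
    def score(cols: list[str]) -> float:
        keep = list(cols) + [f"{c}__mask" for c in cols if f"{c}__mask" in features]
        return run_protocol(
            features[keep], labels, iterations=iterations, seed=seed
        ).mean_accuracy

    return score


def feature_ablation(
    features: pd.DataFrame,
    labels: LabeledPairSet | list[str],
    round1_keep: int = 50,
    iterations: int = 5,
    seed: int = 0,
    scorer=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One- and two-feature classifier sweep.

    Round 1 scores each feature alone and retains the ``round1_keep`` best
    (ties broken by feature name for determinism).  Round 2 scores every
    unordered pair from the kept set — C(round1_keep, 2) rows.

    ``scorer(columns) -> accuracy`` may be injected (e.g. a cheaper proxy
    for structural checks); the default is the full MLP protocol with
    ``iterations`` splits.

    Returns (round1 table, round2 table), each sorted by descending accuracy.
    """
    score = scorer or _default_scorer(features, labels, iterations, seed)
    value_cols = [str(c) for c in features.columns if not str(c).endswith("__mask")]

    r1 = pd.DataFrame(
        {"feature": value_cols, "accuracy": [score([c]) for c in value_cols]}
    ).sort_values(["accuracy", "feature"], ascending=[False, True], ignore_index=True)
    kept = list(r1["feature"].head(round1_keep))

    rows = []
    for a, b in itertools.combinations(kept, 2):
        rows.append({"feature_1": a, "feature_2": b, "accuracy": score([a, b])})
    r2 = pd.DataFrame(rows).sort_values(
        ["accuracy", "feature_1", "feature_2"],
        ascending=[False, True, True],
        ignore_index=True,
    )
    return r1, r2


def grouped_metric_comparison(
    features: pd.DataFrame,
    labels: LabeledPairSet | list[str],
    iterations: int = 5,
    seed: int = 0,
) -> dict[str, ClassificationReport]:
    """Similarity-only vs association-only classifier comparison.

    Runs the protocol twice on the two column subsets (30 association
    features, 75 similarity features) and returns both reports.
    """
    groups = {
        "association": [c for c in ASSOCIATION_FEATURES if c in features],
        "similarity": [c for c in SIMILARITY_FEATURES if c in features],
    }
    out = {}
    for name, cols in groups.items():
        if not cols:
            raise ValueError(f"no {name} feature columns present")
        keep = cols + [f"{c}__mask" for c in cols if f"{c}__mask" in features]
        out[name] = run_protocol(features[keep], labels, iterations=iterations, seed=seed)
    return out


def svm_feature_selection(
    features: pd.DataFrame,
    labels: LabeledPairSet | list[str],
    n_keep: int = 10,
    seed: int = 0,
) -> list[str]:
    """Rank features by linear-SVM weight magnitude; return the top n_keep.

    A utility for reducing the feature set; scores of the reduced set are
    obtained by feeding the returned columns back to :func:`run_protocol`.
    """
    y = np.asarray(labels.labels if isinstance(labels, LabeledPairSet) else labels)
    value_cols = [str(c) for c in features.columns if not str(c).endswith("__mask")]
    X = features[value_cols].to_numpy(dtype=float)
    Xp, _ = _prepare(X, X)
    svc = LinearSVC(C=1.0, random_state=seed).fit(Xp, y)
    coef = np.atleast_2d(svc.coef_)
    importance = np.abs(coef).sum(axis=0)
    order = np.lexsort((value_cols, -importance))
    return [value_cols[i] for i in order[:n_keep]]
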