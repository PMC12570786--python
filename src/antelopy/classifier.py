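"""Supervised behaviour classification from burst feature vectors.

Feature selection drops redundant features by absolute Pearson correlation
(threshold 0.9) after ranking candidates by single-feature cross-validated
accuracy; the classifier itself is a gradient-boosted decision-tree
ensemble.  Contribution scores are forward-stepwise gains in held-out
accuracy over the retained features.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FeatureSelection",
    "ClassifierModel",
    "ConfusionMatrix",
    "remove_redundant",
    "rank_contributions",
    "train",
    "classify",
    "save_model",
    "load_model",
]

CORRELATION_THRESHOLD = 0.9
MIN_ROWS_PER_CLASS = 5

#: Video-labelled training-burst counts per collared individual in the
#: original deployments (reference metadata for coverage book-keeping).
REFERENCE_LABELLED_BURSTS: dict[str, dict[str, int]] = {
    "springbok": {"8316": 1188, "8318": 1366, "8320": 1398},
    "kudu": {"8319": 2406},
    "eland": {"7297": 2876},
}


@dataclass(frozen=True)
class FeatureSelection:
    """Retained features in rank order; dropped features point at the
    retained feature each was correlated with."""

    retained: tuple[str, ...]
    dropped: dict[str, str]
    single_feature_accuracy: dict[str, float]


@dataclass
class ClassifierModel:
    estimator: HistGradientBoostingClassifier
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    seed: int


@dataclass(frozen=True)
class ConfusionMatrix:
    """counts[true, predicted] plus per-class recall and precision."""

    counts: pd.DataFrame

    @property
    def recall(self) -> pd.Series:
        support = self.counts.sum(axis=1)
        return pd.Series(np.diag(self.counts), index=self.counts.index) / support.replace(0, np.nan)

    @property
    def precision(self) -> pd.Series:
        predicted = self.counts.sum(axis=0)
        return pd.Series(np.diag(self.counts), index=self.counts.index) / predicted.replace(0, np.nan)

    @property
    def accuracy(self) -> float:
        return float(np.diag(self.counts).sum() / self.counts.to_numpy().sum())

    @property
    def balanced_accuracy(self) -> float:
        return float(self.recall.mean())


def _single_feature_accuracy(
    x: np.ndarray, y: np.ndarray, seed: int, n_splits: int = 5
) -> float:
    """5-fold CV accuracy of a shallow decision tree on one feature."""
    if np.all(x == x[0]):
        return 0.0
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    accs = []
    for tr, te in cv.split(x.reshape(-1, 1), y):
        tree = DecisionTreeClassifier(max_depth=3, random_state=seed)
        tree.fit(x[tr].reshape(-1, 1), y[tr])
        accs.append(float((tree.predict(x[te].reshape(-1, 1)) == y[te]).mean()))
    return float(np.mean(accs))


def remove_redundant(
    table: pd.DataFrame,
    label_column: str = "label",
    threshold: float = CORRELATION_THRESHOLD,
    seed: int = 0,
) -> FeatureSelection:
    """Greedy correlation-based feature selection.

    Features are ranked by single-feature 5-fold classification accuracy
    (descending, ties alphabetical) and visited in that order; a feature is
    retained iff its absolute Pearson correlation with every already
    retained feature is below ``threshold``.  A constant feature has
    undefined correlation; it is treated as uncorrelated and ranked last.
    """
    feature_names = [c for c in table.columns if c != label_column]
    if len(feature_names) < 2:
        raise ValueError("need at least 2 features")
    y = table[label_column].to_numpy()
    acc = {
        name: _single_feature_accuracy(table[name].to_numpy(dtype=float), y, seed)
        for name in feature_names
    }
    order = sorted(feature_names, key=lambda n: (-acc[n], n))
    X = table[feature_names].to_numpy(dtype=float)
    col = {n: i for i, n in enumerate(feature_names)}
    sd = X.std(axis=0)

    retained: list[str] = []
    dropped: dict[str, str] = {}
    for name in order:
        i = col[name]
        culprit = None
        for kept in retained:
            j = col[kept]
            if sd[i] == 0 or sd[j] == 0:
                continue  # undefined correlation -> treat as uncorrelated
            r = np.corrcoef(X[:, i], X[:, j])[0, 1]
            if abs(r) >= threshold:
                culprit = kept
                break
        if culprit is None:
            retained.append(name)
        else:
            dropped[name] = culprit
    return FeatureSelection(
        retained=tuple(retained), dropped=dropped, single_feature_accuracy=acc
    )


def _make_estimator(seed: int, max_iter: int = 150) -> HistGradientBoostingClassifier:
    return HistGradientBoostingClassifier(
        max_iter=max_iter,
        learning_rate=0.1,
        max_depth=None,
        random_state=seed,
    )


def rank_contributions(
    table: pd.DataFrame,
    selection: FeatureSelection,
    label_column: str = "label",
    n_top: int = 5,
    split: float = 0.75,
    seed: int = 0,
) -> dict[str, float]:
    """Forward-stepwise accuracy gains over the retained features.

    The contribution of the j-th retained feature is the held-out accuracy
    with features 1..j minus that with features 1..j-1, where the accuracy
    of the empty set is the majority-class rate.  Reported for the first
    ``n_top`` retained features.
    """
    y = table[label_column].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("contribution ranking needs at least 2 classes")
    X = table[list(selection.retained)].to_numpy(dtype=float)
    idx_tr, idx_te = train_test_split(
        np.arange(len(y)), train_size=split, stratify=y, random_state=seed
    )
    majority_label = pd.Series(y[idx_tr]).mode().iloc[0]
    prev = float((y[idx_te] == majority_label).mean())  # accuracy of the empty set
    contributions: dict[str, float] = {}
    for j, name in enumerate(selection.retained[:n_top], start=1):
        est = _make_estimator(seed, max_iter=80)
        est.fit(X[idx_tr, :j], y[idx_tr])
        acc = float((est.predict(X[idx_te, :j]) == y[idx_te]).mean())
        contributions[name] = acc - prev
        prev = acc
    return contributions


def train(
    table: pd.DataFrame,
    label_column: str = "label",
    feature_names: tuple[str, ...] | None = None,
    split: float = 0.75,
    seed: int = 0,
) -> tuple[ClassifierModel, ConfusionMatrix]:
    """Fit the gradient-boosted classifier with a stratified hold-out test.

    Classes with fewer than 5 rows are excluded with a warning.  Returns the
    fitted model and the hold-out confusion matrix; deterministic under a
    fixed seed.
    """
    if feature_names is None:
        feature_names = tuple(c for c in table.columns if c != label_column)
    y = table[label_column].to_numpy()
    counts = pd.Series(y).value_counts()
    small = counts[counts < MIN_ROWS_PER_CLASS].index.tolist()
    if small:
        warnings.warn(f"excluding classes with < {MIN_ROWS_PER_CLASS} rows: {small}")
        keep = ~pd.Series(y).isin(small).to_numpy()
        table = table.loc[keep]
        y = y[keep]
    X = table[list(feature_names)].to_numpy(dtype=float)
    idx_tr, idx_te = train_test_split(
        np.arange(len(y)), train_size=split, stratify=y, random_state=seed
    )
    est = _make_estimator(seed)
    est.fit(X[idx_tr], y[idx_tr])
    classes = tuple(est.classes_)
    pred = est.predict(X[idx_te])
    cm = pd.crosstab(
        pd.Categorical(y[idx_te], categories=classes),
        pd.Categorical(pred, categories=classes),
        dropna=False,
    )
    cm.index = pd.Index(classes, name="true")
    cm.columns = pd.Index(classes, name="predicted")
    model = ClassifierModel(estimator=est, feature_names=tuple(feature_names), classes=classes, seed=seed)
    return model, ConfusionMatrix(counts=cm)


def classify(model: ClassifierModel, features: pd.DataFrame) -> pd.DataFrame:
    """Predicted label and class probabilities per burst.

    Carries through ``individual_id`` / ``start_utc`` / ``static_pitch_deg``
    columns when present; probability columns are ``p_<class>`` and sum to
    1 per row.
    """
    missing = [c for c in model.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    carried = [c for c in ("individual_id", "start_utc", "static_pitch_deg") if c in features.columns]
    out = features[carried].copy() if carried else pd.DataFrame(index=features.index)
    if len(features) == 0:
        out["label"] = pd.Series(dtype=object)
        for c in model.classes:
            out[f"p_{c}"] = pd.Series(dtype=float)
        return out
    X = features[list(model.feature_names)].to_numpy(dtype=float)
    proba = model.estimator.predict_proba(X)
    out["label"] = [model.classes[i] for i in np.argmax(proba, axis=1)]
    for i, c in enumerate(model.classes):
        out[f"p_{c}"] = proba[:, i]
    return out


def save_model(model: ClassifierModel, path) -> None:
    """Persist the model (joblib) with a JSON sidecar of its metadata."""
    path = Path(path)
    joblib.dump(model.estimator, path)
    sidecar = {
        "feature_names": list(model.feature_names),
        "classes": list(model.classes),
        "seed": model.seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> ClassifierModel:
    path = Path(path)
    est = joblib.load(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ClassifierModel(
        estimator=est,
        feature_names=tuple(meta["feature_names"]),
        classes=tuple(meta["classes"]),
        seed=int(meta["seed"]),
    )


def shuffled_label_baseline(
    table: pd.DataFrame,
    label_column: str = "label",
    feature_names: tuple[str, ...] | None = None,
    seed: int = 0,
) -> float:
    """Held-out balanced accuracy after permuting labels (chance floor)."""
    rng = np.random.default_rng(seed)
    shuffled = table.copy()
    shuffled[label_column] = rng.permutation(shuffled[label_column].to_numpy())
    _, cm = train(shuffled, label_column=label_column, feature_names=feature_names, seed=seed)
    return cm.balanced_accuracy
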