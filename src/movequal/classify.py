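"""Boosted-tree classification of functional-test error parameters.

A discrete (SAMME-style) AdaBoost ensemble of shallow decision trees is
trained per error parameter against the physiotherapists' consensus
labels, with the faulty class (error present) as the positive class.

Each boosting round fits a depth-bounded tree by weighted Gini impurity
on a random subset of floor(sqrt(d)) features, computes the weighted
error ``e``, assigns the learner weight ``alpha = lr * ln((1 - e) / e)``
and multiplies the weights of misclassified samples by ``exp(alpha)``
before renormalising.  A round with zero error keeps its learner and
stops; a round with error >= 0.5 redraws its feature subset once and
stops after the retry if the refit is no better.  The ensemble predicts
by the sign of the weighted vote ``sum(alpha * (2 h(x) - 1))``, ties
resolved toward the non-faulty class.

The feature-subset schedule is seeded per (seed, round), not per data
order, so permuting training rows together with their labels leaves the
fitted model's predictions unchanged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, DegenerateLabelsError, InsufficientDataError

_EPS_ERR = 1e-10


@dataclass
class BoostParams:
    """Hyper-parameters of the boosted ensemble and the data split."""

    n_learners: int = 50
    learning_rate: float = 0.1
    max_depth: int = 3
    feature_subset: str | int = "sqrt"  # floor(sqrt(d)) features per learner
    seed: int = 42
    split: tuple[float, float, float] = (0.80, 0.15, 0.05)
    base_learner: str = "tree"  # "tree" (Gini CART) or "stump" (exhaustive)

    def __post_init__(self) -> None:
        if self.n_learners < 1:
            raise ConfigurationError("n_learners must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.max_depth < 1:
            raise ConfigurationError("max_depth must be >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ConfigurationError(f"split fractions must sum to 1, got {self.split}")
        if self.base_learner not in ("tree", "stump"):
            raise ConfigurationError(f"unknown base_learner {self.base_learner!r}")

    def subset_size(self, d: int) -> int:
        if self.feature_subset == "sqrt":
            return max(1, int(np.floor(np.sqrt(d))))
        if self.feature_subset in ("all", None):
            return d
        k = int(self.feature_subset)
        if not 1 <= k <= d:
            raise ConfigurationError(f"feature_subset {k} outside 1..{d}")
        return k


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer allocation of n items by the largest-remainder rule.

    Ties in remainders go to the earlier (larger-fraction) split, making
    the allocation deterministic.
    """
    quotas = [n * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    order = sorted(range(len(fractions)), key=lambda i: (-remainders[i], i))
    for i in order[: n - sum(counts)]:
        counts[i] += 1
    return counts


def stratified_split(
    labels: Sequence[int],
    params: BoostParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic stratified (train, validation, test) index sets.

    Within each class, indices are shuffled by the seed and allocated to
    the three splits by largest-remainder rounding of the class count, so
    class proportions survive up to integer rounding.  If any split ends
    up without one of the classes, a warning is issued and the validation
    split absorbs the test split.
    """
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateLabelsError("both classes must be present to split")
    rng = np.random.default_rng(params.seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    for c in classes:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        counts = _largest_remainder(idx.size, params.split)
        start = 0
        for s, cnt in enumerate(counts):
            parts[s].append(idx[start:start + cnt])
            start += cnt
    train, val, test = (np.sort(np.concatenate(p)) for p in parts)

    starving = any(
        np.intersect1d(split, np.flatnonzero(y == c)).size == 0
        for split in (train, val, test)
        for c in classes
    )
    if starving:
        warnings.warn(
            "a split received zero members of a class; "
            "validation absorbs the test split",
            stacklevel=2,
        )
        val = np.sort(np.concatenate([val, test]))
        test = np.array([], dtype=int)
    return train, val, test


# ---------------------------------------------------------------------------
# Weak learners as nested node records
# ---------------------------------------------------------------------------

def _sklearn_tree_to_nodes(tree: DecisionTreeClassifier,
                           subset: np.ndarray) -> dict:
    """Convert a fitted sklearn tree into a nested node record.

    Feature indices are mapped from the subset back to the full feature
    space.  Leaves carry the majority class (ties toward class 0, which
    argmax already gives).  Split rule: x[feature] <= threshold -> left.
    """
    t = tree.tree_
    tree_classes = tree.classes_

    def node(i: int) -> dict:
        if t.children_left[i] == -1:
            cls = int(tree_classes[int(np.argmax(t.value[i][0]))])
            return {"leaf": cls}
        return {
            "feature": int(subset[t.feature[i]]),
            "threshold": float(t.threshold[i]),
            "left": node(t.children_left[i]),
            "right": node(t.children_right[i]),
        }

    return node(0)


def _fit_stump(X: np.ndarray, y: np.ndarray, w: np.ndarray,
               subset: np.ndarray) -> dict:
    """Exhaustive minimum-weighted-error decision stump.

    Scans features in index order, candidate thresholds (midpoints of
    consecutive sorted unique values, plus one below the minimum) in
    ascending order and both leaf polarities; keeps the first strict
    minimum, so tie-breaking is fully deterministic.
    """
    best = None  # (error, feature, threshold, left_cls, right_cls)
    for f in subset:
        x = X[:, f]
        uniq = np.unique(x)
        thresholds = [uniq[0] - 1.0]
        thresholds += [(uniq[i] + uniq[i + 1]) / 2.0 for i in range(len(uniq) - 1)]
        for thr in thresholds:
            left = x <= thr
            for left_cls in (0, 1):
                pred = np.where(left, left_cls, 1 - left_cls)
                err = float(w[pred != y].sum())
                if best is None or err < best[0] - 1e-15:
                    best = (err, int(f), float(thr), left_cls, 1 - left_cls)
    assert best is not None
    _, f, thr, lc, rc = best
    return {"feature": f, "threshold": thr,
            "left": {"leaf": lc}, "right": {"leaf": rc}}


def _predict_nodes(node: dict, X: np.ndarray) -> np.ndarray:
    """Evaluate a nested node record over a sample matrix."""
    out = np.empty(X.shape[0], dtype=int)
    idx = np.arange(X.shape[0])
    stack = [(node, idx)]
    while stack:
        nd, rows = stack.pop()
        if rows.size == 0:
            continue
        if "leaf" in nd:
            out[rows] = nd["leaf"]
            continue
        go_left = X[rows, nd["feature"]] <= nd["threshold"]
        stack.append((nd["left"], rows[go_left]))
        stack.append((nd["right"], rows[~go_left]))
    return out


def _node_depth(node: dict) -> int:
    if "leaf" in node:
        return 0
    return 1 + max(_node_depth(node["left"]), _node_depth(node["right"]))


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """Weighted collection of shallow trees; classes {0 non-faulty, 1 faulty}."""

    trees: list[dict]
    alphas: np.ndarray
    n_features: int
    feature_names: list[str] = field(default_factory=list)
    params: BoostParams | None = None

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        if len(self.trees) != len(self.alphas):
            raise ValueError("one alpha per learner required")
        if not np.all(np.isfinite(self.alphas)):
            raise ValueError("alphas must be finite")

    def decision_scores(self, X) -> np.ndarray:
        X = _as_matrix(X, self.n_features)
        score = np.zeros(X.shape[0])
        for node, alpha in zip(self.trees, self.alphas):
            score += alpha * (2 * _predict_nodes(node, X) - 1)
        return score

    def predict(self, X) -> np.ndarray:
        """Weighted-vote labels; a zero score falls to class 0 (non-faulty)."""
        return (self.decision_scores(X) > 0).astype(int)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "trees": self.trees,
            "alphas": self.alphas.tolist(),
            "n_features": self.n_features,
            "feature_names": self.feature_names,
            "params": asdict(self.params) if self.params else None,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EnsembleModel":
        p = Path(source)
        doc = json.loads(p.read_text() if p.exists() else str(source))
        params = BoostParams(**{k: tuple(v) if k == "split" else v
                                for k, v in doc["params"].items()}) \
            if doc.get("params") else None
        return cls(
            trees=doc["trees"],
            alphas=np.asarray(doc["alphas"]),
            n_features=int(doc["n_features"]),
            feature_names=list(doc.get("feature_names", [])),
            params=params,
        )


def _as_matrix(X, n_features: int | None = None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"feature matrix must be 2-D, got shape {X.shape}")
    if n_features is not None and X.shape[1] != n_features:
        raise ValueError(
            f"feature dimensionality {X.shape[1]} != model's {n_features}"
        )
    return X


def _round_subset(seed: int, t: int, retry: int, d: int, k: int) -> np.ndarray:
    rng = np.random.default_rng([seed, t, retry])
    return np.sort(rng.choice(d, size=k, replace=False))


def train_adaboost(
    X,
    y,
    params: BoostParams | None = None,
) -> EnsembleModel:
    """Fit the discrete AdaBoost ensemble.

    Raises
    ------
    DegenerateLabelsError
        If the labels contain a single class.
    """
    params = params or BoostParams()
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else []
    X = _as_matrix(X)
    y = np.asarray(y, dtype=int)
    n, d = X.shape
    if n < 2:
        raise InsufficientDataError("need at least 2 training samples")
    if np.unique(y).size < 2:
        raise DegenerateLabelsError("training labels contain a single class")
    k = params.subset_size(d)

    w = np.full(n, 1.0 / n)
    trees: list[dict] = []
    alphas: list[float] = []
    for t in range(params.n_learners):
        node, err = _fit_round(X, y, w, params, t, retry=0, k=k)
        if err >= 0.5:
            node, err = _fit_round(X, y, w, params, t, retry=1, k=k)
            if err >= 0.5:
                break  # redrawn subset no better: stop boosting
        err_c = min(max(err, _EPS_ERR), 1.0 - _EPS_ERR)
        alpha = params.learning_rate * np.log((1.0 - err_c) / err_c)
        trees.append(node)
        alphas.append(float(alpha))
        if err == 0.0:
            break  # perfect learner: keep it and stop
        pred = _predict_nodes(node, X)
        w = w * np.where(pred != y, np.exp(alpha), 1.0)
        w /= w.sum()
    return EnsembleModel(trees=trees, alphas=np.asarray(alphas),
                         n_features=d, feature_names=feature_names,
                         params=params)


def _fit_round(X, y, w, params: BoostParams, t: int, retry: int,
               k: int) -> tuple[dict, float]:
    subset = _round_subset(params.seed, t, retry, X.shape[1], k)
    if params.base_learner == "stump":
        node = _fit_stump(X, y, w, subset)
    else:
        learner = DecisionTreeClassifier(
            max_depth=params.max_depth,
            random_state=int(np.random.default_rng([params.seed, t, retry, 1])
                             .integers(2**31)),
        )
        learner.fit(X[:, subset], y, sample_weight=w)
        node = _sklearn_tree_to_nodes(learner, subset)
    pred = _predict_nodes(node, X)
    return node, float(w[pred != y].sum())


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Confusion matrix and the three headline metrics, positive = faulty.

    Ratios with a zero denominator are NaN and flagged in ``undefined``,
    never silently zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")

    @property
    def undefined(self) -> list[str]:
        flags = []
        if self.tp + self.fn == 0:
            flags.append("sensitivity")
        if self.tn + self.fp == 0:
            flags.append("specificity")
        if self.n == 0:
            flags.append("accuracy")
        return flags

    def as_row(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "undefined": ";".join(self.undefined),
        }


def evaluate_predictions(y_true, y_pred) -> EvaluationReport:
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must align")
    return EvaluationReport(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def evaluate(model: EnsembleModel, X_test, y_test) -> EvaluationReport:
    """Confusion matrix and metrics of a fitted model on a held-out set."""
    X_test = _as_matrix(X_test, model.n_features)
    if X_test.shape[0] == 0:
        raise InsufficientDataError("test set is empty")
    return evaluate_predictions(y_test, model.predict(X_test))


def cross_validate(
    X,
    y,
    params: BoostParams | None = None,
    k: int = 5,
) -> EvaluationReport:
    """Stratified k-fold cross-validation aggregating out-of-fold predictions.

    With small cohorts a held-out 5% test split is a handful of subjects,
    so per-parameter metrics are reported from pooled out-of-fold
    predictions instead.
    """
    from sklearn.model_selection import StratifiedKFold

    params = params or BoostParams()
    X = _as_matrix(X)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise DegenerateLabelsError("both classes required for cross-validation")
    k = min(k, int(np.bincount(y).min()))
    if k < 2:
        raise InsufficientDataError("minority class too small for cross-validation")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=params.seed)
    pred = np.empty_like(y)
    for train_idx, test_idx in skf.split(X, y):
        model = train_adaboost(X[train_idx], y[train_idx], params)
        pred[test_idx] = model.predict(X[test_idx])
    return evaluate_predictions(y, pred)
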