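"""Variant classification from error patterns.

A depth-limited decision tree (greedy binary splits minimizing weighted
Gini impurity) classifies patients into the three PPA variants from their
three error-type percentages. The clinically interpretable depth limit of
2 means at most two questions separate any patient from a diagnosis.
Significance is assessed against an empirical chance distribution: labels
are permuted and the full cross-validated score recomputed, giving
``p = (1 + #{null >= observed}) / (1 + n_perm)``. The theoretical chance
level for three balanced classes is 1/3.

The tree is implemented here (not wrapped) because its determinism rules
are part of the contract: split thresholds are midpoints of consecutive
sorted unique feature values, equal-impurity splits resolve to the lowest
threshold of the earliest feature, and leaf ties resolve to the
lexicographically first class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .coding import SubjectProfile

#: Feature columns used for classification. Accuracy is the linear
#: complement of the three error percentages and is deliberately excluded.
FEATURE_COLUMNS: tuple[str, ...] = ("pct_not_verb", "pct_unrelated_verb", "pct_missing")


@dataclass
class TreeNode:
    """One node of the fitted tree; leaves have ``feature is None``."""

    n: int
    probs: np.ndarray  # class-probability vector, sums to 1
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self, feature_names: Sequence[str] | None = None) -> dict:
        if self.is_leaf:
            return {"leaf": True, "n": int(self.n), "probs": self.probs.tolist()}
        name = feature_names[self.feature] if feature_names else self.feature
        return {
            "leaf": False, "n": int(self.n), "feature": name,
            "threshold": float(self.threshold),
            "left": self.left.to_dict(feature_names),
            "right": self.right.to_dict(feature_names),
        }


def _gini_of_counts(counts: np.ndarray, n: int) -> float:
    return 1.0 - float(np.sum((counts / n) ** 2))


def _best_split(X: np.ndarray, y: np.ndarray, n_classes: int
                ) -> tuple[int, float] | None:
    """Exact search for the (feature, threshold) minimizing weighted Gini.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values. Features are scanned in order and thresholds ascending; a new
    candidate replaces the incumbent only when strictly better, which
    realizes the lowest-threshold / earliest-feature tie-break.
    """
    n = len(y)
    onehot = np.eye(n_classes, dtype=float)[y]
    best: tuple[float, int, float] | None = None  # (impurity, feature, threshold)
    for f in range(X.shape[1]):
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        boundaries = np.nonzero(xs[1:] > xs[:-1])[0]  # split after index i
        if boundaries.size == 0:
            continue
        cum = np.cumsum(onehot[order], axis=0)
        total = cum[-1]
        nl = (boundaries + 1).astype(float)
        nr = n - nl
        left = cum[boundaries]
        right = total - left
        gini_l = 1.0 - np.sum((left / nl[:, None]) ** 2, axis=1)
        gini_r = 1.0 - np.sum((right / nr[:, None]) ** 2, axis=1)
        weighted = (nl * gini_l + nr * gini_r) / n
        thresholds = (xs[boundaries] + xs[boundaries + 1]) / 2.0
        i = int(np.argmin(weighted))  # argmin returns the first = lowest threshold
        if best is None or weighted[i] < best[0]:
            best = (float(weighted[i]), f, float(thresholds[i]))
    if best is None:
        return None
    return best[1], best[2]


class DecisionTree:
    """Greedy Gini decision tree with a hard depth limit (default 2)."""

    def __init__(self, max_depth: int = 2):
        if max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        self.max_depth = max_depth
        self.classes_: np.ndarray | None = None
        self.root: TreeNode | None = None

    def _build(self, X: np.ndarray, y: np.ndarray, depth: int) -> TreeNode:
        n = len(y)
        counts = np.bincount(y, minlength=len(self.classes_)).astype(float)
        node = TreeNode(n=n, probs=counts / n)
        pure = np.max(counts) == n
        if depth >= self.max_depth or pure or n < 2:
            return node
        split = _best_split(X, y, len(self.classes_))
        if split is None:  # constant features with mixed labels
            return node
        f, thr = split
        mask = X[:, f] <= thr
        node.feature = f
        node.threshold = thr
        node.left = self._build(X[mask], y[mask], depth + 1)
        node.right = self._build(X[~mask], y[~mask], depth + 1)
        return node

    def fit(self, X: np.ndarray, y: Sequence) -> "DecisionTree":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        if len(y) < 1:
            raise ValueError("empty training set")
        self.classes_, y_codes = np.unique(np.asarray(y), return_inverse=True)
        self.root = self._build(X, y_codes, depth=0)
        return self

    def _route(self, x: np.ndarray) -> TreeNode:
        node = self.root
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.root is None:
            raise ValueError("tree not fitted")
        X = np.asarray(X, dtype=float)
        return np.array([self._route(x).probs for x in X])

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        # argmax takes the first maximum: lexicographically first class on ties
        return self.classes_[np.argmax(proba, axis=1)]

    def depth(self) -> int:
        def _d(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))
        return _d(self.root)

    def to_dict(self, feature_names: Sequence[str] | None = None) -> dict:
        return {
            "max_depth": self.max_depth,
            "classes": [str(c) for c in self.classes_],
            "root": self.root.to_dict(feature_names),
        }


@dataclass
class ClassificationResult:
    """Observed CV score against its permutation null distribution."""

    cv_mean: float
    cv_sd: float
    null_scores: np.ndarray
    p_empirical: float
    chance_theoretical: float
    n_perm: int
    seed: int
    k_folds: int
    tree: DecisionTree | None = field(default=None, repr=False)

    @property
    def null_95th(self) -> float:
        return float(np.percentile(self.null_scores, 95))


def build_feature_matrix(profiles: Sequence[SubjectProfile]
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """Error-percentage feature matrix and variant labels (HC rows dropped)."""
    rows = []
    labels = []
    for p in profiles:
        if p.group == "HC":
            continue
        rows.append({"subject_id": p.subject_id,
                     "pct_not_verb": p.pct_not_verb,
                     "pct_unrelated_verb": p.pct_unrelated_verb,
                     "pct_missing": p.pct_missing})
        labels.append(p.group)
    X = pd.DataFrame(rows).set_index("subject_id") if rows else pd.DataFrame(
        columns=list(FEATURE_COLUMNS))
    return X, np.asarray(labels)


def fit_tree(X: np.ndarray | pd.DataFrame, y: Sequence, max_depth: int = 2
             ) -> DecisionTree:
    """Fit the depth-limited Gini tree on the full data."""
    X = np.asarray(X, dtype=float)
    if len(np.unique(np.asarray(y))) < 2:
        # pure-label input: a single majority leaf
        pass
    return DecisionTree(max_depth=max_depth).fit(X, y)


def _effective_k(y: np.ndarray, k_folds: int) -> int:
    smallest = int(np.min(np.bincount(np.unique(y, return_inverse=True)[1])))
    if smallest < k_folds:
        warnings.warn(f"smallest class has {smallest} members; reducing folds "
                      f"from {k_folds} to {smallest}")
        return max(2, smallest)
    return k_folds


def _cv_scores(X: np.ndarray, y: np.ndarray, k: int, max_depth: int,
               random_state: int) -> np.ndarray:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=random_state)
    scores = np.empty(k)
    for i, (train, test) in enumerate(skf.split(X, y)):
        tree = DecisionTree(max_depth=max_depth).fit(X[train], y[train])
        scores[i] = float(np.mean(tree.predict(X[test]) == y[test]))
    return scores


def cross_validated_score(X: np.ndarray | pd.DataFrame, y: Sequence,
                          k_folds: int = 5, seed: int = 0, max_depth: int = 2
                          ) -> tuple[float, float]:
    """Stratified k-fold accuracy of the tree: (mean, SD over folds)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    k = _effective_k(y, k_folds)
    scores = _cv_scores(X, y, k, max_depth, random_state=seed)
    return float(scores.mean()), float(scores.std(ddof=0))


def permutation_test(X: np.ndarray | pd.DataFrame, y: Sequence,
                     n_perm: int = 1000, k_folds: int = 5, seed: int = 0,
                     max_depth: int = 2) -> ClassificationResult:
    """Label-permutation estimate of the classifier's chance level.

    Each permutation shuffles the labels and recomputes the full stratified
    CV score; the empirical p includes the observed score in the tally, so
    its minimum is ``1 / (n_perm + 1)``. Identical seeds give identical
    folds, permutations, and scores.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: empirical p will be unstable")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    k = _effective_k(y, k_folds)
    rng = np.random.default_rng(seed)
    observed = _cv_scores(X, y, k, max_depth, random_state=seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        rs = int(rng.integers(0, 2**31 - 1))
        null[i] = _cv_scores(X, y_perm, k, max_depth, random_state=rs).mean()
    cv_mean = float(observed.mean())
    p_emp = (1.0 + float(np.sum(null >= cv_mean))) / (1.0 + n_perm)
    tree = DecisionTree(max_depth=max_depth).fit(X, y)
    return ClassificationResult(
        cv_mean=cv_mean, cv_sd=float(observed.std(ddof=0)), null_scores=null,
        p_empirical=p_emp, chance_theoretical=1.0 / len(np.unique(y)),
        n_perm=n_perm, seed=seed, k_folds=k, tree=tree,
    )
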