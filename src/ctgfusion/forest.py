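"""Stage IV: tree ensembles in deterministic and probabilistic modes.

Both modes grow ``n_estimators`` CART trees (Gini impurity, depth-capped)
on independent bootstrap resamples whose index multisets are recorded, so
out-of-bag (OOB) class probabilities can be captured exactly: each training
sample is scored by averaging only the trees whose bootstrap omitted it.

The probabilistic mode (PRF) treats feature values as uncertain rather
than fixed:

* each tree's bootstrap is augmented with a fraction
  (``new_syn_data_frac``) of jittered copies of existing rows, with noise
  scaled by the per-feature median absolute deviation (MAD);
* at prediction time a sample traverses *both* children of every split,
  with branch probabilities given by a logistic function of the signed
  distance to the threshold (scale = ``softness`` x feature MAD); paths
  whose cumulative probability falls below the ``keep_proba`` floor are
  pruned and the surviving mass renormalized.

With ``keep_proba = 1``, zero softness and no augmentation, the
probabilistic traversal degenerates exactly, tree for tree, to the
deterministic forest.

Tree induction itself is delegated to scikit-learn's
``DecisionTreeClassifier``; the fitted trees are immediately converted to
a plain array representation on which both traversal modes (and the JSON
serialization) operate, so predictions never depend on scikit-learn
internals.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.special import expit
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ForestHyper",
    "TreeArrays",
    "ForestModel",
    "OOBEstimate",
    "fit_forest",
    "predict_proba",
    "oob_proba",
]

_MODES = ("deterministic", "probabilistic")


@dataclass(frozen=True)
class ForestHyper:
    """Forest hyperparameters.

    ``keep_proba`` is the path-probability pruning floor of the soft
    traversal and ``new_syn_data_frac`` the per-tree augmented-sample
    fraction; both only matter in probabilistic mode.  ``softness`` scales
    the per-feature MAD into the logistic branch-probability scale.
    """

    n_estimators: int = 25
    max_depth: int = 10
    mode: str = "deterministic"
    keep_proba: float = 0.05
    softness: float = 0.3
    new_syn_data_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if not 0 < self.keep_proba <= 1:
            raise ValueError("keep_proba must be in (0, 1]")
        if not 0 <= self.new_syn_data_frac < 1:
            raise ValueError("new_syn_data_frac must be in [0, 1)")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.softness < 0:
            raise ValueError("softness must be >= 0")


@dataclass
class TreeArrays:
    """Array representation of one fitted tree.

    ``feature[i] < 0`` marks node ``i`` as a leaf; internal nodes route
    ``x[feature] <= threshold`` to ``left``.  ``value`` holds each node's
    class-frequency distribution (rows sum to 1).
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray

    def hard_leaf_distribution(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = self.feature[node] >= 0
        while np.any(active):
            idx = np.flatnonzero(active)
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.left[nd], self.right[nd])
            active = self.feature[node] >= 0
        return self.value[node]

    def soft_distribution(
        self, X: np.ndarray, scale: np.ndarray, keep_proba: float
    ) -> np.ndarray:
        """Soft traversal: samples follow both children with logistic branch
        probabilities; paths below the ``keep_proba`` floor are pruned and
        the kept mass renormalized.  Samples whose paths are all pruned
        fall back to the hard traversal."""
        n, k = X.shape[0], self.value.shape[1]
        out = np.zeros((n, k))
        mass = np.zeros(n)
        stack = [(0, np.arange(n), np.ones(n))]
        while stack:
            node, idx, prob = stack.pop()
            f = self.feature[node]
            if f < 0:
                out[idx] += prob[:, None] * self.value[node]
                mass[idx] += prob
                continue
            s = scale[f]
            if s > 0:
                p_left = expit((self.threshold[node] - X[idx, f]) / s)
            else:
                p_left = (X[idx, f] <= self.threshold[node]).astype(float)
            for child, p in ((self.left[node], prob * p_left),
                             (self.right[node], prob * (1.0 - p_left))):
                keep = p >= keep_proba
                if np.any(keep):
                    stack.append((int(child), idx[keep], p[keep]))
        covered = mass > 0
        out[covered] /= mass[covered, None]
        if not np.all(covered):
            out[~covered] = self.hard_leaf_distribution(X[~covered])
        return out


@dataclass
class ForestModel:
    """Fitted ensemble with recorded bootstraps and feature dispersions."""

    trees: list[TreeArrays]
    bootstrap_indices: list[np.ndarray]
    classes_: np.ndarray
    hyper: ForestHyper
    feature_mad: np.ndarray
    n_features: int
    training_checksum: str

    # -- JSON round trip ---------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "hyper": self.hyper.__dict__,
            "classes": self.classes_.tolist(),
            "n_features": self.n_features,
            "feature_mad": self.feature_mad.tolist(),
            "training_checksum": self.training_checksum,
            "bootstrap_indices": [b.tolist() for b in self.bootstrap_indices],
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "value": t.value.tolist(),
                }
                for t in self.trees
            ],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ForestModel":
        trees = [
            TreeArrays(
                feature=np.asarray(t["feature"], dtype=np.int64),
                threshold=np.asarray(t["threshold"], dtype=float),
                left=np.asarray(t["left"], dtype=np.int64),
                right=np.asarray(t["right"], dtype=np.int64),
                value=np.asarray(t["value"], dtype=float),
            )
            for t in d["trees"]
        ]
        return cls(
            trees=trees,
            bootstrap_indices=[np.asarray(b, dtype=np.int64)
                               for b in d["bootstrap_indices"]],
            classes_=np.asarray(d["classes"]),
            hyper=ForestHyper(**d["hyper"]),
            feature_mad=np.asarray(d["feature_mad"], dtype=float),
            n_features=int(d["n_features"]),
            training_checksum=d["training_checksum"],
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict()))

    @classmethod
    def load(cls, path) -> "ForestModel":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


def _checksum(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()


def _convert_tree(clf: DecisionTreeClassifier, tree_classes: np.ndarray,
                  global_classes: np.ndarray) -> TreeArrays:
    t = clf.tree_
    counts = t.value[:, 0, :] * t.weighted_n_node_samples[:, None]
    dist = counts / counts.sum(axis=1, keepdims=True)
    # map the tree's (possibly reduced) class set into the global class order
    value = np.zeros((dist.shape[0], global_classes.size))
    col = {c: j for j, c in enumerate(global_classes.tolist())}
    for i, c in enumerate(tree_classes.tolist()):
        value[:, col[c]] = dist[:, i]
    return TreeArrays(
        feature=t.feature.astype(np.int64),
        threshold=t.threshold.astype(float),
        left=t.children_left.astype(np.int64),
        right=t.children_right.astype(np.int64),
        value=value,
    )


def fit_forest(X, y, hyper: ForestHyper | None = None) -> ForestModel:
    """Grow the ensemble on bootstrap resamples of the training set.

    In probabilistic mode each bootstrap is augmented with
    ``new_syn_data_frac * n`` MAD-jittered copies of its own rows before
    the tree is grown.  Fully deterministic given ``hyper.seed``.

    Raises
    ------
    ValueError
        On NaN inputs or a single-class label vector.
    """
    hyper = hyper or ForestHyper()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D and aligned with y")
    if np.isnan(X).any():
        raise ValueError("X contains NaN")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    n, d = X.shape
    mad = np.median(np.abs(X - np.median(X, axis=0)), axis=0)
    rng = np.random.default_rng(hyper.seed)
    trees, bootstraps = [], []
    for _ in range(hyper.n_estimators):
        boot = rng.integers(0, n, n)
        Xb, yb = X[boot], y[boot]
        if hyper.mode == "probabilistic" and hyper.new_syn_data_frac > 0:
            m = int(round(hyper.new_syn_data_frac * n))
            if m > 0:
                sel = rng.integers(0, n, m)
                noise = rng.standard_normal((m, d)) * mad
                Xb = np.vstack([Xb, Xb[sel] + noise])
                yb = np.concatenate([yb, yb[sel]])
        clf = DecisionTreeClassifier(
            criterion="gini",
            max_depth=hyper.max_depth,
            random_state=int(rng.integers(2**31)),
        ).fit(Xb, yb)
        trees.append(_convert_tree(clf, clf.classes_, classes))
        bootstraps.append(boot)
    return ForestModel(
        trees=trees,
        bootstrap_indices=bootstraps,
        classes_=classes,
        hyper=hyper,
        feature_mad=mad,
        n_features=d,
        training_checksum=_checksum(X, y),
    )


def _tree_distribution(model: ForestModel, tree: TreeArrays, X: np.ndarray) -> np.ndarray:
    if model.hyper.mode == "probabilistic":
        scale = model.hyper.softness * model.feature_mad
        return tree.soft_distribution(X, scale, model.hyper.keep_proba)
    return tree.hard_leaf_distribution(X)


def predict_proba(model: ForestModel, X) -> np.ndarray:
    """Class-probability matrix (rows sum to 1) in the global class order.

    Raises
    ------
    ValueError
        If the column count differs from training.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} feature columns, got {X.shape}"
        )
    acc = np.zeros((X.shape[0], model.classes_.size))
    for tree in model.trees:
        acc += _tree_distribution(model, tree, X)
    acc /= len(model.trees)
    return acc / acc.sum(axis=1, keepdims=True)


@dataclass
class OOBEstimate:
    """Out-of-bag probabilities for the training samples.

    ``proba`` rows are NaN where ``covered`` is False (no tree omitted the
    sample); covered rows sum to 1.
    """

    proba: np.ndarray
    covered: np.ndarray
    n_trees_omitting: np.ndarray


def oob_proba(model: ForestModel, X, y) -> OOBEstimate:
    """Average each training sample over exactly the trees that omitted it.

    Raises
    ------
    ValueError
        If (X, y) are not the data the model was fitted on.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if _checksum(X, y) != model.training_checksum:
        raise ValueError("oob_proba must be called with the model's training data")
    n = X.shape[0]
    k = model.classes_.size
    acc = np.zeros((n, k))
    count = np.zeros(n, dtype=int)
    for tree, boot in zip(model.trees, model.bootstrap_indices):
        in_bag = np.bincount(boot, minlength=n) > 0
        oob = ~in_bag
        if not np.any(oob):
            continue
        acc[oob] += _tree_distribution(model, tree, X[oob])
        count[oob] += 1
    covered = count > 0
    proba = np.full((n, k), np.nan)
    proba[covered] = acc[covered] / count[covered, None]
    proba[covered] /= proba[covered].sum(axis=1, keepdims=True)
    return OOBEstimate(proba=proba, covered=covered, n_trees_omitting=count)
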