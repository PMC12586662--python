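"""Stage III/IV support: random undersampling and stratified k-fold plans.

Undersampling draws, per class, exactly the minority-class count of samples
uniformly without replacement; it is applied to training folds only so the
test folds keep the cohort's natural class proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = ["FoldPlan", "random_undersample", "stratified_kfold"]


@dataclass
class FoldPlan:
    """A stratified partition: per-fold test index sets plus provenance."""

    k: int
    test_indices: list[np.ndarray]
    seed: int
    n_samples: int

    def train_indices(self, fold: int) -> np.ndarray:
        test = set(self.test_indices[fold].tolist())
        return np.array([i for i in range(self.n_samples) if i not in test])

    def iter_folds(self):
        for fold in range(self.k):
            yield self.train_indices(fold), self.test_indices[fold]


def random_undersample(labels, seed: int = 0) -> np.ndarray:
    """Indices of a class-balanced subsample (minority-count per class).

    Every class retains exactly the minority class's count, drawn uniformly
    without replacement; the returned indices are sorted and deterministic
    given the seed.

    Raises
    ------
    ValueError
        With fewer than two classes present.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("undersampling requires at least two classes")
    m = int(counts.min())
    rng = np.random.default_rng(seed)
    keep = [
        rng.choice(np.flatnonzero(labels == c), size=m, replace=False)
        for c in classes
    ]
    return np.sort(np.concatenate(keep))


def stratified_kfold(labels, k: int = 3, seed: int = 0) -> FoldPlan:
    """Shuffled stratified k-fold plan over the label sequence.

    Test sets partition the index set and per-fold class counts deviate
    from exact proportionality by less than one sample (e.g. class counts
    351/114/37 at k=3 give test supports (117,38,13), (117,38,12),
    (117,38,12)).

    Raises
    ------
    ValueError
        If ``k < 2`` or any class has fewer than ``k`` members.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    if int(counts.min()) < k:
        small = classes[np.argmin(counts)]
        raise ValueError(f"class {small!r} has fewer than k={k} members")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    test_sets = [test for _, test in splitter.split(np.zeros(labels.size), labels)]
    return FoldPlan(k=k, test_indices=test_sets, seed=seed, n_samples=labels.size)
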