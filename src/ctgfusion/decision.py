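"""Stage IV/V: probability fusion, the lambda decision rule and its tuning.

The deterministic and probabilistic forests each emit a class-probability
triple (Normal, Suspicious, Pathological); the two are combined by
weighted addition.  Decisions then follow a *threshold moving* rule: when
Normal holds the strict maximum probability the case is Normal; otherwise
the Suspicious-vs-Pathological margin ``p_S - p_P`` is compared against a
threshold lambda — Suspicious only when the margin exceeds lambda, else
Pathological.  At lambda = 0 the rule reduces to plain argmax; raising
lambda trades Suspicious predictions for Pathological ones, which is the
clinically conservative direction.

Lambda is tuned on out-of-bag predictions by maximizing
``f_score = weighted Cohen's kappa + precision(Pathological)``, a
chance-corrected agreement term plus a term rewarding trustworthy
Pathological calls.  Grid ties break toward the largest lambda (the most
Pathological-favoring setting among equals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import cohen_kappa, confusion_matrix
from .signal_io import ClassLabel

__all__ = [
    "DecisionPolicy",
    "ThresholdSearchResult",
    "default_grid",
    "fuse",
    "decide",
    "f_score",
    "optimize_threshold",
]


def default_grid() -> np.ndarray:
    """The 12-point lambda grid 0.00, 0.04, ..., 0.44."""
    return np.round(np.arange(12) * 0.04, 2)


def fuse(p_rf, p_prf, w: float = 0.5) -> np.ndarray:
    """Weighted addition ``w * p_rf + (1 - w) * p_prf``, renormalized.

    Accepts single probability triples or matrices of them.

    Raises
    ------
    ValueError
        If ``w`` lies outside [0, 1] or the inputs are off the simplex.
    """
    if not 0 <= w <= 1:
        raise ValueError("fusion weight w must be in [0, 1]")
    a = np.asarray(p_rf, dtype=float)
    b = np.asarray(p_prf, dtype=float)
    if a.shape != b.shape:
        raise ValueError("probability inputs must share a shape")
    for p in (a, b):
        if np.any(p < -1e-9) or np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-6):
            raise ValueError("inputs must lie on the probability simplex")
    out = w * a + (1.0 - w) * b
    return out / out.sum(axis=-1, keepdims=True)


def decide(P, lam: float):
    """Apply the lambda rule to one triple or a matrix of triples.

    Normal requires the strict maximum (Normal-vs-rest ties resolve away
    from Normal, severity first); otherwise Suspicious iff
    ``p_S - p_P > lam``, else Pathological.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    P = np.asarray(P, dtype=float)
    single = P.ndim == 1
    P2 = P[None, :] if single else P
    pn, ps, pp = P2[:, 0], P2[:, 1], P2[:, 2]
    labels = np.where(
        (pn > ps) & (pn > pp),
        int(ClassLabel.NORMAL),
        np.where(ps - pp > lam, int(ClassLabel.SUSPICIOUS),
                 int(ClassLabel.PATHOLOGICAL)),
    )
    return ClassLabel(int(labels[0])) if single else labels


def f_score(y_true, y_pred, kappa_weighting: str = "linear") -> float:
    """Threshold-search objective: weighted kappa + Pathological precision.

    Kappa uses linear ordinal weights over Normal < Suspicious <
    Pathological by default; Pathological precision is 0 when no
    Pathological predictions exist.  Bounded above by 2.

    Raises
    ------
    ValueError
        On length mismatch or empty input.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be aligned and non-empty")
    cm = confusion_matrix(y_true, y_pred)
    kappa = cohen_kappa(cm, weighting=kappa_weighting)
    p = int(ClassLabel.PATHOLOGICAL)
    predicted_p = cm.counts[p, :].sum()
    precision = cm.counts[p, p] / predicted_p if predicted_p > 0 else 0.0
    return float(kappa + precision)


@dataclass(frozen=True)
class DecisionPolicy:
    """Fusion weight and margin threshold defining the decision rule."""

    w: float = 0.5
    lam: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.w <= 1:
            raise ValueError("w must be in [0, 1]")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")

    def apply(self, p_rf, p_prf):
        return decide(fuse(p_rf, p_prf, self.w), self.lam)


@dataclass
class ThresholdSearchResult:
    """Lambda grid, objective value per lambda, and the tie-aware winner."""

    grid: np.ndarray
    scores: np.ndarray
    best_lambda: float
    ties: np.ndarray  # all grid values attaining the maximum score


def optimize_threshold(
    oob_probs,
    y_oob,
    grid=None,
    kappa_weighting: str = "linear",
) -> ThresholdSearchResult:
    """Grid-search lambda on fused out-of-bag probabilities.

    Every lambda in the grid is scored with :func:`f_score` against the
    out-of-bag labels; the winner maximizes the score, with ties broken
    toward the largest lambda.

    Raises
    ------
    ValueError
        On an empty covered set or empty grid.
    """
    P = np.asarray(oob_probs, dtype=float)
    y = np.asarray(y_oob)
    if P.ndim != 2 or P.shape[0] == 0:
        raise ValueError("no covered out-of-bag samples to tune on")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    scores = np.array([f_score(y, decide(P, lam), kappa_weighting) for lam in grid])
    ties = grid[scores >= scores.max() - 1e-12]
    return ThresholdSearchResult(
        grid=grid, scores=scores, best_lambda=float(ties.max()), ties=ties
    )
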