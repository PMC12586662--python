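"""Evaluation artifacts: confusion matrices, classification reports,
Cohen's kappa and the Friedman/Iman-Davenport method comparison.

Confusion matrices use the orientation rows = predicted, columns = true
(an explicit field records this), with the fixed class order Normal,
Suspicious, Pathological.  Reports display values rounded half-up to two
decimals while retaining full precision internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

from .signal_io import ClassLabel

__all__ = [
    "ConfusionMatrix",
    "ClassificationReport",
    "ImanDavenportResult",
    "confusion_matrix",
    "report",
    "cohen_kappa",
    "iman_davenport",
]

CLASS_NAMES = tuple(c.display for c in ClassLabel)


@dataclass
class ConfusionMatrix:
    """3x3 counts with rows = predicted label, columns = true label."""

    counts: np.ndarray
    orientation: str = "rows=predicted, columns=true"
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.class_names),) * 2:
            raise ValueError("confusion matrix must be square over the classes")
        if np.any(self.counts < 0):
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def supports(self) -> np.ndarray:
        """Per-class true counts (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    """Tally ``counts[pred, true]`` over the three classes.

    Raises
    ------
    ValueError
        On a label outside {0, 1, 2} or misaligned inputs.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be aligned")
    k = len(ClassLabel)
    if np.any((y_true < 0) | (y_true >= k)) or np.any((y_pred < 0) | (y_pred >= k)):
        raise ValueError("labels must be in {0, 1, 2}")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (y_pred, y_true), 1)
    return ConfusionMatrix(counts=counts)


def _round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ClassificationReport:
    """Per-class precision/recall/F1/support plus accuracy and averages."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    class_names: tuple[str, ...] = CLASS_NAMES

    def rounded(self) -> dict:
        """Display form: half-up rounding to two decimals."""
        out = {
            name: {
                "precision": _round2(self.precision[i]),
                "recall": _round2(self.recall[i]),
                "f1": _round2(self.f1[i]),
                "support": int(self.support[i]),
            }
            for i, name in enumerate(self.class_names)
        }
        out["accuracy"] = _round2(self.accuracy)
        out["macro avg"] = {
            "precision": _round2(self.macro_precision),
            "recall": _round2(self.macro_recall),
            "f1": _round2(self.macro_f1),
        }
        out["weighted avg"] = {
            "precision": _round2(self.weighted_precision),
            "recall": _round2(self.weighted_recall),
            "f1": _round2(self.weighted_f1),
        }
        return out

    def to_text(self) -> str:
        r = self.rounded()
        lines = [f"{'':<14}{'precision':>10}{'recall':>8}{'f1':>8}{'support':>9}"]
        for name in self.class_names:
            c = r[name]
            lines.append(
                f"{name:<14}{c['precision']:>10.2f}{c['recall']:>8.2f}"
                f"{c['f1']:>8.2f}{c['support']:>9d}"
            )
        lines.append(f"{'accuracy':<14}{'':>10}{'':>8}{r['accuracy']:>8.2f}"
                     f"{int(self.support.sum()):>9d}")
        for key in ("macro avg", "weighted avg"):
            c = r[key]
            lines.append(
                f"{key:<14}{c['precision']:>10.2f}{c['recall']:>8.2f}"
                f"{c['f1']:>8.2f}{int(self.support.sum()):>9d}"
            )
        return "\n".join(lines)


def report(cm: ConfusionMatrix) -> ClassificationReport:
    """Classification report from a confusion matrix.

    Precision divides the diagonal by the prediction (row) sum, recall by
    the true (column) sum; zero denominators yield 0.  Weighted averages
    are support-weighted; macro averages are unweighted class means.

    Raises
    ------
    ValueError
        On an all-zero matrix.
    """
    c = cm.counts.astype(float)
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(c)
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(row > 0, diag / np.where(row > 0, row, 1), 0.0)
        recall = np.where(col > 0, diag / np.where(col > 0, col, 1), 0.0)
    denom = precision + recall
    f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    support = col
    w = support / total
    return ClassificationReport(
        precision=precision,
        recall=recall,
        f1=f1,
        support=support.astype(int),
        accuracy=float(diag.sum() / total),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        weighted_precision=float(np.sum(w * precision)),
        weighted_recall=float(np.sum(w * recall)),
        weighted_f1=float(np.sum(w * f1)),
    )


def cohen_kappa(cm: ConfusionMatrix, weighting: str = "none") -> float:
    """Chance-corrected agreement from a confusion matrix.

    ``weighting`` selects the disagreement weight matrix: ``none``
    (0/1 off-diagonal), ``linear`` (|i - j|) or ``quadratic`` ((i - j)^2)
    over the ordinal class order.  Degenerate marginals (expected
    agreement 1) return 0 with a warning.
    """
    c = cm.counts.astype(float)
    n = c.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    k = c.shape[0]
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    if weighting == "none":
        w = (i != j).astype(float)
    elif weighting == "linear":
        w = np.abs(i - j).astype(float)
    elif weighting == "quadratic":
        w = (i - j).astype(float) ** 2
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    observed = c / n
    expected = np.outer(c.sum(axis=1), c.sum(axis=0)) / n**2
    denom = float(np.sum(w * expected))
    if denom == 0:
        warnings.warn("degenerate marginals: expected agreement is 1, kappa set to 0")
        return 0.0
    return float(1.0 - np.sum(w * observed) / denom)


@dataclass
class ImanDavenportResult:
    """Friedman rank test with the Iman-Davenport F correction."""

    chi2_f: float
    statistic: float
    p_value: float
    df1: int
    df2: int
    rank_sums: np.ndarray


def iman_davenport(scores) -> ImanDavenportResult:
    """Compare k methods over n folds by ranks (higher score = better).

    Within each fold methods are ranked 1 (best) to k, ties receiving mean
    ranks.  The Friedman statistic
    ``chi2_F = 12/(n k (k+1)) * sum(R_j^2) - 3 n (k+1)`` over the rank
    sums ``R_j`` is corrected to
    ``F = (n-1) chi2_F / (n (k-1) - chi2_F)`` with (k-1, (k-1)(n-1))
    degrees of freedom.

    Raises
    ------
    ValueError
        On fewer than 2 methods/folds, or when the F denominator vanishes.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be a methods x folds matrix")
    k, n = scores.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 methods and 2 folds")
    ranks = np.column_stack(
        [sps.rankdata(-scores[:, j], method="average") for j in range(n)]
    )
    rank_sums = ranks.sum(axis=1)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    denom = n * (k - 1) - chi2
    if abs(denom) < 1e-12:
        raise ValueError("Iman-Davenport F undefined: chi2_F equals n(k-1)")
    f_stat = (n - 1) * chi2 / denom
    df1, df2 = k - 1, (k - 1) * (n - 1)
    p = float(sps.f.sf(f_stat, df1, df2))
    return ImanDavenportResult(
        chi2_f=float(chi2),
        statistic=float(f_stat),
        p_value=p,
        df1=df1,
        df2=df2,
        rank_sums=rank_sums,
    )
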