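"""End-to-end experiment orchestration.

preprocess -> extract features -> stratified k-fold -> undersample the
training folds -> fit the deterministic and probabilistic forests ->
capture out-of-bag probabilities -> fuse -> tune lambda on the fused OOB
predictions -> decide on the test fold -> report.

One lambda is tuned per fold from that fold's own training OOB estimates.
Undersampling touches only training folds, so per-fold test supports equal
the stratified plan exactly.  Reruns with identical configuration and
seeds write byte-identical JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .decision import decide, default_grid, f_score, fuse, optimize_threshold
from .evaluation import ConfusionMatrix, confusion_matrix, report
from .features import FeatureConfig, extract_all
from .forest import ForestHyper, fit_forest, oob_proba, predict_proba
from .preprocessing import (CleanParams, SegmentPolicy, UnusableRecordError,
                            clean_fhr, segment_signal)
from .resampling import random_undersample, stratified_kfold
from .signal_io import ClassLabel
from .synthetic import DEFAULT_COUNTS, default_params, simulate_dataset

__all__ = ["ExperimentConfig", "FoldResult", "ExperimentResult", "run_experiment"]

log = logging.getLogger("ctgfusion")


@dataclass(frozen=True)
class ExperimentConfig:
    """All knobs of one experiment; round-trips losslessly through YAML."""

    counts: tuple[int, int, int] = DEFAULT_COUNTS
    k: int = 3
    seed: int = 0
    n_estimators: int = 25
    max_depth: int = 10
    keep_proba: float = 0.05
    softness: float = 0.3
    new_syn_data_frac: float = 0.1
    fusion_weight: float = 0.5
    kappa_weighting: str = "linear"
    grid_step: float = 0.04
    grid_max: float = 0.44

    def grid(self) -> np.ndarray:
        n = int(round(self.grid_max / self.grid_step)) + 1
        return np.round(np.arange(n) * self.grid_step, 4)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["counts"] = tuple(d["counts"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class FoldResult:
    fold: int
    test_supports: tuple[int, int, int]
    best_lambda: float
    lambda_grid: list[float]
    f_scores: list[float]
    oob_f_score_at_zero: float
    oob_f_score_best: float
    cm_default: ConfusionMatrix
    cm_tuned: ConfusionMatrix
    report_default: dict
    report_tuned: dict
    pathological_recall_default: float
    pathological_recall_tuned: float

    def to_json_dict(self) -> dict:
        return {
            "fold": self.fold,
            "test_supports": list(self.test_supports),
            "best_lambda": self.best_lambda,
            "lambda_grid": self.lambda_grid,
            "f_scores": self.f_scores,
            "oob_f_score_at_zero": self.oob_f_score_at_zero,
            "oob_f_score_best": self.oob_f_score_best,
            "confusion_default": {
                "orientation": self.cm_default.orientation,
                "counts": self.cm_default.counts.tolist(),
            },
            "confusion_tuned": {
                "orientation": self.cm_tuned.orientation,
                "counts": self.cm_tuned.counts.tolist(),
            },
            "report_default": self.report_default,
            "report_tuned": self.report_tuned,
            "pathological_recall_default": self.pathological_recall_default,
            "pathological_recall_tuned": self.pathological_recall_tuned,
        }


@dataclass
class ExperimentResult:
    folds: list[FoldResult]
    n_segments: int
    manifest: dict

    def to_json_dict(self) -> dict:
        return {
            "manifest": self.manifest,
            "n_segments": self.n_segments,
            "folds": [f.to_json_dict() for f in self.folds],
        }

    def save(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "results.json"
        path.write_text(json.dumps(self.to_json_dict(), sort_keys=True, indent=1))
        return path


def build_feature_matrix(records, clean_params=None, policy=None, feature_config=None):
    """Preprocess and featurize recordings into (X, y, provenance)."""
    clean_params = clean_params or CleanParams()
    policy = policy or SegmentPolicy()
    feature_config = feature_config or FeatureConfig()
    rows, labels, prov = [], [], []
    n_unusable = 0
    for rec in records:
        try:
            cleaned = clean_fhr(rec, clean_params)
        except UnusableRecordError:
            n_unusable += 1
            continue
        for seg in segment_signal(cleaned, rec.resolved_label(), policy,
                                  record_id=rec.record_id):
            fv = extract_all(seg, feature_config)
            rows.append(fv.values)
            labels.append(int(seg.label))
            prov.append((seg.record_id, seg.segment_index))
    if n_unusable:
        log.info("preprocess: dropped %d unusable recordings", n_unusable)
    if not rows:
        raise ValueError("no valid segments produced from the input recordings")
    log.info("preprocess: %d recordings -> %d segments", len(records), len(rows))
    return np.vstack(rows), np.asarray(labels), prov


def run_experiment(config: ExperimentConfig | None = None, records=None) -> ExperimentResult:
    """Run the full cross-validated experiment.

    ``records`` defaults to the simulated cohort defined by
    ``config.counts`` and ``config.seed``.  Returns per-fold default
    (argmax) and threshold-moved reports, both confusion matrices, the
    lambda grid with objective scores, and the chosen lambda.
    """
    config = config or ExperimentConfig()
    if records is None:
        records = simulate_dataset(config.counts, default_params(), seed=config.seed)
    X, y, _prov = build_feature_matrix(records)
    plan = stratified_kfold(y, k=config.k, seed=config.seed)
    grid = config.grid()
    folds = []
    for fold, (train_idx, test_idx) in enumerate(plan.iter_folds()):
        y_train = y[train_idx]
        keep = random_undersample(y_train, seed=config.seed + 1000 * (fold + 1))
        Xu, yu = X[train_idx][keep], y_train[keep]
        log.info("fold %d: train %d -> undersampled %d, test %d",
                 fold, len(train_idx), len(keep), len(test_idx))

        rf = fit_forest(Xu, yu, ForestHyper(
            n_estimators=config.n_estimators, max_depth=config.max_depth,
            mode="deterministic", seed=config.seed + 10 * fold + 1))
        prf = fit_forest(Xu, yu, ForestHyper(
            n_estimators=config.n_estimators, max_depth=config.max_depth,
            mode="probabilistic", keep_proba=config.keep_proba,
            softness=config.softness, new_syn_data_frac=config.new_syn_data_frac,
            seed=config.seed + 10 * fold + 2))

        oob_rf = oob_proba(rf, Xu, yu)
        oob_prf = oob_proba(prf, Xu, yu)
        covered = oob_rf.covered & oob_prf.covered
        if not covered.any():
            raise RuntimeError(f"fold {fold}: no out-of-bag coverage for tuning")
        fused_oob = fuse(oob_rf.proba[covered], oob_prf.proba[covered],
                         config.fusion_weight)
        search = optimize_threshold(fused_oob, yu[covered], grid,
                                    config.kappa_weighting)

        fused_test = fuse(predict_proba(rf, X[test_idx]),
                          predict_proba(prf, X[test_idx]), config.fusion_weight)
        y_test = y[test_idx]
        pred_default = decide(fused_test, 0.0)
        pred_tuned = decide(fused_test, search.best_lambda)
        cm_d = confusion_matrix(y_test, pred_default)
        cm_t = confusion_matrix(y_test, pred_tuned)
        p = int(ClassLabel.PATHOLOGICAL)
        supports = tuple(int(v) for v in cm_d.supports)

        def _recall(cm):
            col = cm.counts[:, p].sum()
            return float(cm.counts[p, p] / col) if col else 0.0

        zero_i = int(np.argmin(np.abs(grid - 0.0)))
        best_i = int(np.argmin(np.abs(grid - search.best_lambda)))
        folds.append(FoldResult(
            fold=fold,
            test_supports=supports,
            best_lambda=search.best_lambda,
            lambda_grid=[float(v) for v in grid],
            f_scores=[float(s) for s in search.scores],
            oob_f_score_at_zero=float(search.scores[zero_i]),
            oob_f_score_best=float(search.scores[best_i]),
            cm_default=cm_d,
            cm_tuned=cm_t,
            report_default=report(cm_d).rounded(),
            report_tuned=report(cm_t).rounded(),
            pathological_recall_default=_recall(cm_d),
            pathological_recall_tuned=_recall(cm_t),
        ))
    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
    }
    manifest["config"]["counts"] = list(manifest["config"]["counts"])
    return ExperimentResult(folds=folds, n_segments=int(y.size), manifest=manifest)
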