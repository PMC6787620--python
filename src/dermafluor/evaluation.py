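"""Diagnostic-performance evaluation and the end-to-end experiment driver.

Melanoma is the positive class throughout.  From a 2x2 confusion matrix the
standard screening metrics are derived:

* sensitivity = 100*TP/(TP+FN), specificity = 100*TN/(TN+FP)
* accuracy    = 100*(TP+TN)/N
* diagnostic odds ratio  DOR = (TP*TN)/(FN*FP)
* number needed to excise NNE = lesions excised per confirmed melanoma
  = N/(TP+FN)
* excision reduction = 100*TN/(TN+FP), the share of benign excisions a
  score-guided policy would have avoided.

The ROC curve sweeps every integer score cut-off (prediction = score > c,
consistent with the lesion classifier) and integrates by the trapezoidal
rule.  :func:`run_experiment` chains the whole pipeline on a synthetic
cohort: simulate -> stratified split -> preprocess -> train (with optional
lesion-wise k-fold CV) -> score every test lesion with and without ROI
correction -> metrics and ROC for both variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spectra_core import (
    EmptyScanError,
    InvalidInputError,
    PathologyRecord,
    UndefinedMetricError,
    UnscorableLesionError,
    split_dataset,
)
from .synthetic_data import GeneratorConfig, make_dataset
from .preprocessing import preprocess_scan
from .svm_classifier import SVMModel, TrainingReport, kfold_cv, train_svm
from .lesion_scoring import (
    DEFAULT_CUTOFF,
    DEFAULT_FACTOR_FLOOR,
    classify_lesion,
    score_lesion,
)

logger = logging.getLogger("dermafluor")

__all__ = [
    "ConfusionMatrix",
    "DiagnosticMetrics",
    "ROCCurve",
    "AgreementRate",
    "ExperimentConfig",
    "ExperimentReport",
    "confusion",
    "metrics",
    "roc_sweep",
    "agreement_rate",
    "run_experiment",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 lesion-level counts; melanoma is the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(predictions: Sequence[int], truths: Sequence[int]) -> ConfusionMatrix:
    """Count TP/FN/FP/TN from per-lesion binary predictions and truths."""
    preds = np.asarray(predictions).astype(int).ravel()
    t = np.asarray(truths).astype(int).ravel()
    if preds.shape != t.shape or preds.size == 0:
        raise InvalidInputError("predictions and truths must have equal length >= 1")
    return ConfusionMatrix(
        tp=int(np.sum((preds == 1) & (t == 1))),
        fn=int(np.sum((preds == 0) & (t == 1))),
        fp=int(np.sum((preds == 1) & (t == 0))),
        tn=int(np.sum((preds == 0) & (t == 0))),
    )


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Screening performance; percentages on the 0–100 scale, exact values.

    ``dor`` is ``inf`` (flagged by ``dor_infinite``) when FN*FP = 0.
    """

    sensitivity: float
    specificity: float
    accuracy: float
    dor: float
    nne: float
    excision_reduction: float

    @property
    def dor_infinite(self) -> bool:
        return not np.isfinite(self.dor)

    def rounded(self) -> dict[str, float]:
        """Values at the conventional printed precisions."""
        return {
            "sensitivity": round(self.sensitivity, 1),
            "specificity": round(self.specificity, 1),
            "accuracy": round(self.accuracy, 2),
            "dor": round(self.dor, 3) if np.isfinite(self.dor) else float("inf"),
            "nne": round(self.nne, 3),
            "excision_reduction": round(self.excision_reduction, 1),
        }


def metrics(cm: ConfusionMatrix, n_excised: int | None = None) -> DiagnosticMetrics:
    """Derive the diagnostic metrics from a confusion matrix.

    ``n_excised`` defaults to the total lesion count; NNE is the number of
    excised lesions per pathology-confirmed melanoma.
    """
    if cm.n_positive == 0:
        raise UndefinedMetricError("sensitivity undefined: no melanoma lesions")
    if cm.n_negative == 0:
        raise UndefinedMetricError("specificity undefined: no benign lesions")
    n_excised = cm.total if n_excised is None else int(n_excised)
    dor = (
        (cm.tp * cm.tn) / (cm.fn * cm.fp) if cm.fn * cm.fp > 0 else float("inf")
    )
    return DiagnosticMetrics(
        sensitivity=100.0 * cm.tp / cm.n_positive,
        specificity=100.0 * cm.tn / cm.n_negative,
        accuracy=100.0 * (cm.tp + cm.tn) / cm.total,
        dor=dor,
        nne=n_excised / cm.n_positive,
        excision_reduction=100.0 * cm.tn / cm.n_negative,
    )


@dataclass
class ROCCurve:
    """Operating points over every integer score cut-off, plus AUC.

    ``points[k]`` is ``(1 - specificity, sensitivity)`` (both as fractions)
    at cut-off ``cutoffs[k]``; prediction is ``score > cutoff``, matching
    the lesion classifier.  Cut-off -1 calls everything melanoma (point
    (1, 1)); cut-off 60 calls nothing (point (0, 0)).
    """

    cutoffs: np.ndarray
    points: np.ndarray  # (n, 2): (fpr, tpr)
    auc: float


def roc_sweep(scores: Sequence[int], truths: Sequence[int]) -> ROCCurve:
    """ROC over cut-offs -1..60 with trapezoidal AUC."""
    s = np.asarray(scores).astype(int).ravel()
    t = np.asarray(truths).astype(int).ravel()
    if s.shape != t.shape or s.size == 0:
        raise InvalidInputError("scores and truths must have equal length >= 1")
    if np.any((s < 0) | (s > 60)):
        raise InvalidInputError("scores must lie in [0, 60]")
    n_pos = int(np.sum(t == 1))
    n_neg = int(np.sum(t == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC undefined with a single-class truth")
    cutoffs = np.arange(-1, 61)
    tpr = np.array([np.sum((s > c) & (t == 1)) / n_pos for c in cutoffs])
    fpr = np.array([np.sum((s > c) & (t == 0)) / n_neg for c in cutoffs])
    points = np.column_stack([fpr, tpr])
    order = np.lexsort((tpr, fpr))  # ascending staircase for the integral
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return ROCCurve(cutoffs=cutoffs, points=points, auc=auc)


@dataclass(frozen=True)
class AgreementRate:
    """Unanimity of the three pathologist diagnoses across a cohort."""

    n_unanimous: int
    n_total: int

    @property
    def percent(self) -> float:
        return 100.0 * self.n_unanimous / self.n_total

    @property
    def percent_rounded(self) -> int:
        return int(round(self.percent))


def agreement_rate(records: Iterable[PathologyRecord]) -> AgreementRate:
    """Share of lesions on which all three pathologists agree."""
    records = list(records)
    if not records:
        raise InvalidInputError("no pathology records")
    return AgreementRate(
        n_unanimous=sum(1 for r in records if r.unanimous),
        n_total=len(records),
    )


# ---------------------------------------------------------------------------
# End-to-end experiment

@dataclass
class ExperimentConfig:
    """Everything needed to rerun a full synthetic study.

    Cohort defaults mirror the study design: 214 lesions total, a 49-lesion
    stratified training set and 165 test lesions of which ~24 are melanoma.
    ``kernel_scale`` rescales the raw count vectors inside the kernel so the
    inner products are O(1) (see docs/methods.md); ``cv_folds=None`` skips
    cross-validation.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_melanoma: int = 31
    n_nevus: int = 183
    n_train: int = 49
    cv_folds: int | None = 20
    box_constraint: float = 0.165
    kernel_scale: float = 1000.0
    kernel_degree: int = 3
    class_weight: str | None = "balanced"
    solver_tol: float = 1e-3
    cutoff: int = DEFAULT_CUTOFF
    factor_floor: float = DEFAULT_FACTOR_FLOOR


@dataclass
class ExperimentReport:
    """Full output of one seeded experiment run."""

    seed: int
    config: ExperimentConfig
    model: SVMModel
    cv_report: TrainingReport | None
    lesions: pd.DataFrame
    confusion_no_roi: ConfusionMatrix
    confusion_roi: ConfusionMatrix
    metrics_no_roi: DiagnosticMetrics
    metrics_roi: DiagnosticMetrics
    roc_no_roi: ROCCurve
    roc_roi: ROCCurve
    agreement: AgreementRate


def _training_arrays(scans) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    blocks, labels, groups = [], [], []
    for scan in scans:
        try:
            pre = preprocess_scan(scan)
        except EmptyScanError:
            logger.warning("training lesion %s empty after filtering; skipped",
                           scan.lesion_id)
            continue
        blocks.append(pre.matrix)
        labels.append(np.full(pre.n_retained, scan.labels.consensus))
        groups.append(np.full(pre.n_retained, scan.lesion_id, dtype=object))
    if not blocks:
        raise EmptyScanError("no training spectra after preprocessing")
    return np.vstack(blocks), np.concatenate(labels), np.concatenate(groups)


def run_experiment(config: ExperimentConfig | None = None, seed: int = 0) -> ExperimentReport:
    """Simulate, split, train, score and evaluate one synthetic cohort.

    Deterministic for a fixed seed: the data, split and CV sub-seeds are all
    derived from the master seed.
    """
    config = config or ExperimentConfig()
    data_seed, split_seed, cv_seed = (
        int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(3)
    )

    logger.info("simulating cohort: %d melanoma + %d nevus lesions",
                config.n_melanoma, config.n_nevus)
    dataset = make_dataset(config.n_melanoma, config.n_nevus, config.generator,
                           seed=data_seed)
    dataset = split_dataset(dataset, config.n_train, seed=split_seed)
    train_scans = dataset.subset("train")
    test_scans = dataset.subset("test")

    X, y, groups = _training_arrays(train_scans)
    logger.info("training SVM on %d spectra from %d lesions",
                len(y), len(train_scans))
    model = train_svm(X, y, C=config.box_constraint, scale=config.kernel_scale,
                      degree=config.kernel_degree, tol=config.solver_tol,
                      class_weight=config.class_weight)

    cv_report = None
    if config.cv_folds:
        cv_report = kfold_cv(X, y, groups, k=config.cv_folds,
                             C=config.box_constraint, scale=config.kernel_scale,
                             degree=config.kernel_degree, tol=config.solver_tol,
                             class_weight=config.class_weight, seed=cv_seed)
        logger.info("%d-fold lesion-wise CV mean error: %.4f",
                    config.cv_folds, cv_report.mean_cv_error)

    rows = []
    for scan in test_scans:
        try:
            res = score_lesion(scan, model, use_roi=True, cutoff=config.cutoff,
                               factor_floor=config.factor_floor)
        except UnscorableLesionError:
            logger.warning("test lesion %s unscorable; excluded", scan.lesion_id)
            continue
        corrected = res.raw_score if res.corrected_score is None else res.corrected_score
        rows.append({
            "lesion_id": scan.lesion_id,
            "truth": scan.labels.consensus,
            "n_total": res.n_total,
            "n_retained": res.n_retained,
            "n_malignant": res.n_malignant,
            "raw_score": res.raw_score,
            "corrected_score": corrected,
            "pred_no_roi": classify_lesion(res.raw_score, config.cutoff),
            "pred_roi": classify_lesion(corrected, config.cutoff),
        })
    lesions = pd.DataFrame(rows)

    truths = lesions["truth"].to_numpy()
    cm_raw = confusion(lesions["pred_no_roi"].to_numpy(), truths)
    cm_roi = confusion(lesions["pred_roi"].to_numpy(), truths)
    return ExperimentReport(
        seed=seed,
        config=config,
        model=model,
        cv_report=cv_report,
        lesions=lesions,
        confusion_no_roi=cm_raw,
        confusion_roi=cm_roi,
        metrics_no_roi=metrics(cm_raw),
        metrics_roi=metrics(cm_roi),
        roc_no_roi=roc_sweep(lesions["raw_score"].to_numpy(), truths),
        roc_roi=roc_sweep(lesions["corrected_score"].to_numpy(), truths),
        agreement=agreement_rate([s.labels for s in dataset.scans]),
    )
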