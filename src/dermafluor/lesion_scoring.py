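"""Lesion-level 0–60 score, ROI correction and the cut-off decision.

Per-spectrum SVM predictions are aggregated into a score that scales
linearly with the number of malignant spectra::

    raw_score = round(60 * n_malignant / n_retained)

(rounding half away from zero, clamped to [0, 60]), so the score reaches 0
when no retained spectrum is malignant and 60 when all are.  A lesion is
called melanoma when its score strictly exceeds the cut-off (28): 28 itself
is non-melanoma, 29 is melanoma.  The exact linear coefficients of the
device score are a reconstruction — see docs/methods.md.

When the operator's scan rectangle does not match the lesion, the raw score
under- or over-samples pigmented tissue; the ROI-corrected score divides by
both segmentation-derived factors (each floored to avoid blow-up on tiny
overlaps)::

    corrected = clamp(round(raw / (max(f_pig, floor) * max(f_cov, floor))), 0, 60)

which is a no-op when scan area and lesion coincide (factors (1, 1)) and
can only raise the score otherwise — raising sensitivity at some cost in
specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .spectra_core import (
    DegenerateContrastError,
    EmptyScanError,
    InvalidInputError,
    LesionScan,
    UnscorableLesionError,
)
from .preprocessing import preprocess_scan
from .roi_segmentation import (
    CorrectionFactors,
    correction_factors,
    segment_lesion,
)
from .svm_classifier import SVMModel

logger = logging.getLogger("dermafluor")

__all__ = [
    "DEFAULT_CUTOFF",
    "DEFAULT_FACTOR_FLOOR",
    "ScoreResult",
    "raw_score",
    "apply_roi_correction",
    "classify_lesion",
    "score_lesion",
]

DEFAULT_CUTOFF = 28
DEFAULT_FACTOR_FLOOR = 0.2


def _round_half_away(x: float) -> int:
    """Round half away from zero (27.5 -> 28), unlike banker's rounding."""
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


@dataclass
class ScoreResult:
    """Scoring outcome for one lesion."""

    lesion_id: str
    n_total: int
    n_retained: int
    n_malignant: int
    raw_score: int
    corrected_score: int | None
    predicted: int
    cutoff: int = DEFAULT_CUTOFF

    @property
    def used_score(self) -> int:
        return self.raw_score if self.corrected_score is None else self.corrected_score


def raw_score(n_malignant: int, n_retained: int) -> int:
    """Linear 0–60 score: 60 times the malignant fraction, rounded."""
    if n_retained < 1:
        raise UnscorableLesionError("no retained spectra; lesion unscorable")
    if not 0 <= n_malignant <= n_retained:
        raise InvalidInputError(
            f"n_malignant={n_malignant} outside [0, {n_retained}]"
        )
    return min(max(_round_half_away(60.0 * n_malignant / n_retained), 0), 60)


def apply_roi_correction(
    raw: int, factors: CorrectionFactors, floor: float = DEFAULT_FACTOR_FLOOR
) -> int:
    """Divide the raw score by both floored factors; clamp to [0, 60]."""
    if not 0 <= raw <= 60:
        raise InvalidInputError(f"raw score {raw} outside [0, 60]")
    if not 0.0 < floor <= 1.0:
        raise InvalidInputError(f"factor floor must be in (0, 1], got {floor}")
    denom = max(factors.f_pig, floor) * max(factors.f_cov, floor)
    return min(max(_round_half_away(raw / denom), 0), 60)


def classify_lesion(score: int, cutoff: int = DEFAULT_CUTOFF) -> int:
    """1 (melanoma) iff the score strictly exceeds the cut-off."""
    if not 0 <= score <= 60:
        raise InvalidInputError(f"score {score} outside [0, 60]")
    return 1 if score > cutoff else 0


def score_lesion(
    scan: LesionScan,
    model: SVMModel,
    use_roi: bool = False,
    cutoff: int = DEFAULT_CUTOFF,
    factor_floor: float = DEFAULT_FACTOR_FLOOR,
) -> ScoreResult:
    """Full per-lesion pipeline: preprocess, classify spectra, score.

    With ``use_roi`` the photograph is segmented and the score divided by
    the two normalization factors; if segmentation reports degenerate
    contrast the correction is skipped with a logged warning and the raw
    score is used.

    Raises :class:`UnscorableLesionError` (via preprocessing) when no
    spectrum survives the intensity filter.
    """
    try:
        pre = preprocess_scan(scan)
    except EmptyScanError as exc:
        raise UnscorableLesionError(str(exc)) from exc
    n_malignant = int(model.predict(pre.matrix).sum())
    raw = raw_score(n_malignant, pre.n_retained)

    corrected: int | None = None
    if use_roi:
        seg = segment_lesion(scan.photo)
        if not seg.contrast_ok:
            logger.warning(
                "lesion %s: degenerate photo contrast, ROI correction skipped",
                scan.lesion_id,
            )
        else:
            try:
                factors = correction_factors(seg.lesion_mask, scan.scan_rect)
            except DegenerateContrastError:
                logger.warning(
                    "lesion %s: empty lesion mask, ROI correction skipped",
                    scan.lesion_id,
                )
            else:
                corrected = apply_roi_correction(raw, factors, factor_floor)

    used = raw if corrected is None else corrected
    return ScoreResult(
        lesion_id=scan.lesion_id,
        n_total=pre.n_total,
        n_retained=pre.n_retained,
        n_malignant=n_malignant,
        raw_score=raw,
        corrected_score=corrected,
        predicted=classify_lesion(used, cutoff),
        cutoff=cutoff,
    )
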