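"""Lesion segmentation by minimum cross-entropy (Li) thresholding and the
two ROI normalization factors.

Pigmented lesions are dark on a brighter skin background, so a single
global threshold separates them when imaging geometry and illumination are
fixed.  The threshold minimizes the Li–Tam cross-entropy between the image
and its two-level reconstruction; it is found by the fixed-point iteration

    t_{n+1} = (mu_below(t_n) - mu_above(t_n)) / (ln mu_below - ln mu_above)

i.e. the logarithmic mean of the two class means, iterated until the
threshold moves by less than half a gray level.  An exhaustive minimizer of
the same criterion (:func:`li_threshold_bruteforce`) serves as the in-module
oracle the iteration is validated against.

From the lesion mask and the operator's scan rectangle two normalization
factors are derived for score correction:

* ``f_cov`` — fraction of the segmented lesion that was actually scanned;
* ``f_pig`` — fraction of the scan area lying on pigmented lesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .spectra_core import DegenerateContrastError, InvalidInputError

__all__ = [
    "SegmentationResult",
    "CorrectionFactors",
    "li_threshold",
    "li_cross_entropy",
    "li_threshold_bruteforce",
    "segment_lesion",
    "correction_factors",
]

#: gray level 0 is offset to this value before taking log-means
_ZERO_OFFSET = 0.5


def _gray_values(image: np.ndarray) -> np.ndarray:
    g = np.asarray(image, dtype=float).ravel()
    g[g == 0] = _ZERO_OFFSET  # guard ln 0; sub-quantization impact
    return g


def li_threshold(
    image: np.ndarray,
    tol: float = 0.5,
    init: float | None = None,
    max_iter: int = 200,
) -> float:
    """Minimum cross-entropy threshold by Li–Tam fixed-point iteration.

    Starts at the image mean (configurable) and iterates the log-mean map
    until the threshold changes by less than ``tol`` gray levels.

    Raises :class:`DegenerateContrastError` on a constant image.
    """
    g = _gray_values(image)
    if np.ptp(g) == 0:
        raise DegenerateContrastError("image has a single gray level")
    t = float(np.mean(g)) if init is None else float(init)
    for _ in range(max_iter):
        below = g[g < t]
        above = g[g >= t]
        if below.size == 0 or above.size == 0:
            # threshold fell outside the data range; nudge to the mean
            t = float(np.mean(g))
            continue
        mu_b = float(np.mean(below))
        mu_a = float(np.mean(above))
        if mu_b == mu_a:
            break
        t_next = (mu_b - mu_a) / (np.log(mu_b) - np.log(mu_a))
        if abs(t_next - t) < tol:
            t = t_next
            break
        t = t_next
    return float(t)


def li_cross_entropy(image: np.ndarray, t: float) -> float:
    """Li–Tam cross-entropy criterion of thresholding ``image`` at ``t``.

    Up to an additive constant of the image, this is the cross entropy
    between the image and its two-level reconstruction by the class means;
    lower is better.  Infinite when one side of the split is empty.
    """
    g = _gray_values(image)
    below = g[g < t]
    above = g[g >= t]
    if below.size == 0 or above.size == 0:
        return float("inf")
    return float(
        -np.sum(below) * np.log(np.mean(below))
        - np.sum(above) * np.log(np.mean(above))
    )


def li_threshold_bruteforce(image: np.ndarray) -> float:
    """Exhaustive minimizer of the cross-entropy criterion (oracle).

    Evaluates every candidate threshold between consecutive occupied gray
    levels and returns the best; independent of the fixed-point iteration.
    """
    g = np.unique(_gray_values(image))
    if g.size < 2:
        raise DegenerateContrastError("image has a single gray level")
    candidates = (g[:-1] + g[1:]) / 2.0
    costs = [li_cross_entropy(image, t) for t in candidates]
    return float(candidates[int(np.argmin(costs))])


@dataclass
class SegmentationResult:
    """Threshold, lesion mask and a contrast flag for one photograph."""

    threshold: float
    lesion_mask: np.ndarray
    contrast_ok: bool


@dataclass(frozen=True)
class CorrectionFactors:
    """ROI normalization factors, both in [0, 1].

    ``f_cov``: scanned fraction of the segmented lesion.
    ``f_pig``: pigmented (on-lesion) fraction of the scan area.
    Both are 1 exactly when scan area and lesion coincide.
    """

    f_cov: float
    f_pig: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_cov <= 1.0 and 0.0 <= self.f_pig <= 1.0):
            raise InvalidInputError("correction factors must lie in [0, 1]")


def segment_lesion(photo: np.ndarray, invert: bool = False) -> SegmentationResult:
    """Threshold the photograph and keep the largest connected component.

    The lesion is the dark phase (melanin absorbs); pass ``invert=True`` for
    non-standard imaging where the lesion is bright.  On degenerate contrast
    the result carries an empty mask and ``contrast_ok=False`` instead of
    raising, so callers can fall back to uncorrected scoring.
    """
    photo = np.asarray(photo)
    try:
        t = li_threshold(photo)
    except DegenerateContrastError:
        return SegmentationResult(
            threshold=float("nan"),
            lesion_mask=np.zeros(photo.shape, dtype=bool),
            contrast_ok=False,
        )
    mask = (photo > t) if invert else (photo < t)
    if not mask.any():
        return SegmentationResult(threshold=t, lesion_mask=mask, contrast_ok=False)
    labeled, n = ndimage.label(mask, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    if n > 1:
        sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
        mask = labeled == (1 + int(np.argmax(sizes)))
    return SegmentationResult(threshold=t, lesion_mask=mask, contrast_ok=True)


def correction_factors(
    mask: np.ndarray, scan_rect: tuple[int, int, int, int]
) -> CorrectionFactors:
    """Pixel-count overlap factors between lesion mask and scan rectangle.

    ``f_cov = |mask ∩ rect| / |mask|`` is the scanned fraction of the lesion.
    ``f_pig`` is the on-lesion density of the scan area *relative to the
    density of the lesion in its own bounding box*::

        f_pig = min(1, (|mask ∩ rect| / |rect|) / (|mask| / |bbox(mask)|))

    The normalization makes an operator rectangle congruent with the lesion
    bounding box — the recommended procedure — an exact no-op ``(1, 1)``
    even for non-rectangular lesions, while a rectangle diluted by
    surrounding skin still scores ``f_pig < 1``.  For a lesion that fills
    its bounding box the normalizer is 1 and ``f_pig`` reduces to the plain
    on-lesion fraction of the scan area.  Half-open rectangle convention.
    """
    mask = np.asarray(mask, dtype=bool)
    x0, y0, x1, y1 = scan_rect
    h, w = mask.shape
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise InvalidInputError(f"scan_rect {scan_rect} outside image bounds")
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise DegenerateContrastError("empty lesion mask; factors undefined")
    inter = int(mask[y0:y1, x0:x1].sum())
    n_rect = (x1 - x0) * (y1 - y0)
    ys, xs = np.nonzero(mask)
    n_bbox = (int(ys.max()) - int(ys.min()) + 1) * (int(xs.max()) - int(xs.min()) + 1)
    bbox_fill = n_mask / n_bbox
    return CorrectionFactors(
        f_cov=inter / n_mask,
        f_pig=min(1.0, (inter / n_rect) / bbox_fill),
    )
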