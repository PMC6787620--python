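"""Raw-scan preprocessing: spectral truncation and the low-intensity filter.

Two steps reduce a raw scan to the classifier input matrix:

1. each raw spectrum is truncated to the canonical 750-point 382–680 nm
   grid, discarding the signal of unknown origin above 680 nm (linear
   interpolation if the raw grid differs from the canonical one);
2. spectra whose maximum count in the 480–600 nm window is below 10 are
   dropped — they carry no usable melanin fluorescence (typically grid
   positions on un-pigmented skin).

No smoothing, baseline subtraction or normalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_core import (
    CANONICAL_GRID,
    CoverageError,
    EmptyScanError,
    LesionScan,
    WavelengthGrid,
)

__all__ = [
    "INTENSITY_WINDOW_NM",
    "MIN_COUNTS",
    "PreprocessedScan",
    "truncate_spectrum",
    "passes_intensity_filter",
    "preprocess_scan",
]

#: Inclusive wavelength window of the low-intensity filter, nm.
INTENSITY_WINDOW_NM = (480.0, 600.0)
#: Spectra with window maximum below this many counts are discarded.
MIN_COUNTS = 10.0


@dataclass
class PreprocessedScan:
    """Retained, truncated spectra of one scan, in row-major grid order."""

    matrix: np.ndarray  # n_retained x 750
    positions: list[tuple[int, int]]
    n_total: int
    n_retained: int

    def __post_init__(self) -> None:
        assert self.matrix.shape == (self.n_retained, CANONICAL_GRID.n_points)
        assert len(self.positions) == self.n_retained
        assert self.n_retained <= self.n_total


def truncate_spectrum(
    counts: np.ndarray,
    raw_wavelengths_nm: np.ndarray,
    grid: WavelengthGrid = CANONICAL_GRID,
) -> np.ndarray:
    """Resample a raw spectrum onto the canonical grid, dropping >680 nm.

    Exact when the raw grid already contains the canonical points (the
    synthetic generator's case); otherwise linear interpolation.
    """
    raw = np.asarray(raw_wavelengths_nm, dtype=float)
    if raw[0] > grid.start_nm or raw[-1] < grid.stop_nm:
        raise CoverageError(
            f"raw grid [{raw[0]:.2f}, {raw[-1]:.2f}] nm does not cover the "
            f"canonical range [{grid.start_nm}, {grid.stop_nm}] nm"
        )
    return np.interp(grid.values, raw, np.asarray(counts, dtype=float))


def passes_intensity_filter(
    spectrum750: np.ndarray,
    grid: WavelengthGrid = CANONICAL_GRID,
    min_counts: float = MIN_COUNTS,
) -> bool:
    """True iff the 480–600 nm window peak reaches ``min_counts`` counts.

    Spectra *below* 10 counts are excluded; a peak of exactly 10 is kept.
    """
    window = grid.window_mask(*INTENSITY_WINDOW_NM)
    return bool(np.max(np.asarray(spectrum750)[window]) >= min_counts)


def preprocess_scan(scan: LesionScan) -> PreprocessedScan:
    """Truncate every spectrum, apply the intensity filter, stack the rest.

    Raises :class:`EmptyScanError` when nothing survives — the lesion cannot
    be scored (distinct from I/O failures).
    """
    ordered = sorted(scan.spectra, key=lambda s: (s.row, s.col))
    kept_rows: list[np.ndarray] = []
    positions: list[tuple[int, int]] = []
    for s in ordered:
        trunc = truncate_spectrum(s.counts, scan.wavelengths_nm)
        if passes_intensity_filter(trunc):
            kept_rows.append(trunc)
            positions.append((s.row, s.col))
    if not kept_rows:
        raise EmptyScanError(
            f"lesion {scan.lesion_id!r}: no spectrum passes the "
            f"{MIN_COUNTS:.0f}-count intensity filter"
        )
    return PreprocessedScan(
        matrix=np.vstack(kept_rows),
        positions=positions,
        n_total=len(scan.spectra),
        n_retained=len(kept_rows),
    )
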