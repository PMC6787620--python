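"""Domain types and scan-bundle I/O for dermatofluoroscopic scans.

A dermatofluoroscope records one melanin fluorescence spectrum per grid
position (200 um step) inside an operator-chosen rectangle on a lesion
photograph.  This module defines the shared containers — the canonical
wavelength grid, single spectra, whole lesion scans with their pathology
labels — plus the on-disk bundle format and the stratified train/test split.

A *scan bundle* is a directory with three parts::

    <bundle>/
      spectra.csv   # long table: row, col, one column per raw wavelength (nm)
      photo.png     # 8-bit grayscale lesion photograph
      meta.yaml     # lesion_id, step_um, um_per_pixel, scan_rect, labels

Image coordinates are top-left origin, row-major, 0-based; ``scan_rect`` is
half-open ``[x0, x1) x [y0, y1)`` in photo pixels.  Spectrum grid position
``(row, col)`` maps to pixel ``(y0 + row*step_px, x0 + col*step_px)`` with
``step_px = step_um / um_per_pixel`` and nearest-pixel rounding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

logger = logging.getLogger("dermafluor")

__all__ = [
    "WavelengthGrid",
    "CANONICAL_GRID",
    "Spectrum",
    "PathologyRecord",
    "LesionScan",
    "Dataset",
    "consensus_label",
    "split_dataset",
    "read_scan",
    "write_scan",
    "DermafluorError",
    "InvalidInputError",
    "FormatError",
    "ConsistencyError",
    "CoverageError",
    "EmptyScanError",
    "DegenerateContrastError",
    "DegenerateTrainingError",
    "ConvergenceError",
    "UnscorableLesionError",
    "UndefinedMetricError",
]


# ---------------------------------------------------------------------------
# Errors

class DermafluorError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(DermafluorError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(DermafluorError):
    """A scan bundle is missing a component or a component is unreadable."""


class ConsistencyError(DermafluorError):
    """Bundle components disagree (grid vs. metadata, rect vs. photo)."""


class CoverageError(DermafluorError):
    """A raw wavelength grid does not cover the canonical analysis range."""


class EmptyScanError(DermafluorError):
    """No spectrum in the scan survives preprocessing; lesion unscorable."""


class DegenerateContrastError(DermafluorError):
    """The photograph has no usable contrast for segmentation."""


class DegenerateTrainingError(DermafluorError):
    """Training data contains a single class."""


class ConvergenceError(DermafluorError):
    """The dual solver did not converge; carries the remaining KKT gap."""

    def __init__(self, message: str, gap: float):
        super().__init__(message)
        self.gap = float(gap)


class UnscorableLesionError(DermafluorError):
    """A lesion score cannot be computed (no retained spectra)."""


class UndefinedMetricError(DermafluorError):
    """A diagnostic metric is undefined for this confusion matrix."""


# ---------------------------------------------------------------------------
# Wavelength grid

@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength sampling grid, in nanometres.

    The canonical analysis grid spans 382–680 nm in 750 points
    (spacing ~0.39786 nm), one point per spectral predictor.
    """

    start_nm: float = 382.0
    stop_nm: float = 680.0
    n_points: int = 750

    def __post_init__(self) -> None:
        if not (self.stop_nm > self.start_nm):
            raise InvalidInputError("wavelength grid must be strictly increasing")
        if self.n_points < 2:
            raise InvalidInputError("wavelength grid needs at least 2 points")

    @property
    def spacing_nm(self) -> float:
        return (self.stop_nm - self.start_nm) / (self.n_points - 1)

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.start_nm, self.stop_nm, self.n_points)

    def window_mask(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Boolean mask of grid points with ``lo_nm <= lambda <= hi_nm``."""
        v = self.values
        return (v >= lo_nm) & (v <= hi_nm)


CANONICAL_GRID = WavelengthGrid()


# ---------------------------------------------------------------------------
# Spectra and scans

@dataclass
class Spectrum:
    """One detector readout at a grid position.

    ``counts`` lives on the *raw* device grid, which may extend beyond
    680 nm before truncation; values are non-negative photon counts.
    """

    row: int
    col: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise InvalidInputError("spectrum counts must be a 1-D vector")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise InvalidInputError("spectrum counts must be finite and >= 0")


def consensus_label(diagnoses: Sequence[int]) -> int:
    """Majority melanoma/non-melanoma call from three pathologist labels.

    Returns 1 (melanoma) iff at least two of the three binary labels are 1.
    """
    if len(diagnoses) != 3:
        raise InvalidInputError(
            f"exactly three pathologist labels required, got {len(diagnoses)}"
        )
    labels = [int(d) for d in diagnoses]
    if any(l not in (0, 1) for l in labels):
        raise InvalidInputError("pathologist labels must be 0 or 1")
    return 1 if sum(labels) >= 2 else 0


@dataclass
class PathologyRecord:
    """Three independent binary pathologist diagnoses (1 = melanoma)."""

    diagnoses: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.diagnoses = tuple(int(d) for d in self.diagnoses)  # type: ignore[assignment]
        consensus_label(self.diagnoses)  # validates arity and values

    @property
    def consensus(self) -> int:
        return consensus_label(self.diagnoses)

    @property
    def unanimous(self) -> bool:
        return len(set(self.diagnoses)) == 1


@dataclass
class LesionScan:
    """One lesion: spatially indexed spectra + photograph + geometry + labels.

    Parameters
    ----------
    wavelengths_nm:
        The raw device wavelength grid shared by every spectrum in the scan.
    scan_rect:
        ``(x0, y0, x1, y1)`` half-open rectangle in photo pixel coordinates —
        the measurement area chosen by the operator.
    """

    lesion_id: str
    step_um: float
    wavelengths_nm: np.ndarray
    spectra: list[Spectrum]
    photo: np.ndarray
    scan_rect: tuple[int, int, int, int]
    um_per_pixel: float
    labels: PathologyRecord

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.photo = np.asarray(self.photo)
        if self.photo.ndim != 2 or self.photo.dtype != np.uint8:
            raise InvalidInputError("photo must be a 2-D 8-bit grayscale image")
        if self.step_um <= 0 or self.um_per_pixel <= 0:
            raise InvalidInputError("step_um and um_per_pixel must be positive")
        x0, y0, x1, y1 = self.scan_rect
        h, w = self.photo.shape
        if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
            raise ConsistencyError(
                f"scan_rect {self.scan_rect} outside photo bounds {w}x{h}"
            )
        positions = [(s.row, s.col) for s in self.spectra]
        if len(set(positions)) != len(positions):
            raise ConsistencyError("duplicate (row, col) grid positions in scan")
        n_rows, n_cols = self.grid_shape
        for s in self.spectra:
            if not (0 <= s.row < n_rows and 0 <= s.col < n_cols):
                raise ConsistencyError(
                    f"grid position ({s.row}, {s.col}) inconsistent with "
                    f"scan_rect and step ({n_rows}x{n_cols} grid expected)"
                )
            if s.counts.shape != self.wavelengths_nm.shape:
                raise ConsistencyError("spectrum length differs from wavelength grid")

    @property
    def step_px(self) -> float:
        return self.step_um / self.um_per_pixel

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) of grid positions fitting in the scan rectangle."""
        x0, y0, x1, y1 = self.scan_rect
        n_rows = int(np.ceil((y1 - y0) / self.step_px))
        n_cols = int(np.ceil((x1 - x0) / self.step_px))
        return max(n_rows, 1), max(n_cols, 1)

    def grid_to_pixel(self, row: int, col: int) -> tuple[int, int]:
        """Photo pixel (y, x) sampled by grid position (row, col)."""
        x0, y0, _, _ = self.scan_rect
        y = int(round(y0 + row * self.step_px))
        x = int(round(x0 + col * self.step_px))
        return y, x


@dataclass
class Dataset:
    """A cohort of lesion scans with an optional train/test assignment."""

    scans: list[LesionScan]
    split: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.lesion_id for s in self.scans]
        if len(set(ids)) != len(ids):
            raise ConsistencyError("lesion ids are not unique")
        known = set(ids)
        for lid, part in self.split.items():
            if lid not in known:
                raise ConsistencyError(f"split references unknown lesion {lid!r}")
            if part not in ("train", "test"):
                raise InvalidInputError(f"split value must be train/test, got {part!r}")

    def subset(self, part: str) -> list[LesionScan]:
        return [s for s in self.scans if self.split.get(s.lesion_id) == part]


def split_dataset(dataset: Dataset, n_train: int, seed: int) -> Dataset:
    """Stratified random train/test split on consensus labels.

    The number of melanomas in the training set is the proportional
    allocation ``round(n_melanoma * n_train / n_lesions)``, so both sets keep
    a similar melanoma/non-melanoma mix.  Deterministic for a fixed seed.
    """
    n = len(dataset.scans)
    if not (0 < n_train < n):
        raise InvalidInputError(f"n_train must be in (0, {n}), got {n_train}")
    rng = np.random.default_rng(seed)
    mel = [s.lesion_id for s in dataset.scans if s.labels.consensus == 1]
    ben = [s.lesion_id for s in dataset.scans if s.labels.consensus == 0]
    n_mel_train = int(round(len(mel) * n_train / n))
    n_mel_train = min(max(n_mel_train, n_train - len(ben)), len(mel), n_train)
    rng.shuffle(mel)
    rng.shuffle(ben)
    train = set(mel[:n_mel_train]) | set(ben[: n_train - n_mel_train])
    split = {
        s.lesion_id: ("train" if s.lesion_id in train else "test")
        for s in dataset.scans
    }
    return Dataset(scans=dataset.scans, split=split)


# ---------------------------------------------------------------------------
# Bundle I/O

_SPECTRA_FILE = "spectra.csv"
_PHOTO_FILE = "photo.png"
_META_FILE = "meta.yaml"


def write_scan(scan: LesionScan, path: str | Path) -> Path:
    """Write a scan bundle directory; returns the bundle path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    cols = {"row": [s.row for s in scan.spectra], "col": [s.col for s in scan.spectra]}
    counts = np.array([s.counts for s in scan.spectra])
    table = pd.DataFrame(cols)
    wl_cols = [f"{w:.5f}" for w in scan.wavelengths_nm]
    table = pd.concat(
        [table, pd.DataFrame(counts, columns=wl_cols)], axis=1
    )
    table.to_csv(path / _SPECTRA_FILE, index=False)

    Image.fromarray(scan.photo, mode="L").save(path / _PHOTO_FILE)

    meta = {
        "lesion_id": scan.lesion_id,
        "step_um": float(scan.step_um),
        "um_per_pixel": float(scan.um_per_pixel),
        "scan_rect": [int(v) for v in scan.scan_rect],
        "labels": [int(d) for d in scan.labels.diagnoses],
    }
    (path / _META_FILE).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_scan(path: str | Path) -> LesionScan:
    """Read a scan bundle directory written by :func:`write_scan`."""
    path = Path(path)
    for part in (_SPECTRA_FILE, _PHOTO_FILE, _META_FILE):
        if not (path / part).is_file():
            raise FormatError(f"scan bundle {path} is missing {part}")

    meta = yaml.safe_load((path / _META_FILE).read_text())
    if not isinstance(meta, Mapping):
        raise FormatError(f"{path / _META_FILE} is not a key/value document")
    try:
        lesion_id = str(meta["lesion_id"])
        step_um = float(meta["step_um"])
        um_per_pixel = float(meta["um_per_pixel"])
        scan_rect = tuple(int(v) for v in meta["scan_rect"])
        labels = PathologyRecord(tuple(int(v) for v in meta["labels"]))
    except (KeyError, TypeError) as exc:
        raise FormatError(f"metadata field missing or malformed: {exc}") from exc

    photo = np.asarray(Image.open(path / _PHOTO_FILE).convert("L"), dtype=np.uint8)

    table = pd.read_csv(path / _SPECTRA_FILE)
    if table.columns[:2].tolist() != ["row", "col"]:
        raise FormatError("spectra.csv must start with row,col columns")
    wavelengths = np.array([float(c) for c in table.columns[2:]])
    spectra = [
        Spectrum(int(r.iloc[0]), int(r.iloc[1]), r.iloc[2:].to_numpy(dtype=float))
        for _, r in table.iterrows()
    ]
    return LesionScan(
        lesion_id=lesion_id,
        step_um=step_um,
        wavelengths_nm=wavelengths,
        spectra=spectra,
        photo=photo,
        scan_rect=scan_rect,  # type: ignore[arg-type]
        um_per_pixel=um_per_pixel,
        labels=labels,
    )
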