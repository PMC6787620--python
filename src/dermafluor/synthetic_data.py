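"""Synthetic dermatofluoroscopic scan generator.

Emulates the structure of the device output that the analysis pipeline
assumes, so the whole chain is testable without clinical data:

* melanin fluorescence as a single Gaussian band — peaked near 590 nm for
  nevus-type spectra and near 640 nm for melanoma-type spectra (the
  bathochromic shift that carries the diagnostic signal);
* a narrow second-harmonic-generation (SHG) line near 400 nm from dermal
  collagen, present in every spectrum;
* weak skin-type spectra (amplitude below the 10-count intensity filter)
  at grid positions outside the pigmented lesion;
* a small spurious band above 680 nm on the raw grid, so spectral
  truncation has signal to remove;
* Poisson counting noise per wavelength, matching photon-counting detection;
* an elliptical dark lesion on a brighter skin background photograph, with
  the operator's scan rectangle placed per one of four clinical scenarios
  (a: rectangle matches the lesion box; b: lesion box dilated 50 % per side;
  c: left half of the lesion box; d: half box shifted onto surrounding skin).

Lesion pixels of a melanoma emit melanoma-type spectra with probability
``p_mal_melanoma`` (default 0.63) and nevus-type otherwise; nevi use
``p_mal_nevus`` (default 0.29).  With the linear 0–60 score downstream these
defaults place expected raw scores near 38 and 17 respectively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .spectra_core import (
    CANONICAL_GRID,
    Dataset,
    InvalidInputError,
    LesionScan,
    PathologyRecord,
    Spectrum,
)

__all__ = [
    "GeneratorConfig",
    "RAW_GRID_STOP_NM",
    "raw_wavelength_grid",
    "expected_spectrum",
    "make_spectrum",
    "make_lesion_image",
    "make_lesion_scan",
    "make_dataset",
]

SpectrumKind = Literal["benign", "malignant", "skin"]

#: Raw device grid extends past the canonical 680 nm stop, at the same spacing.
RAW_GRID_STOP_NM = 720.0


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic scan generator.

    Amplitudes are in detector counts, wavelengths in nm, image levels in
    8-bit gray values.  Defaults are the documented study conditions.
    """

    benign_peak_nm: float = 590.0
    malignant_peak_nm: float = 640.0
    band_sigma_nm: float = 40.0
    shg_peak_nm: float = 400.0
    shg_sigma_nm: float = 5.0
    fluor_amplitude: float = 120.0
    shg_amplitude: float = 200.0
    skin_amplitude: float = 3.0  # below the 10-count intensity filter
    spurious_peak_nm: float = 700.0  # above 680 nm; removed by truncation
    spurious_sigma_nm: float = 8.0
    spurious_amplitude: float = 40.0
    p_mal_melanoma: float = 0.63
    p_mal_nevus: float = 0.29
    lesion_axes_px: tuple[int, int] = (16, 10)  # (semi-x, semi-y)
    photo_size_px: tuple[int, int] = (96, 96)  # (height, width)
    um_per_pixel: float = 50.0
    step_um: float = 200.0
    pigment_level: int = 60
    skin_level: int = 200
    image_noise_sd: float = 8.0
    label_flip_rate: float = 0.0  # per-pathologist independent flip probability
    poisson_noise: bool = True
    scenario: Literal["a", "b", "c", "d"] = "a"

    def __post_init__(self) -> None:
        for name in ("p_mal_melanoma", "p_mal_nevus", "label_flip_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidInputError(f"{name} must be in [0, 1], got {p}")
        for name in ("benign_peak_nm", "malignant_peak_nm", "shg_peak_nm"):
            peak = getattr(self, name)
            if not CANONICAL_GRID.start_nm <= peak <= CANONICAL_GRID.stop_nm:
                raise InvalidInputError(f"{name}={peak} outside the 382-680 nm range")
        # equality is allowed: it produces a zero-contrast photo that the
        # downstream segmentation must flag, which is itself worth testing
        if self.pigment_level > self.skin_level:
            raise InvalidInputError("pigment_level must not exceed skin_level")
        if self.scenario not in ("a", "b", "c", "d"):
            raise InvalidInputError(f"unknown scenario {self.scenario!r}")


def raw_wavelength_grid() -> np.ndarray:
    """Raw device grid: canonical spacing from 382 nm continued to ~720 nm.

    The first 750 points coincide exactly with the canonical analysis grid,
    so truncation on synthetic data is a pure cut, not an interpolation.
    """
    spacing = CANONICAL_GRID.spacing_nm
    n_extra = int(np.floor((RAW_GRID_STOP_NM - CANONICAL_GRID.stop_nm) / spacing))
    n = CANONICAL_GRID.n_points + n_extra
    return CANONICAL_GRID.start_nm + spacing * np.arange(n)


def expected_spectrum(
    kind: SpectrumKind, config: GeneratorConfig, wavelengths_nm: np.ndarray
) -> np.ndarray:
    """Noise-free expected counts mu(lambda) for one spectrum kind."""
    lam = np.asarray(wavelengths_nm, dtype=float)
    if kind == "benign":
        amp, peak = config.fluor_amplitude, config.benign_peak_nm
    elif kind == "malignant":
        amp, peak = config.fluor_amplitude, config.malignant_peak_nm
    elif kind == "skin":
        amp, peak = config.skin_amplitude, config.benign_peak_nm
    else:
        raise InvalidInputError(f"unknown spectrum kind {kind!r}")
    mu = amp * np.exp(-((lam - peak) ** 2) / (2 * config.band_sigma_nm**2))
    mu += config.shg_amplitude * np.exp(
        -((lam - config.shg_peak_nm) ** 2) / (2 * config.shg_sigma_nm**2)
    )
    mu += config.spurious_amplitude * np.exp(
        -((lam - config.spurious_peak_nm) ** 2) / (2 * config.spurious_sigma_nm**2)
    )
    return mu


def make_spectrum(
    kind: SpectrumKind, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw one raw-grid counts vector; Poisson noise per wavelength."""
    mu = expected_spectrum(kind, config, raw_wavelength_grid())
    if not config.poisson_noise:
        return mu
    return rng.poisson(mu).astype(float)


def _ellipse_mask(shape: tuple[int, int], axes: tuple[int, int]) -> np.ndarray:
    h, w = shape
    ax, ay = axes
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def make_lesion_image(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Photograph of a centered elliptical lesion plus its ground-truth mask.

    Returns ``(photo, mask)``: an 8-bit grayscale image with mean
    ``pigment_level`` inside the ellipse and ``skin_level`` outside, additive
    Gaussian noise of sd ``image_noise_sd`` clipped to [0, 255], and the
    noise-free boolean lesion mask.
    """
    h, w = config.photo_size_px
    ax, ay = config.lesion_axes_px
    if 2 * ax >= w or 2 * ay >= h:
        raise InvalidInputError(
            f"lesion semi-axes {config.lesion_axes_px} do not fit in a "
            f"{h}x{w} photo"
        )
    mask = _ellipse_mask((h, w), (ax, ay))
    photo = np.where(mask, float(config.pigment_level), float(config.skin_level))
    if config.image_noise_sd > 0:
        photo = photo + rng.normal(0.0, config.image_noise_sd, size=photo.shape)
    return np.clip(np.rint(photo), 0, 255).astype(np.uint8), mask


def _mask_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Half-open bounding box (x0, y0, x1, y1) of the true pixels."""
    ys, xs = np.nonzero(mask)
    return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


def scenario_rect(
    bbox: tuple[int, int, int, int],
    scenario: str,
    photo_shape: tuple[int, int],
) -> tuple[int, int, int, int]:
    """Operator scan rectangle for one of the four clinical scenarios.

    a: congruent with the lesion bounding box (recommended procedure);
    b: box dilated by 50 % of its size on every side (skin included);
    c: left half of the lesion box (partial coverage, all pigmented);
    d: left half of the box shifted left by half its width, so roughly half
       the measured area lies on surrounding skin.
    """
    x0, y0, x1, y1 = bbox
    w, h = x1 - x0, y1 - y0
    if scenario == "a":
        rect = (x0, y0, x1, y1)
    elif scenario == "b":
        rect = (x0 - w // 2, y0 - h // 2, x1 + w // 2, y1 + h // 2)
    elif scenario == "c":
        rect = (x0, y0, x0 + w // 2, y1)
    elif scenario == "d":
        rect = (x0 - w // 4, y0, x0 + w // 2 - w // 4, y1)
    else:
        raise InvalidInputError(f"unknown scenario {scenario!r}")
    ph, pw = photo_shape
    rx0, ry0, rx1, ry1 = rect
    return (max(rx0, 0), max(ry0, 0), min(rx1, pw), min(ry1, ph))


def make_lesion_scan(
    diagnosis: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
    lesion_id: str = "lesion-0",
) -> LesionScan:
    """Generate one complete scan bundle in memory.

    ``diagnosis`` is the true lesion class (1 = melanoma).  Grid positions
    inside the true lesion mask emit malignant-type spectra with probability
    ``p_mal(diagnosis)`` and benign-type otherwise; positions outside emit
    weak skin-type spectra.  The three pathology labels equal the diagnosis,
    each independently flipped with ``label_flip_rate``.
    """
    photo, mask = make_lesion_image(config, rng)
    rect = scenario_rect(_mask_bbox(mask), config.scenario, photo.shape)
    p_mal = config.p_mal_melanoma if diagnosis == 1 else config.p_mal_nevus

    step_px = config.step_um / config.um_per_pixel
    x0, y0, x1, y1 = rect
    n_rows = max(int(np.ceil((y1 - y0) / step_px)), 1)
    n_cols = max(int(np.ceil((x1 - x0) / step_px)), 1)

    spectra: list[Spectrum] = []
    for row in range(n_rows):
        for col in range(n_cols):
            y = int(round(y0 + row * step_px))
            x = int(round(x0 + col * step_px))
            y = min(y, photo.shape[0] - 1)
            x = min(x, photo.shape[1] - 1)
            if mask[y, x]:
                kind = "malignant" if rng.random() < p_mal else "benign"
            else:
                kind = "skin"
            spectra.append(Spectrum(row, col, make_spectrum(kind, config, rng)))

    labels = tuple(
        int(diagnosis) ^ int(rng.random() < config.label_flip_rate) for _ in range(3)
    )
    return LesionScan(
        lesion_id=lesion_id,
        step_um=config.step_um,
        wavelengths_nm=raw_wavelength_grid(),
        spectra=spectra,
        photo=photo,
        scan_rect=rect,
        um_per_pixel=config.um_per_pixel,
        labels=PathologyRecord(labels),  # type: ignore[arg-type]
    )


def make_dataset(
    n_melanoma: int,
    n_nevus: int,
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> Dataset:
    """Generate a cohort of ``n_melanoma + n_nevus`` lesion scans.

    Per-lesion generators are spawned deterministically from the master seed,
    so the cohort is byte-identical across runs with the same seed.
    """
    if n_melanoma < 0 or n_nevus < 0:
        raise InvalidInputError("lesion counts must be non-negative")
    if n_melanoma + n_nevus == 0:
        raise InvalidInputError("at least one lesion is required")
    config = config or GeneratorConfig()
    children = np.random.SeedSequence(seed).spawn(n_melanoma + n_nevus)
    scans = []
    for i in range(n_melanoma):
        scans.append(
            make_lesion_scan(
                1, config, np.random.default_rng(children[i]), f"mel-{i:03d}"
            )
        )
    for j in range(n_nevus):
        scans.append(
            make_lesion_scan(
                0,
                config,
                np.random.default_rng(children[n_melanoma + j]),
                f"nev-{j:03d}",
            )
        )
    return Dataset(scans=scans)
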