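"""Synthetic mid-IR spectra and hyperspectral skin maps.

The generator emulates transmission FTIR microspectroscopy of paraffin
skin sections: absorbance spectra on a 900-4000 cm^-1 grid built as sums
of Gaussian/Lorentzian bands, with three tissue classes whose Amide I
composition encodes the protein-conformation contrasts seen between
normal epidermis (alpha-helix 1650, antiparallel beta-sheet 1695 cm^-1),
electrical marks (beta-sheet 1619, beta-turn 1681 cm^-1 elevated) and
collagen-rich dermis. Scatter distortions (multiplicative scale from
section thickness, additive offset and polynomial baseline) and white
detector noise are added so that EMSC preprocessing has work to do.

The module also reproduces the study design used throughout the package:
per-class spectrum counts for PCA calibration, PLS calibration, internal
prediction and external validation, plus 14x20-pixel raster maps from a
140 x 200 um^2 scan at a 10 um step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import Spectrum, SpectrumSet

CLASS_NORMAL_EPIDERMIS = "normal_epidermis"
CLASS_ELECTRICAL_MARK = "electrical_mark"
CLASS_NORMAL_DERMIS = "normal_dermis"
CLASS_BACKGROUND = "background"
TISSUE_CLASSES = (CLASS_NORMAL_EPIDERMIS, CLASS_ELECTRICAL_MARK,
                  CLASS_NORMAL_DERMIS)
ALL_CLASSES = TISSUE_CLASSES + (CLASS_BACKGROUND,)

SPLIT_PCA_CAL = "pca_cal"
SPLIT_PLS_CAL = "pls_cal"
SPLIT_INTERNAL_PRED = "internal_pred"
SPLIT_EXTERNAL_VAL = "external_val"


def default_grid(low: float = 900.0, high: float = 4000.0,
                 step: float = 4.0) -> np.ndarray:
    """Default ascending wavenumber grid, 900-4000 cm^-1 at 4 cm^-1.

    The 4 cm^-1 spacing is finer than the instrument's nominal 16 cm^-1
    resolution, emulating the zero-filled grids instrument software
    exports; it puts >=31 channels in the Amide I window so a 9-point
    derivative filter is meaningful there.
    """
    n = int(round((high - low) / step))
    return low + step * np.arange(n + 1)


@dataclass
class BandComponent:
    """One vibrational band: center (cm^-1), FWHM (cm^-1), peak amplitude."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 900.0 <= self.center <= 4000.0:
            raise ValueError("center must lie within [900, 4000] cm^-1")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, grid: np.ndarray, amplitude: float | None = None
                ) -> np.ndarray:
        """Band absorbance on ``grid`` (unit peak height times amplitude)."""
        a = self.amplitude if amplitude is None else amplitude
        x = grid - self.center
        if self.shape == "gaussian":
            return a * np.exp(-4.0 * math.log(2.0) * x ** 2 / self.fwhm ** 2)
        hw = self.fwhm / 2.0
        return a * hw ** 2 / (x ** 2 + hw ** 2)


@dataclass
class ClassProfile:
    """Band composition and variability of one tissue class.

    ``amplitude_cv`` is the relative standard deviation of per-spectrum,
    per-band amplitude jitter; ``noise_sd`` the additive white-noise
    standard deviation in absorbance units.
    """

    name: str
    bands: list[BandComponent]
    amplitude_cv: float = 0.10
    noise_sd: float = 0.005

    def __post_init__(self) -> None:
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def pure_spectrum(self, grid: np.ndarray) -> np.ndarray:
        """Deterministic, noise- and scatter-free band sum on ``grid``."""
        out = np.zeros_like(np.asarray(grid, dtype=float))
        for band in self.bands:
            out += band.profile(grid)
        return out

    def amplitude_at(self, center: float) -> float:
        """Mean amplitude of the band whose center is nearest ``center``
        (0 if the nearest band is more than its own FWHM away)."""
        best = 0.0
        dist = np.inf
        for band in self.bands:
            d = abs(band.center - center)
            if d < dist and d <= band.fwhm:
                best, dist = band.amplitude, d
        return best


@dataclass
class ScatterModel:
    """Additive/multiplicative scatter distortions applied per spectrum.

    The multiplicative scale is log-normal, ``exp(N(0, scale_log_sd))``, so
    it is always positive; offset, slope and curvature are Gaussian
    coefficients of a degree-2 baseline on the wavenumber axis rescaled to
    [-1, 1] — exactly the terms EMSC (degree 2) is built to remove.
    """

    offset_sd: float = 0.02
    scale_log_sd: float = 0.15
    slope_sd: float = 0.01
    curvature_sd: float = 0.005

    def __post_init__(self) -> None:
        for name in ("offset_sd", "scale_log_sd", "slope_sd", "curvature_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def none(cls) -> "ScatterModel":
        """A zeroed model: no scatter distortion at all."""
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass
class ScanGeometry:
    """Raster-scan geometry: scanned area (um), step (um), aperture (um)."""

    area_x: float = 140.0
    area_y: float = 200.0
    step: float = 10.0
    aperture: float = 40.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the pixel grid = floor(area / step) per axis."""
        return (int(self.area_x // self.step), int(self.area_y // self.step))


@dataclass
class StudyDesign:
    """Per-class spectrum counts for every analysis split.

    Defaults replicate the study layout: 35 electrical-mark and 46
    normal-epidermis spectra for PCA; 35/34/27 electrical / epidermis /
    dermis spectra for PLS calibration; 48 internal-prediction spectra
    drawn across the three classes; 17/20/14 external-validation spectra.
    """

    pca_cal_electrical: int = 35
    pca_cal_epidermis: int = 46
    pls_cal_electrical: int = 35
    pls_cal_epidermis: int = 34
    pls_cal_dermis: int = 27
    internal_pred_total: int = 48
    external_electrical: int = 17
    external_epidermis: int = 20
    external_dermis: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pca_cal_electrical", "pca_cal_epidermis",
                     "pls_cal_electrical", "pls_cal_epidermis",
                     "pls_cal_dermis", "internal_pred_total",
                     "external_electrical", "external_epidermis",
                     "external_dermis"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def internal_pred_counts(self) -> dict[str, int]:
        """Split the internal-prediction total across the three classes as
        evenly as possible (remainder to the earlier classes)."""
        base, rem = divmod(self.internal_pred_total, 3)
        return {cls_: base + (1 if i < rem else 0)
                for i, cls_ in enumerate(TISSUE_CLASSES)}


# ---------------------------------------------------------------------------
# Band library
# ---------------------------------------------------------------------------

def default_band_library() -> dict[str, ClassProfile]:
    """Mean band composition of the four map classes.

    Amide I sub-band geometry encodes the tissue contrasts: normal
    epidermis is dominated by alpha-helix (1650) with a clear antiparallel
    beta-sheet shoulder (1695); the electrical mark shows elevated
    beta-sheet (1619) and beta-turn (1681) with reduced 1650/1695 —
    the heat-denaturation signature; dermis is collagen-like with a strong
    1660 band and a 1631 triple-helix component. All tissue profiles also
    carry Amide II, C-H stretch and Amide A bands outside 1585-1710 cm^-1
    so that windowing is a meaningful operation. The background class has
    no bands at all.
    """
    g = "gaussian"
    epidermis = ClassProfile(CLASS_NORMAL_EPIDERMIS, [
        BandComponent(1650.0, 26.0, 0.80, g),   # alpha-helix
        BandComponent(1695.0, 20.0, 0.35, g),   # antiparallel beta-sheet
        BandComponent(1619.0, 22.0, 0.10, g),   # beta-sheet (minor)
        BandComponent(1681.0, 18.0, 0.08, g),   # beta-turn (minor)
        BandComponent(1548.0, 44.0, 0.45, g),   # Amide II
        BandComponent(2930.0, 42.0, 0.20, g),   # CH2 stretch
        BandComponent(3290.0, 130.0, 0.55, g),  # Amide A
        BandComponent(1080.0, 55.0, 0.15, g),   # carbohydrate region
    ])
    electrical = ClassProfile(CLASS_ELECTRICAL_MARK, [
        BandComponent(1619.0, 22.0, 0.60, g),   # beta-sheet (dominant)
        BandComponent(1681.0, 18.0, 0.42, g),   # beta-turn (elevated)
        BandComponent(1650.0, 26.0, 0.38, g),   # alpha-helix (reduced)
        BandComponent(1695.0, 20.0, 0.12, g),   # antiparallel (reduced)
        BandComponent(1545.0, 44.0, 0.42, g),   # Amide II
        BandComponent(2930.0, 42.0, 0.18, g),
        BandComponent(3285.0, 130.0, 0.50, g),
        BandComponent(1080.0, 55.0, 0.15, g),
    ])
    dermis = ClassProfile(CLASS_NORMAL_DERMIS, [
        BandComponent(1660.0, 28.0, 0.85, g),   # collagen amide I
        BandComponent(1631.0, 22.0, 0.35, g),   # collagen triple helix
        BandComponent(1695.0, 20.0, 0.05, g),
        BandComponent(1550.0, 44.0, 0.55, g),   # Amide II
        BandComponent(1338.0, 30.0, 0.20, g),   # collagen CH2 wag
        BandComponent(2935.0, 42.0, 0.15, g),
        BandComponent(3300.0, 130.0, 0.60, g),
        BandComponent(1082.0, 55.0, 0.25, g),
    ])
    background = ClassProfile(CLASS_BACKGROUND, [], amplitude_cv=0.0,
                              noise_sd=0.005)
    return {p.name: p for p in (epidermis, electrical, dermis, background)}


# ---------------------------------------------------------------------------
# Spectrum / dataset / map synthesis
# ---------------------------------------------------------------------------

def synth_spectrum(profile: ClassProfile, grid: np.ndarray,
                   scatter: ScatterModel, rng: np.random.Generator,
                   label: str | None = None) -> Spectrum:
    """Draw one synthetic spectrum.

    ``value = scale * sum_bands + offset + slope*nu* + curvature*nu*^2 +
    noise`` with per-band amplitudes jittered by ``profile.amplitude_cv``
    (truncated at zero) and ``nu*`` the grid rescaled to [-1, 1]. With a
    zeroed :class:`ScatterModel` and ``noise_sd = 0`` the result is the
    deterministic band sum.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")

    signal = np.zeros_like(grid)
    for band in profile.bands:
        amp = band.amplitude
        if profile.amplitude_cv > 0:
            amp = max(0.0, amp * (1.0 + profile.amplitude_cv *
                                  rng.standard_normal()))
        signal += band.profile(grid, amplitude=amp)

    offset = scatter.offset_sd * rng.standard_normal()
    slope = scatter.slope_sd * rng.standard_normal()
    curvature = scatter.curvature_sd * rng.standard_normal()
    scale = math.exp(scatter.scale_log_sd * rng.standard_normal())

    lo, hi = grid[0], grid[-1]
    nu_star = (2.0 * (grid - lo) / (hi - lo) - 1.0) if hi > lo else 0.0 * grid
    values = scale * signal + offset + slope * nu_star + curvature * nu_star ** 2
    if profile.noise_sd > 0:
        values = values + profile.noise_sd * rng.standard_normal(grid.size)
    return Spectrum(grid, values, label=label or profile.name)


def synth_dataset(design: StudyDesign,
                  library: dict[str, ClassProfile] | None = None,
                  grid: np.ndarray | None = None,
                  scatter: ScatterModel | None = None,
                  rng: np.random.Generator | None = None) -> SpectrumSet:
    """Generate the full labelled, split-tagged study dataset.

    Spectrum counts per (split, class) follow ``design`` exactly. All
    randomness flows from ``design.seed`` unless an explicit generator is
    passed; identical seeds give bit-identical datasets.
    """
    library = library if library is not None else default_band_library()
    grid = grid if grid is not None else default_grid()
    scatter = scatter if scatter is not None else ScatterModel()
    rng = rng if rng is not None else np.random.default_rng(design.seed)

    internal = design.internal_pred_counts()
    plan: list[tuple[str, str, int]] = [
        (SPLIT_PCA_CAL, CLASS_ELECTRICAL_MARK, design.pca_cal_electrical),
        (SPLIT_PCA_CAL, CLASS_NORMAL_EPIDERMIS, design.pca_cal_epidermis),
        (SPLIT_PLS_CAL, CLASS_ELECTRICAL_MARK, design.pls_cal_electrical),
        (SPLIT_PLS_CAL, CLASS_NORMAL_EPIDERMIS, design.pls_cal_epidermis),
        (SPLIT_PLS_CAL, CLASS_NORMAL_DERMIS, design.pls_cal_dermis),
        (SPLIT_INTERNAL_PRED, CLASS_NORMAL_EPIDERMIS,
         internal[CLASS_NORMAL_EPIDERMIS]),
        (SPLIT_INTERNAL_PRED, CLASS_ELECTRICAL_MARK,
         internal[CLASS_ELECTRICAL_MARK]),
        (SPLIT_INTERNAL_PRED, CLASS_NORMAL_DERMIS,
         internal[CLASS_NORMAL_DERMIS]),
        (SPLIT_EXTERNAL_VAL, CLASS_ELECTRICAL_MARK,
         design.external_electrical),
        (SPLIT_EXTERNAL_VAL, CLASS_NORMAL_EPIDERMIS,
         design.external_epidermis),
        (SPLIT_EXTERNAL_VAL, CLASS_NORMAL_DERMIS, design.external_dermis),
    ]

    rows, labels, splits, ids = [], [], [], []
    for split, cls_, count in plan:
        profile = library[cls_]
        for i in range(count):
            s = synth_spectrum(profile, grid, scatter, rng)
            rows.append(s.values)
            labels.append(cls_)
            splits.append(split)
            ids.append(f"{split}/{cls_}/{i:03d}")
    values = np.vstack(rows) if rows else np.empty((0, grid.size))
    return SpectrumSet(grid, values, labels=np.array(labels, dtype=object),
                       splits=np.array(splits, dtype=object),
                       ids=np.array(ids, dtype=object))


# ---------------------------------------------------------------------------
# Hyperspectral maps
# ---------------------------------------------------------------------------

@dataclass
class HyperMap:
    """A spatial grid of spectra: cube (rows x cols x channels) plus
    wavenumber grid, scan geometry and optional per-pixel truth labels."""

    cube: np.ndarray
    wavenumbers: np.ndarray
    geometry: ScanGeometry
    truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.cube.ndim != 3:
            raise ValueError("cube must be rows x cols x channels")
        if self.cube.shape[2] != self.wavenumbers.size:
            raise ValueError("cube depth must match grid length")
        if self.cube.shape[:2] != self.geometry.shape:
            raise ValueError("cube dims inconsistent with scan geometry")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=object)
            if self.truth.shape != self.cube.shape[:2]:
                raise ValueError("truth dims must match cube")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cube.shape[:2]

    def to_spectrum_set(self, mask: np.ndarray | None = None) -> SpectrumSet:
        """Flatten (a masked subset of) pixels into a SpectrumSet, with
        ids ``r{row}c{col}`` preserving pixel identity."""
        rows, cols, _ = self.cube.shape
        flat = self.cube.reshape(rows * cols, -1)
        idx = np.arange(rows * cols)
        if mask is not None:
            idx = idx[np.asarray(mask).reshape(-1)]
        labels = (self.truth.reshape(-1)[idx] if self.truth is not None
                  else None)
        ids = np.array([f"r{i // cols:02d}c{i % cols:02d}" for i in idx],
                       dtype=object)
        return SpectrumSet(self.wavenumbers, flat[idx], labels=labels,
                           ids=ids)


def lesion_layout(shape: tuple[int, int] = (14, 20)) -> np.ndarray:
    """Truth image of an electrical lesion: background above, an epidermal
    band whose central region is electrically injured, dermis below."""
    rows, cols = shape
    layout = np.full(shape, CLASS_NORMAL_DERMIS, dtype=object)
    bg_rows = max(1, rows // 7)
    epi_rows = max(2, rows // 3)
    layout[:bg_rows, :] = CLASS_BACKGROUND
    layout[bg_rows:bg_rows + epi_rows, :] = CLASS_NORMAL_EPIDERMIS
    c0, c1 = cols // 3, cols - cols // 3
    layout[bg_rows:bg_rows + epi_rows, c0:c1] = CLASS_ELECTRICAL_MARK
    return layout


def normal_skin_layout(shape: tuple[int, int] = (14, 20)) -> np.ndarray:
    """Truth image of normal skin: background, epidermis band, dermis."""
    rows, cols = shape
    layout = np.full(shape, CLASS_NORMAL_DERMIS, dtype=object)
    bg_rows = max(1, rows // 7)
    epi_rows = max(2, rows // 3)
    layout[:bg_rows, :] = CLASS_BACKGROUND
    layout[bg_rows:bg_rows + epi_rows, :] = CLASS_NORMAL_EPIDERMIS
    return layout


LAYOUTS = {"electrical_lesion": lesion_layout, "normal_skin":
           normal_skin_layout}


def synth_map(layout: np.ndarray | str,
              geometry: ScanGeometry | None = None,
              library: dict[str, ClassProfile] | None = None,
              grid: np.ndarray | None = None,
              scatter: ScatterModel | None = None,
              rng: np.random.Generator | None = None,
              seed: int = 0) -> HyperMap:
    """Generate a hyperspectral map: one spectrum per pixel drawn from the
    pixel's class profile. ``layout`` may be a truth-label image or the
    name of a built-in layout ('electrical_lesion' or 'normal_skin')."""
    geometry = geometry if geometry is not None else ScanGeometry()
    if isinstance(layout, str):
        layout = LAYOUTS[layout](geometry.shape)
    layout = np.asarray(layout, dtype=object)
    if layout.shape != geometry.shape:
        raise ValueError(
            f"layout dims {layout.shape} != geometry grid {geometry.shape}")
    library = library if library is not None else default_band_library()
    grid = grid if grid is not None else default_grid()
    scatter = scatter if scatter is not None else ScatterModel()
    rng = rng if rng is not None else np.random.default_rng(seed)

    rows, cols = layout.shape
    cube = np.empty((rows, cols, grid.size))
    for r in range(rows):
        for c in range(cols):
            cube[r, c] = synth_spectrum(library[layout[r, c]], grid,
                                        scatter, rng).values
    return HyperMap(cube, grid, geometry, truth=layout.copy())
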