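"""Pixel-wise classification of hyperspectral maps into tissue classes.

Each pixel of a raster-scanned absorbance cube is pushed through the
trained pipeline — EMSC against the stored calibration reference,
Savitzky-Golay second derivative, Amide I windowing, PLS prediction and
Y-thresholding — and the result is rendered as a pseudo-colored digital
map with a fixed legend: yellow = electrical mark, light blue = normal
epidermis, brown = normal dermis, dark blue = background.

Pixels with essentially no Amide I absorbance (bare substrate) are set
aside as background *before* EMSC, since fitting a multiplicative scale
to a near-zero spectrum is ill-posed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemometrics import PLSModel
from .preprocess import (AMIDE_I_WINDOW, Spectrum, emsc_correct,
                         extract_window, savgol_second_derivative)
from .synthgen import (ALL_CLASSES, CLASS_BACKGROUND, HyperMap, ScanGeometry,
                       TISSUE_CLASSES)

__all__ = ["HyperMap", "ScanGeometry", "ClassMap", "LEGEND",
           "classify_hypermap", "render_class_map", "decode_class_map",
           "confusion_on_truth"]

#: Fixed pseudo-color legend (RGB).
LEGEND = {
    "electrical_mark": (255, 255, 0),     # yellow
    "normal_epidermis": (173, 216, 230),  # light blue
    "normal_dermis": (139, 69, 19),       # brown
    "background": (0, 0, 139),            # dark blue
}
_RGB_TO_CLASS = {rgb: cls for cls, rgb in LEGEND.items()}


@dataclass
class ClassMap:
    """Per-pixel categorical image over the four map classes."""

    labels: np.ndarray  # (rows, cols) of str
    legend: dict[str, tuple[int, int, int]] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D image")
        if self.legend is None:
            self.legend = dict(LEGEND)
        unknown = set(self.labels.reshape(-1)) - set(self.legend)
        if unknown:
            raise ValueError(f"labels outside the legend: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def classify_hypermap(hmap: HyperMap, emsc_reference: Spectrum,
                      pls: PLSModel,
                      background_threshold: float | None = None,
                      emsc_degree: int = 2, sg_window: int = 9,
                      sg_order: int = 3,
                      window: tuple[float, float] = AMIDE_I_WINDOW
                      ) -> ClassMap:
    """Classify every pixel of a raw absorbance map.

    Pixels whose mean raw Amide I absorbance falls below
    ``background_threshold`` become background; by default the threshold
    is 10% of the map's median per-pixel Amide I absorbance (a heuristic
    — real instruments leave the choice to the analyst). All remaining
    pixels are EMSC-corrected against the stored calibration reference,
    second-derivative transformed, windowed and PLS-classified. Each
    pixel is treated independently.
    """
    nu = hmap.wavenumbers
    high, low = window
    amide = (nu >= low) & (nu <= high)
    if not amide.any():
        raise ValueError("Amide window does not intersect the map grid")
    pix_mean = hmap.cube[:, :, amide].mean(axis=2)
    if background_threshold is None:
        background_threshold = 0.1 * float(np.median(pix_mean))
    bg = pix_mean < background_threshold

    labels = np.full(hmap.shape, CLASS_BACKGROUND, dtype=object)
    if not bg.all():
        tissue = hmap.to_spectrum_set(mask=~bg)
        corrected = emsc_correct(tissue, reference=emsc_reference,
                                 poly_degree=emsc_degree).corrected
        deriv = savgol_second_derivative(corrected, sg_window, sg_order)
        windowed = extract_window(deriv, high, low)
        if pls.wavenumbers is not None and \
                not np.array_equal(windowed.wavenumbers, pls.wavenumbers):
            raise ValueError("map grid does not match the PLS training grid "
                             "after windowing")
        labels[~bg] = pls.classify(windowed)
    return ClassMap(labels)


def render_class_map(cmap: ClassMap, path, upscale: int = 1) -> None:
    """Write the class map as a PNG with the exact legend colors,
    one image pixel per spectrum (optionally integer-upscaled)."""
    from PIL import Image

    if upscale < 1:
        raise ValueError("upscale must be a positive integer")
    rows, cols = cmap.shape
    rgb = np.zeros((rows, cols, 3), dtype=np.uint8)
    for cls, color in cmap.legend.items():
        rgb[cmap.labels == cls] = color
    if upscale > 1:
        rgb = np.kron(rgb, np.ones((upscale, upscale, 1), dtype=np.uint8))
    Image.fromarray(rgb, mode="RGB").save(path, format="PNG")


def decode_class_map(path, upscale: int = 1) -> ClassMap:
    """Read a rendered class-map PNG back into labels (exact legend
    round trip); raises on any color outside the legend."""
    from PIL import Image

    rgb = np.asarray(Image.open(path).convert("RGB"))
    if upscale > 1:
        rgb = rgb[::upscale, ::upscale]
    rows, cols, _ = rgb.shape
    labels = np.empty((rows, cols), dtype=object)
    for r in range(rows):
        for c in range(cols):
            key = tuple(int(v) for v in rgb[r, c])
            if key not in _RGB_TO_CLASS:
                raise ValueError(f"pixel ({r},{c}) color {key} is not in "
                                 "the legend")
            labels[r, c] = _RGB_TO_CLASS[key]
    return ClassMap(labels)


def confusion_on_truth(cmap: ClassMap, truth: np.ndarray,
                       include_background: bool = False) -> pd.DataFrame:
    """Pixel confusion matrix (rows = truth, columns = prediction).

    Background pixels (in either map) are excluded unless
    ``include_background`` is set.
    """
    truth = np.asarray(truth, dtype=object)
    if truth.shape != cmap.shape:
        raise ValueError("truth dims must match the class map")
    classes = list(ALL_CLASSES) if include_background \
        else list(TISSUE_CLASSES)
    table = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(truth.reshape(-1), cmap.labels.reshape(-1)):
        if t in table.index and p in table.columns:
            table.loc[t, p] += 1
    table.index.name = "true"
    table.columns.name = "predicted"
    return table
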