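"""Spectral preprocessing: EMSC normalisation, Savitzky-Golay second
derivatives, and windowing.

The preprocessing chain mirrors standard mid-IR tissue workflows: raw
absorbance spectra are first normalised by extended multiplicative signal
correction (EMSC) against a reference spectrum, removing additive offsets,
a low-order polynomial baseline and the multiplicative scaling caused by
section-thickness variation; the corrected spectra are then transformed to
second derivatives with a Savitzky-Golay filter so that overlapping Amide I
sub-bands resolve into distinct negative minima; finally the analysis is
restricted to the protein-conformation window (1710-1585 cm^-1 by default).

The two in-memory containers here, :class:`Spectrum` and
:class:`SpectrumSet`, are shared by every other module in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import savgol_filter

MODE_ABSORBANCE = "absorbance"
MODE_SECOND_DERIVATIVE = "second_derivative"

#: Protein Amide I window bounds in cm^-1 (high, low).
AMIDE_I_WINDOW = (1710.0, 1585.0)


@dataclass
class Spectrum:
    """One absorbance (or second-derivative) trace on a wavenumber grid.

    Parameters
    ----------
    wavenumbers : array of float
        Strictly increasing wavenumber grid in cm^-1.
    values : array of float
        Absorbance (``mode="absorbance"``) or second-derivative absorbance
        per cm^-2 (``mode="second_derivative"``), same length as the grid.
    mode : str
        Either :data:`MODE_ABSORBANCE` or :data:`MODE_SECOND_DERIVATIVE`.
    label : str or None
        Optional tissue-class label.
    pixel : tuple of int or None
        Optional (row, col) position when the spectrum comes from a map.
    """

    wavenumbers: np.ndarray
    values: np.ndarray
    mode: str = MODE_ABSORBANCE
    label: str | None = None
    pixel: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavenumbers.ndim != 1 or self.values.ndim != 1:
            raise ValueError("wavenumbers and values must be 1-D")
        if self.wavenumbers.size != self.values.size:
            raise ValueError("wavenumbers and values must have equal length")
        if self.wavenumbers.size == 0:
            raise ValueError("empty wavenumber grid")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")


@dataclass
class SpectrumSet:
    """An aligned collection of spectra sharing one wavenumber grid.

    ``values`` is the (n_spectra, n_channels) predictor matrix; ``labels``
    and ``splits`` carry per-spectrum class labels and study-design split
    tags, ``ids`` unique spectrum identifiers.
    """

    wavenumbers: np.ndarray
    values: np.ndarray
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    splits: np.ndarray = field(default=None)  # type: ignore[assignment]
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    mode: str = MODE_ABSORBANCE

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.wavenumbers.size:
            raise ValueError("values width must match grid length")
        if self.wavenumbers.size and np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        n = self.values.shape[0]
        if self.labels is None:
            self.labels = np.array([""] * n, dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
        if self.splits is None:
            self.splits = np.array([""] * n, dtype=object)
        else:
            self.splits = np.asarray(self.splits, dtype=object)
        if self.ids is None:
            self.ids = np.array([f"s{i:04d}" for i in range(n)], dtype=object)
        else:
            self.ids = np.asarray(self.ids, dtype=object)
        for name, arr in (("labels", self.labels), ("splits", self.splits),
                          ("ids", self.ids)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per spectrum")

    @property
    def n_spectra(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum],
                     ids: Iterable[str] | None = None) -> "SpectrumSet":
        if not spectra:
            raise ValueError("need at least one spectrum")
        grid = spectra[0].wavenumbers
        for s in spectra[1:]:
            if not np.array_equal(s.wavenumbers, grid):
                raise ValueError("all spectra must share one grid")
        values = np.vstack([s.values for s in spectra])
        labels = np.array([s.label or "" for s in spectra], dtype=object)
        ids_arr = None if ids is None else np.array(list(ids), dtype=object)
        return cls(grid, values, labels=labels, ids=ids_arr,
                   mode=spectra[0].mode)

    def spectrum(self, i: int) -> Spectrum:
        label = self.labels[i] or None
        return Spectrum(self.wavenumbers, self.values[i], mode=self.mode,
                        label=label)

    def subset(self, mask: np.ndarray) -> "SpectrumSet":
        """Row subset (boolean mask or index array) on the same grid."""
        mask = np.asarray(mask)
        return SpectrumSet(self.wavenumbers, self.values[mask],
                           labels=self.labels[mask], splits=self.splits[mask],
                           ids=self.ids[mask], mode=self.mode)

    def select_split(self, split: str) -> "SpectrumSet":
        return self.subset(self.splits == split)

    def mean_spectrum(self) -> Spectrum:
        return Spectrum(self.wavenumbers, self.values.mean(axis=0),
                        mode=self.mode)


# ---------------------------------------------------------------------------
# EMSC
# ---------------------------------------------------------------------------

@dataclass
class EMSCResult:
    """Outcome of an EMSC correction.

    ``coefficients`` has one row per spectrum with columns
    ``(a, b, d1, ..., d_poly_degree)``: additive offset, multiplicative
    scale against the reference, and polynomial baseline coefficients on
    the wavenumber axis rescaled to [-1, 1]. Spectra whose fitted scale is
    non-positive are listed in ``flagged`` and returned uncorrected.
    """

    corrected: SpectrumSet
    coefficients: np.ndarray
    reference: Spectrum
    poly_degree: int
    flagged: np.ndarray


def _nu_star(wavenumbers: np.ndarray) -> np.ndarray:
    lo, hi = wavenumbers[0], wavenumbers[-1]
    if hi == lo:
        return np.zeros_like(wavenumbers)
    return 2.0 * (wavenumbers - lo) / (hi - lo) - 1.0


def emsc_correct(sset: SpectrumSet,
                 reference: Spectrum | str = "mean",
                 poly_degree: int = 2) -> EMSCResult:
    """Extended multiplicative signal correction against a reference.

    Each spectrum ``z`` is fit by least squares as

        z(nu) ~ a + b * m(nu) + sum_k d_k * nu*^k,   nu* in [-1, 1],

    where ``m`` is the reference, and corrected as
    ``(z - a - sum_k d_k nu*^k) / b``. The reference defaults to the set
    mean. Spectra with fitted ``b <= 0`` are flagged and left uncorrected
    rather than silently sign-flipped.
    """
    if sset.n_spectra == 0:
        raise ValueError("empty SpectrumSet")
    if poly_degree not in (0, 1, 2):
        raise ValueError("poly_degree must be 0, 1 or 2")
    if isinstance(reference, str):
        if reference != "mean":
            raise ValueError("reference must be a Spectrum or 'mean'")
        ref = sset.mean_spectrum()
    else:
        ref = reference
        if not np.array_equal(ref.wavenumbers, sset.wavenumbers):
            raise ValueError("reference not on the set's grid")
    m = ref.values
    if np.ptp(m) == 0:
        raise ValueError("constant reference makes the EMSC design singular")

    nu = _nu_star(sset.wavenumbers)
    # design columns: 1, nu*, ..., nu*^deg, m
    cols = [np.ones_like(nu)]
    cols += [nu ** k for k in range(1, poly_degree + 1)]
    cols.append(m)
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, sset.values.T, rcond=None)
    a = coef[0]
    d = coef[1:1 + poly_degree]
    b = coef[-1]

    baseline = a[:, None] + (d.T @ np.vstack([nu ** k for k in
                                              range(1, poly_degree + 1)])
                             if poly_degree else 0.0)
    flagged = np.flatnonzero(b <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = (sset.values - baseline) / b[:, None]
    corrected[flagged] = sset.values[flagged]

    out = replace(sset, values=corrected)
    coeffs = np.column_stack([a, b] + ([d.T[:, k] for k in range(poly_degree)]
                                       if poly_degree else []))
    return EMSCResult(out, coeffs, ref, poly_degree, flagged)


# ---------------------------------------------------------------------------
# Savitzky-Golay second derivative
# ---------------------------------------------------------------------------

def savgol_second_derivative(sset: SpectrumSet, window_points: int = 9,
                             poly_order: int = 3) -> SpectrumSet:
    """Second derivative (per cm^-2) by local polynomial (Savitzky-Golay) fit.

    The grid must be uniformly spaced. At each channel the value is the
    exact second derivative of the degree-``poly_order`` polynomial fitted
    over ``window_points`` neighbouring channels; at the edges the filter
    fits the one-sided window polynomial instead of wrapping around.
    """
    if window_points % 2 != 1:
        raise ValueError("window_points must be odd")
    if poly_order < 2:
        raise ValueError("poly_order must be >= 2 for a second derivative")
    if window_points < poly_order + 1:
        raise ValueError("window_points must be >= poly_order + 1")
    if sset.n_channels < window_points:
        raise ValueError("fewer channels than filter window")
    steps = np.diff(sset.wavenumbers)
    if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-10):
        raise ValueError("non-uniform wavenumber grid")
    deriv = savgol_filter(sset.values, window_points, poly_order, deriv=2,
                          delta=steps[0], axis=-1, mode="interp")
    return replace(sset, values=deriv, mode=MODE_SECOND_DERIVATIVE)


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def extract_window(sset: SpectrumSet, high: float, low: float) -> SpectrumSet:
    """Restrict to channels with ``low <= nu <= high`` (closed interval)."""
    if high <= low:
        raise ValueError("window requires high > low")
    mask = (sset.wavenumbers >= low) & (sset.wavenumbers <= high)
    if not mask.any():
        raise ValueError("window does not intersect the grid")
    return replace(sset, wavenumbers=sset.wavenumbers[mask],
                   values=sset.values[:, mask])
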