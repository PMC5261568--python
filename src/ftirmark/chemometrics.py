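"""PCA exploration and dummy-coded PLS1 classification.

Two statistical engines operate on the preprocessed (second-derivative,
Amide-I-windowed) predictor matrix X:

* Principal component analysis, computed by singular value decomposition
  of the column-mean-centered matrix, for exploratory score/loading
  plots with Hotelling-style confidence ellipses.

* Partial least squares regression of a single dummy-coded response
  (normal epidermis = 1, electrical mark = 2, normal dermis = 3) fitted
  by the 1-block NIPALS algorithm, with leave-one-out cross-validation
  to pick the number of latent factors, and fixed thresholds on the
  predicted Y axis to turn the regression into a three-class rule:
  y < 1.5 -> normal epidermis, 1.5 <= y <= 2.5 -> electrical mark,
  y > 2.5 -> normal dermis.

X is mean-centered but never variance-scaled: channels share units and
EMSC has already normalised the overall scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .preprocess import SpectrumSet

#: Dummy coding of the single PLS response.
DUMMY_CODES = {
    "normal_epidermis": 1.0,
    "electrical_mark": 2.0,
    "normal_dermis": 3.0,
}

#: Wavenumber used to orient PC1: the beta-sheet loading of the injured
#: class is reported at 1621 cm^-1 and must come out positive.
PC1_ORIENT_WAVENUMBER = 1621.0


def _as_matrix(X) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(X, SpectrumSet):
        return X.values, X.wavenumbers
    return np.atleast_2d(np.asarray(X, dtype=float)), None


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    mean: np.ndarray
    loadings: np.ndarray            # (n_components, n_channels), rows o.n.
    scores: np.ndarray              # (n_spectra, n_components)
    explained_variance_pct: np.ndarray
    n_components: int
    wavenumbers: np.ndarray | None = None

    def transform(self, X) -> np.ndarray:
        values, _ = _as_matrix(X)
        return (values - self.mean) @ self.loadings.T


def pca_fit(X, n_components: int) -> PCAModel:
    """PCA of the column-mean-centered matrix via SVD.

    ``explained_variance_pct[k] = 100 * s_k^2 / sum(s^2)``. Sign
    convention: every loading is oriented so its largest-magnitude
    element is positive; PC1 is then re-oriented, if needed, so the
    loading at the channel nearest 1621 cm^-1 is positive — this puts
    the electrically injured class's beta-sheet feature on the positive
    loading side, matching the field's reporting convention.
    """
    values, wavenumbers = _as_matrix(X)
    n, p = values.shape
    limit = min(n - 1, p)
    if not 1 <= n_components <= limit:
        raise ValueError(f"n_components must be in [1, {limit}]")
    mean = values.mean(axis=0)
    centered = values - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(s ** 2))
    loadings = vt[:n_components]
    scores = u[:, :n_components] * s[:n_components]
    explained = 100.0 * s[:n_components] ** 2 / total

    signs = np.sign(loadings[np.arange(n_components),
                             np.argmax(np.abs(loadings), axis=1)])
    signs[signs == 0] = 1.0
    loadings = loadings * signs[:, None]
    scores = scores * signs[None, :]
    if wavenumbers is not None and \
            wavenumbers[0] <= PC1_ORIENT_WAVENUMBER <= wavenumbers[-1]:
        ch = int(np.argmin(np.abs(wavenumbers - PC1_ORIENT_WAVENUMBER)))
        if loadings[0, ch] < 0:
            loadings[0] = -loadings[0]
            scores[:, 0] = -scores[:, 0]
    return PCAModel(mean, loadings, scores, explained, n_components,
                    wavenumbers)


@dataclass
class ConfidenceEllipse:
    """A (1-alpha) coverage ellipse of a 2-D Gaussian score cloud."""

    center: np.ndarray
    semi_axes: np.ndarray     # descending
    rotation: float           # radians, angle of the major axis
    level: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points) - self.center
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        rot = np.array([[c, s], [-s, c]])  # into the ellipse frame
        local = pts @ rot.T
        return (local[:, 0] / self.semi_axes[0]) ** 2 + \
               (local[:, 1] / self.semi_axes[1]) ** 2 <= 1.0


def confidence_ellipse(scores_2d: np.ndarray,
                       level: float = 0.95) -> ConfidenceEllipse:
    """Coverage ellipse from the 2-D sample mean and covariance.

    Semi-axis lengths are ``sqrt(eigenvalue * chi2_2.ppf(level))``, the
    standard bivariate-normal construction used for score-plot
    confidence circles.
    """
    pts = np.atleast_2d(np.asarray(scores_2d, dtype=float))
    if pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("need >= 3 two-dimensional points")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if np.min(eigvals) <= 0:
        raise ValueError("degenerate score covariance")
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    radius2 = chi2.ppf(level, df=2)
    semi = np.sqrt(eigvals * radius2)
    rotation = float(np.arctan2(eigvecs[1, 0], eigvecs[0, 0]))
    return ConfidenceEllipse(center, semi, rotation, level)


# ---------------------------------------------------------------------------
# Threshold rule
# ---------------------------------------------------------------------------

@dataclass
class ThresholdRule:
    """Class boundaries on the predicted dummy Y axis.

    The electrical interval is closed on both ends: y = 1.5 and y = 2.5
    are both classified electrical, so every real y maps to exactly one
    class.
    """

    lower: float = 1.5
    upper: float = 2.5
    codes: dict[str, float] = field(
        default_factory=lambda: dict(DUMMY_CODES))

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("boundaries must be ordered")

    def classify(self, y_pred: np.ndarray) -> np.ndarray:
        y = np.atleast_1d(np.asarray(y_pred, dtype=float))
        out = np.empty(y.shape, dtype=object)
        out[y < self.lower] = "normal_epidermis"
        out[(y >= self.lower) & (y <= self.upper)] = "electrical_mark"
        out[y > self.upper] = "normal_dermis"
        return out

    def encode(self, labels) -> np.ndarray:
        return np.array([self.codes[str(l)] for l in np.asarray(labels)])

    def y_range(self, cls: str) -> str:
        return {"normal_epidermis": f"0–{self.lower:g}",
                "electrical_mark": f"{self.lower:g}–{self.upper:g}",
                "normal_dermis": f">{self.upper:g}"}[cls]


def classify_y(y_pred: np.ndarray,
               rule: ThresholdRule | None = None) -> np.ndarray:
    """Map predicted dummy-Y values to class labels."""
    return (rule or ThresholdRule()).classify(y_pred)


# ---------------------------------------------------------------------------
# PLS1 (NIPALS)
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """A fitted 1-block (single-response) PLS regression.

    ``weights`` (W), ``x_loadings`` (P) and ``y_loadings`` (q) are stored
    per latent factor; ``coef`` is the assembled regression vector
    B = W (P'W)^-1 q so that ``y_hat = y_mean + (x - x_mean) B``.
    Predicting the training X mean therefore returns the training y mean
    exactly.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray        # (n_factors, n_channels)
    x_loadings: np.ndarray     # (n_factors, n_channels)
    y_loadings: np.ndarray     # (n_factors,)
    coef: np.ndarray           # (n_channels,)
    n_latent_factors: int
    x_variance_explained_pct: np.ndarray
    thresholds: ThresholdRule = field(default_factory=ThresholdRule)
    wavenumbers: np.ndarray | None = None

    def predict(self, X) -> np.ndarray:
        values, wavenumbers = _as_matrix(X)
        if self.wavenumbers is not None and wavenumbers is not None and \
                not np.array_equal(wavenumbers, self.wavenumbers):
            raise ValueError("prediction grid differs from training grid")
        return self.y_mean + (values - self.x_mean) @ self.coef

    def classify(self, X) -> np.ndarray:
        return self.thresholds.classify(self.predict(X))


def _nipals_path(Xc: np.ndarray, yc: np.ndarray, max_factors: int):
    """Run NIPALS PLS1 on centered data; return (W, P, q, coefs) where
    ``coefs[k]`` is the regression vector using k+1 factors."""
    n, p = Xc.shape
    W, P, Q, coefs, xvar = [], [], [], [], []
    ssx_total = float(np.sum(Xc ** 2))
    Xk = Xc.copy()
    yk = yc.copy()
    eps = 1e-12 * max(1.0, float(np.abs(Xc).max()) or 1.0)
    for _ in range(max_factors):
        w = Xk.T @ yk
        nw = float(np.linalg.norm(w))
        if nw <= eps:
            break  # deflation exhausted: X carries no further y-covariance
        w /= nw
        t = Xk @ w
        tt = float(t @ t)
        if tt <= eps ** 2:
            break
        p_vec = Xk.T @ t / tt
        q = float(yk @ t / tt)
        Xk = Xk - np.outer(t, p_vec)
        yk = yk - t * q
        W.append(w)
        P.append(p_vec)
        Q.append(q)
        xvar.append(100.0 * tt * float(p_vec @ p_vec) /
                    ssx_total if ssx_total else 0.0)
        Wm = np.column_stack(W)
        Pm = np.column_stack(P)
        coefs.append(Wm @ np.linalg.solve(Pm.T @ Wm, np.array(Q)))
    if not W:
        raise ValueError("degenerate problem: X carries no y covariance")
    return (np.array(W), np.array(P), np.array(Q), coefs, np.array(xvar))


def pls1_fit(X, y: np.ndarray, n_latent_factors: int,
             thresholds: ThresholdRule | None = None) -> PLSModel:
    """Fit PLS1 by NIPALS with ``n_latent_factors`` latent factors.

    Per factor: w = X'y / ||X'y||; t = Xw; p = X't / t't; q = y't / t't;
    then X and y are deflated by the rank-one factor contribution.
    """
    values, wavenumbers = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if values.shape[0] != y.size:
        raise ValueError("X rows must match len(y)")
    if n_latent_factors < 1:
        raise ValueError("n_latent_factors must be >= 1")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance response")
    x_mean = values.mean(axis=0)
    y_mean = float(y.mean())
    W, P, Q, coefs, xvar = _nipals_path(values - x_mean, y - y_mean,
                                        n_latent_factors)
    k = len(coefs)
    if k < n_latent_factors:
        raise ValueError(
            f"deflation degenerate after {k} factors "
            f"(requested {n_latent_factors}); X rank too low")
    return PLSModel(x_mean, y_mean, W, P, Q, coefs[-1], k, xvar,
                    thresholds=thresholds or ThresholdRule(),
                    wavenumbers=wavenumbers)


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """LOOCV sweep over candidate factor counts.

    ``rmsecv[k-1]`` is the root-mean-square error of the held-out
    predictions with k factors; ``chosen`` (1-based) is the first local
    minimum of that curve, ties resolved toward fewer factors;
    ``predictions`` holds the per-left-out-sample predicted y for every
    candidate count, ``predicted_y`` the column at the chosen count.
    """

    rmsecv: np.ndarray
    chosen: int
    predictions: np.ndarray    # (n_samples, n_candidates)
    predicted_y: np.ndarray


def pls_loocv(X, y: np.ndarray, max_factors: int = 10) -> CVResult:
    """Leave-one-out cross-validation of the PLS1 factor count.

    Every sample is predicted by a model refit on the other n-1 samples,
    for each candidate factor count 1..max_factors (capped by the
    training rank). Predictions are independent of sample order.
    """
    values, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n = values.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    if max_factors < 1:
        raise ValueError("max_factors must be >= 1")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance response")
    cap = min(max_factors, n - 2, values.shape[1])
    preds = np.empty((n, cap))
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xt, yt = values[keep], y[keep]
        xm, ym = Xt.mean(axis=0), float(yt.mean())
        _, _, _, coefs, _ = _nipals_path(Xt - xm, yt - ym, cap)
        row = np.empty(cap)
        for k in range(cap):
            b = coefs[min(k, len(coefs) - 1)]
            row[k] = ym + (values[i] - xm) @ b
        preds[i] = row
    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    chosen = cap
    for k in range(cap - 1):
        if rmsecv[k] <= rmsecv[k + 1]:
            chosen = k + 1
            break
    return CVResult(rmsecv, chosen, preds, preds[:, chosen - 1])


# ---------------------------------------------------------------------------
# Accuracy table
# ---------------------------------------------------------------------------

def accuracy_table(pred_labels, true_labels,
                   rule: ThresholdRule | None = None) -> pd.DataFrame:
    """Per-class prediction table: correct/false counts and accuracy (%).

    One row per true class (in dummy-code order), with the class's
    predicted-Y range, ``correct``/``false`` counts out of ``n``, and
    accuracy in percent rounded to 0.1.
    """
    pred = np.asarray(pred_labels, dtype=object)
    true = np.asarray(true_labels, dtype=object)
    if pred.shape != true.shape:
        raise ValueError("label vectors must have equal length")
    rule = rule or ThresholdRule()
    classes = [c for c in rule.codes if c in set(true)]
    if not classes:
        raise ValueError("no true label matches a known class")
    rows = []
    for cls in classes:
        mask = true == cls
        total = int(mask.sum())
        correct = int(np.sum(pred[mask] == cls))
        rows.append({
            "class": cls,
            "y_range": rule.y_range(cls),
            "n": total,
            "correct": correct,
            "false": total - correct,
            "accuracy_pct": round(100.0 * correct / total, 1),
        })
    return pd.DataFrame(rows)
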