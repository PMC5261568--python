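# Methods

## The problem and the pipeline

Electrical injury denatures skin proteins much like heat does: α-helical
content drops and β-sheet content rises. In mid-IR absorbance spectra of
unstained tissue sections this appears as a redistribution of the Amide I
band (1710–1585 cm⁻¹, protein C=O stretching) among its secondary-
structure sub-bands: α-helix ~1650 cm⁻¹ and antiparallel β-sheet ~1695
cm⁻¹ (dominant in normal epidermis) versus β-sheet ~1619 cm⁻¹ and β-turn
~1681 cm⁻¹ (elevated in the electrical mark). Dermis is collagen-rich and
spectrally distinct again (amide I centered near 1660 cm⁻¹ with a ~1631
cm⁻¹ triple-helix component).

The pipeline runs: spectrum simulation (or import) → EMSC normalisation →
Savitzky–Golay second derivative → Amide I windowing → PCA (exploration)
→ dummy-coded PLS1 with LOOCV (classification) → pixel-wise map
classification with pseudo-color rendering.

## Synthetic-data generator

Real patient spectra are not available, so a generator provides data with
the statistical structure the analysis assumes.

**Spectra.** Each class is a sum of Gaussian bands (Lorentzian available;
second-derivative behaviour is equivalent for the checks used). One
synthetic spectrum is

    z(ν) = s · Σ_b A_b g_b(ν) + a + d₁ν* + d₂ν*²  + ε(ν)

with per-band amplitudes A_b jittered by a relative SD `amplitude_cv`
(truncated at zero), a log-normal multiplicative scale
s = exp(N(0, `scale_log_sd`)) emulating section-thickness variation, a
random quadratic baseline on the axis rescaled to ν* ∈ [−1, 1] (the same
parameterisation the EMSC design matrix removes), and white noise ε with
SD `noise_sd`. Defaults: `noise_sd` = 0.005 absorbance,
`amplitude_cv` = 0.10, `scale_log_sd` = 0.15, `offset_sd` = 0.02,
`slope_sd` = 0.01, `curvature_sd` = 0.005. These were chosen once to give
visible class overlap in raw spectra while keeping the classes separable
after preprocessing; no quantitative within-class variances exist to
emulate, only the qualitative class contrasts.

**Band library.** Amplitudes and widths are not reported anywhere for
this system, so the default library encodes the qualitative contrasts
only: normal epidermis 1650 (0.80) ≫ 1695 (0.35) ≫ minor 1619/1681;
electrical mark 1619 (0.60) and 1681 (0.42) elevated with 1650 reduced to
0.38; dermis 1660 (0.85) + 1631 (0.35). Sub-band FWHMs are 18–28 cm⁻¹,
narrow enough that the 9-point second derivative resolves neighbouring
sub-bands 14 cm⁻¹ apart when one of the pair dominates. Every tissue
class also carries Amide II, C–H stretch, Amide A and carbohydrate-region
bands so that windowing at 1710–1585 cm⁻¹ is a meaningful operation. The
background class has no bands.

**Grid.** 900–4000 cm⁻¹ ascending at 4 cm⁻¹ — finer than the 16 cm⁻¹
instrument resolution, emulating the zero-filled grids instrument
software exports, and giving 31 channels in the Amide I window so a
9-point filter is meaningful there.

**Study design.** Default split sizes replicate the study layout: PCA
calibration 35 electrical + 46 normal-epidermis spectra; PLS calibration
35/34/27 (electrical/epidermis/dermis); 48 internal-prediction spectra;
17/20/14 external-validation spectra. The 48 internal spectra are not
broken down by class in the source design; they are split as evenly as
possible (16/16/16). Maps are 14×20 pixels from a 140 × 200 μm² area at a
10 μm step (`floor(area/step)` per axis), with two built-in layouts:
`electrical_lesion` (background strip, epidermal band with a central
electrical region, dermis below) and `normal_skin` (no electrical
region).

**What the generator does not emulate.** Pixels are drawn independently,
although the real 40 × 40 μm aperture overlaps at a 10 μm step and
correlates neighbours; there is no Mie scattering, water-vapor lines,
paraffin residue, or detector drift. Passing tests therefore demonstrate
the correctness and internal consistency of the algorithms under the
assumed noise model, not instrument-grade robustness.

## Preprocessing

**EMSC** fits each spectrum by least squares on the 4-column design
[1, ν*, ν*², m(ν)] (degree-2 baseline by default; degrees 0–2
supported) and divides out the multiplicative coefficient. The reference
is the mean raw spectrum of the calibration splits only (pca_cal +
pls_cal + internal_pred); validation and map spectra are corrected
against this stored reference, so no information leaks from prediction
data into the correction. A fitted scale b ≤ 0 (a spectrum anticorrelated
with the reference) is flagged and left uncorrected rather than silently
sign-flipped; a constant reference raises. EMSC is applied to the full
900–4000 cm⁻¹ range before windowing — correcting inside a narrow window
would leave the baseline under-determined. Correcting an already
corrected set against the same reference is a no-op (the residual is
orthogonal to the design), which the suite asserts at 1e−9.

**Second derivative.** 9-point Savitzky–Golay, polynomial order 3 (the
source states only "9 points"; orders 2 and 3 give identical
second-derivative coefficients, so 3 is a presentation choice), exact for
polynomials up to the order, computed per cm⁻² on the uniform grid, with
one-sided polynomial fits at the edges. The derivative output is not
re-normalised. Windowing keeps the closed interval [1585, 1710] cm⁻¹ —
31 channels on the default grid.

## Band analysis

Band centers appear as negative minima of the second derivative. Peak
positions are refined by a parabola through the minimum and its
neighbours: the 4 cm⁻¹ grid is coarse relative to the 2–3 cm⁻¹ band
shifts that matter here, and refinement recovers, e.g., a band centered
exactly between two grid points. A local minimum is accepted with strict
descent on the left and non-strict on the right, so the two-point plateau
produced by such a symmetric band yields exactly one peak. Assignment to
the four structures is greedy deepest-first within ±8 cm⁻¹ of the nominal
centers (1650/1695/1619/1681); reported band positions drift by 2–3 cm⁻¹
between spectra, so exact matching would be wrong, while ±8 cm⁻¹ (two
grid steps) cannot cross to a neighbouring structure. Intensity maps
support both a raw-absorbance-at-center mode and the default
assigned-band-depth mode, since figure-level "peak absorbance intensity"
rendering is realisable either way.

## Chemometrics

**PCA** is the SVD of the column-centered matrix; explained variance per
component is 100·σₖ²/Σσ². Loadings are sign-fixed (largest-magnitude
element positive), then PC1 is re-oriented if needed so the loading at
the channel nearest 1621 cm⁻¹ is positive — the convention that puts the
electrical β-sheet feature on the positive side. On the default synthetic
calibration set this yields complete sign separation of the two classes
along PC1 with the 1650 cm⁻¹ loading negative, mirroring the expected
loading structure. Confidence ellipses use the bivariate-normal
construction: semi-axes √(λᵢ·χ²₂(level)) from the 2-D sample covariance
eigenvalues.

**PLS1.** The single response is the dummy code 1/2/3; thresholding one
predicted-Y axis (rather than one-hot PLS2) matches the one-dimensional
prediction plot this workflow is built around. NIPALS with rank-one
deflation; the regression vector is assembled as B = W(PᵀW)⁻¹q. At full
rank it equals the OLS solution and with one factor it is proportional to
Xᵀy (both asserted). X is mean-centered but not variance-scaled: channels
share units and EMSC already normalises overall scale. The number of
latent factors is not stated in the source design; it is chosen as the
first local minimum of the LOOCV RMSECV curve (ties toward fewer
factors), capped at 10. LOOCV refits on every n−1 subset, so its
predictions are order-invariant (asserted by permutation). Both the
RMSECV curve and the per-sample cross-validated predictions are exposed,
since cross-validation can legitimately serve either to pick the factor
count or purely to evaluate the classification.

**Thresholds.** y < 1.5 → normal epidermis; 1.5 ≤ y ≤ 2.5 → electrical
mark (closed on both ends, so every real y maps to exactly one class);
y > 2.5 → normal dermis. Accuracy tables report per-true-class
correct/false counts and accuracy to 0.1%.

## Map classification

Pixels whose mean raw Amide I absorbance is below a threshold become
background *before* EMSC, because fitting a multiplicative scale to a
near-zero spectrum is ill-posed. The source figures do not state how
background was decided; the default heuristic is 10% of the map's median
per-pixel Amide I absorbance, and the threshold is exposed as a
parameter. Raising it only grows the background region (tissue-pixel
predictions are per-pixel independent and cannot change). The remaining
pixels run through the stored-reference EMSC → derivative → window → PLS
→ threshold chain. Rendering uses fixed legend colors — yellow
(255,255,0) electrical mark, light blue (173,216,230) normal epidermis,
brown (139,69,19) normal dermis, dark blue (0,0,139) background — chosen
as the nearest standard named colors to the described legend; the
encoding is bijective and round-trips exactly through PNG. No spatial
smoothing is applied: maps show raw per-pixel predictions.

## Numerical and degenerate-input choices

* Grid uniformity for the derivative is checked at rtol 1e−8; non-uniform
  grids raise.
* Parabolic refinement with a zero curvature denominator falls back to
  the raw grid position.
* PLS deflation stops when ‖Xᵀy‖ underflows (rank exhausted); requesting
  more factors than the data support raises, while LOOCV silently reuses
  the highest attainable factor count for the remaining candidates.
* Constant y, < 3 samples for LOOCV, degenerate 2-D covariance for
  ellipses, and inverted window bounds all raise explicit errors.
* All randomness descends from one integer seed through named per-stage
  substreams (`default_rng([seed, stage])`), making every pipeline run
  bit-reproducible; the run manifest records config hash and SHA-256
  digests of all numeric artifacts.

## Problem sizes

Default test and acceptance runs use the study-scale design (276 spectra
of 776 channels, two 280-pixel maps); the pipeline tests use reduced
designs of the same shape (6–12 spectra per class). A full end-to-end run
completes in a few seconds on one CPU.

## Known limitations

Accuracy achieved on synthetic data (typically 100% per class at default
noise) shows the implementation is correct and the study-scale design is
adequate for the class contrasts assumed; it does not certify performance
on real tissue, where within-class heterogeneity, scattering artifacts
and spatial correlation are all richer than the generator's model. The
JCAMP-DX importer deliberately supports only the plain AFFN dialect.
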