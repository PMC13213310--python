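# Methods

## Data model and acquisition geometry

A `SpectralDataset` holds a strictly increasing wavenumber axis (cm⁻¹), an
`n_spectra × n_channels` intensity matrix, and one metadata row per spectrum
(sample id such as `NW5_CAA`, tissue class NA/CAA, weight class NW/OW, ROI
id, map coordinates in µm). Acquisition maps are square ROIs rastered with a
motorized stage; the grid is border-inclusive, so a 30 µm × 30 µm ROI at
1 µm step gives 31 × 31 = 961 positions. Analysis is restricted to the
fingerprint (900–1800 cm⁻¹) and high-wavenumber (2700–3100 cm⁻¹) windows —
closed intervals, since endpoint handling is a free choice — and every stage
after region cutting runs independently per region, each region treated as
its own calibration axis. Files with descending axes are reversed on read
with a logged notice; delimiters (tab/comma/semicolon) are auto-detected.

## Preprocessing

Four steps per spectrum, in this order: baseline correction → SNV →
Savitzky–Golay smoothing → zero-offset shift. No re-normalization follows
the zero shift.

* **Baseline**: iterative min-clipping ("ModPoly"-style) polynomial fit.
  The spectrum is fitted with an order-*n* polynomial on the axis mapped to
  [−1, 1] (conditioning), clipped to the pointwise minimum of itself and the
  fit, and refitted until the baseline changes by < `tol` (relative to the
  spectrum range) or `max_iter` is reached. Sharp Raman bands bias an
  ordinary fit upward; clipping converges onto the broad fluorescence
  background beneath them. Defaults: order 5, `max_iter` 100, `tol` 1e-6.
  The order used by the original instrument software is not documented, so
  it is a configuration parameter.
* **SNV**: (x − mean)/sd with sample sd (ddof = 1, the conventional SNV
  definition; ddof = 0 available). Spectra whose sd is zero or below
  1e-12 × max(1, |mean|) — flat up to floating-point residue, e.g. a
  constant spectrum after baseline subtraction — are rejected as degenerate
  with the offending spectrum named.
* **Savitzky–Golay**: polynomial order 2; window length 11 channels by
  default (roughly half a condensed-phase band FWHM at 1 cm⁻¹ sampling —
  the window is not documented upstream and is configurable). Edges use
  polynomial extrapolation of the edge window.
* **Zero shift**: subtract the per-spectrum minimum.

The chain is deterministic; two runs on the same input are bit-identical.

## PCA-seeded EMSC

Carotenoid bands (1004, 1155, 1520 cm⁻¹) are resonance enhanced at 532 nm
and their intensity is temperature sensitive, so they vary spectrum-to-
spectrum in a way SNV cannot normalize. The correction models each
preprocessed spectrum as

    s = a + Σ_{i=1..p} c_i t^i + b·r + Σ_j d_j g_j + e

with reference `r` = dataset mean, `t` the axis affinely mapped to [−1, 1],
polynomial order p = 4, and interference spectra `g_j` = leading PCA
loadings of the same preprocessed dataset (mean-centred PCA; loadings used
raw — the reference absorbs the mean). Coefficients come from ordinary
least squares via a rank-revealing factorization; the corrected spectrum is
`(s − a − Σ c_i t^i − Σ d_j g_j)/b`. The design matrix is rank-checked at
assembly (a collinear column is named in the error) and its condition
number logged. |b| ≤ 1e-6 marks a degenerate fit; dataset-level correction
quarantines such spectra rather than aborting.

Component count: by default the smallest k whose cumulative explained
variance reaches 0.96, capped at 10; a fixed `n_components=5` switch is
available. Selection is by variance, with the loadings written out for
manual inspection of their carotenoid character.

Two properties worth stating precisely:

* **Idempotence holds for the fitted operator, not the pipeline.**
  Re-correcting with the *same* `EMSCModel` is a no-op to machine precision
  (residuals are orthogonal to the design). Re-running PCA extraction and
  model building on already-corrected data is *not* idempotent: a fresh
  interference basis absorbs residual structure (measured ~2.5% change on
  synthetic cohorts), and the per-spectrum division by `b` makes residual
  means interact with a re-estimated reference. The invariant tested is the
  operator form.
* **The interference basis removes whatever dominates variance.** The
  method presumes the interference manifold outranks the class contrast in
  variance. If class differences are large enough to enter the selected
  PCA subspace, EMSC neutralizes them too. This is intrinsic to
  variance-based selection and is the reason the synthetic generator is
  parameterized in the subtle-contrast regime (below).

## Random-forest wavenumber ranking

100 trees, Gini impurity, fixed seed 42. Stratified 10-fold
cross-validation reports accuracy (mean ± sd over folds); the final forest
is refit on all data. "Stratified sampling during tree construction" is
implemented as a class-balanced bootstrap per tree
(`class_weight='balanced_subsample'`); setting `class_balancing='none'`
leaves only the CV folds stratified. Importances are mean impurity
decrease, normalized to sum to 1 (an all-zero degenerate forest falls back
to uniform), mapped to wavenumbers, sorted descending with ties broken by
ascending wavenumber; the top 15 feed the embedding stage. CV accuracy is
reported but never gates selection. Rankings are computed independently per
region and per patient stratum (all / NW / OW).

## UMAP embedding, stability, silhouette

UMAP with library defaults (n_neighbors 15, min_dist 0.1), spectral
initialization, 2-D output, one run per seed 42–51. "Most stable
projection" is operationalized as the embedding with the minimal mean
Procrustes disparity (optimal translation/rotation/reflection/scaling) to
its sibling-seed embeddings, ties to the lowest seed; scaling is allowed
because UMAP coordinates have no absolute scale. The selection is invariant
to the order embeddings are supplied.

Silhouette is computed on the retained 2-D coordinates with NA/CAA as the
two clusters (per-sample clustering is exposed as an option); it is
undefined — and raises — for a single label or singleton cluster. The
implementation is the standard library routine; tests verify it against an
independent brute-force double loop to 1e-12.

`compare_before_after` runs embed → stabilize → silhouette on all channels
and on the top-k channels and reports both scores and the delta.

## Synthetic cohort generator

Emulates the statistical structure of adipocyte Raman maps:

    intensity = scatter × [ Σ lipid bands × multipliers
                            + carotenoid_amp × carotenoid profile
                            + baseline polynomial ] + noise

* **Band library** (Lorentzian by default; Gaussian available): carotenoid
  1004/1155/1520; fingerprint lipid 1267, 1301, 1440, 1655, 1745;
  high-wavenumber 2840, 2880, 2930, 3010 cm⁻¹. FWHM 10–20 cm⁻¹ (typical
  condensed phase; widths are not documented upstream).
* **Carotenoid interference**: per-spectrum lognormal amplitude
  (σ = 0.7 — resonance enhancement varies by factors of ~2–3 between
  cells), a shared position shift (sd 1.5 cm⁻¹) and width factor
  (lognormal σ = 0.08) for the temperature dependence, and per-band
  relative-amplitude jitter (lognormal σ = 0.2) for varying carotenoid
  species composition. Together these make the interference a
  multi-dimensional manifold occupying the leading PCA directions — the
  regime the EMSC stage presumes. An early single-direction variant
  (amplitude only) put the class contrast among the top variance directions
  and EMSC removed it; the present parameterization was chosen to match the
  target regime (dominant interference, subtle class contrast) and then
  frozen.
* **Class effects**: multiplicative and subtle. CAA/NW raises 1655 (×1.12),
  3010 (×1.15), 1267 (×1.08) and lowers 1745 (×0.92), 2880 (×0.95);
  obesity damps the unsaturation shift (CAA/OW ×1.08/×1.10; NA/OW ×0.96 on
  1655/3010). One lognormal multiplier draw per patient and band
  (σ = 0.04) plus per-spectrum jitter (σ = 0.03) reproduce per-sample
  clustering tendencies in kind.
* **Nuisances**: random order-3 polynomial baseline (scale 0.5), global
  lognormal scatter (σ = 0.15), additive Gaussian noise (sd 0.01 against
  band amplitudes of order 0.2–1.6).
* **Defaults emulate the acquisition design**: 5 NW + 5 OW patients, NA and
  CAA tissue each, one 31 × 31 map (961 spectra) per sample, both analysis
  windows at 1 cm⁻¹ — 19,220 spectra. Every random draw is recorded in a
  ground-truth table so planted values are usable as oracles.

What the generator does *not* emulate: cosmic-ray spikes (removed by
acquisition-time accumulation), detector/wavelength calibration error,
confocal optics and self-absorption, spatial autocorrelation within a map,
and real biochemical heterogeneity beyond band-amplitude variation. Tests
passing on synthetic cohorts therefore demonstrate the pipeline's
correctness and its behaviour in the intended interference regime, not
clinical performance on patient tissue.

## Problem sizes and numerical choices

Tests and the acceptance script use reduced cohorts — 2 patients per weight
class, 5 × 5 µm maps (25 spectra each, 200 total), 3 cm⁻¹ axis step — which
preserve the statistical structure at a few percent of the default cost;
the acceptance embeddings use a single UMAP seed where only the
before/after direction is measured, and the full 42–51 stability selection
where the embedding itself is the deliverable. Least squares uses
`numpy.linalg.lstsq` (SVD); polynomial bases are always built on axes
mapped to [−1, 1]; silhouette needs every cluster ≥ 2 members; Procrustes
stability needs ≥ 2 candidate embeddings (a single-seed run reports
disparity 0). The pipeline's global seed drives cohort generation, while
the supervised and embedding stages keep their conventional fixed seeds
(forest 42, UMAP 42–51), so stage outputs are bit-reproducible given the
config snapshot in the run manifest.

## Known limitations

* The real patient cohort is unavailable, so published silhouette values on
  that data are out of reach by construction; the package asserts the
  direction and mechanism of the feature-selection gain instead.
* Variance-threshold interference selection cannot distinguish "patient
  variability in a band" from "class difference in that band" when both
  load on the same spectral direction; in data where the class contrast is
  not subtle relative to the interference, EMSC will attenuate it.
* The iterative min-clipping baseline assumes peaks point up from a smooth
  background; derivative-like preprocessed spectra would need a different
  baseline model.
* UMAP stability selection compares seeds of one configuration; it does not
  explore n_neighbors/min_dist sensitivity.
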