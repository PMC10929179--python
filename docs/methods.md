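# Methods

## Scope and design

The package follows the quantification chain of a multi-assay cell-line
comparison study: raw measurements (images, tracks, absorbance reads,
caliper and lesion tables) are reduced to per-line summary metrics, and a
correlation/PLS layer relates the in vitro block to the in vivo block.
The statistical unit of the association layer is the **cell line** (per-line
means of per-cell measurements), which is the honest unit when a handful of
lines is profiled: per-cell replication inflates n but not the number of
independent biological units.

## Shape descriptors

Segmentation: the cytoplasm (F-actin) channel is thresholded (Otsu by
default; Yen/Li/mean or a fixed intensity are available), nuclei are
thresholded and labelled as markers, and a watershed on the distance
transform grows each marker through the cytoplasm mask. Mask pixels
unreachable from any nucleus stay background, so each object contains
exactly one nucleus seed. Objects are 8-connected; any object with a
border pixel is discarded before measurement (border cells are truncated
by the field of view and would bias every size/shape metric).

Descriptors are computed in pixel space; only area and perimeter are
converted with the pixel size (µm/px), the other four are dimensionless.

- **Perimeter.** A raw count of boundary pixel edges overestimates
  diagonal boundaries by up to √2 and drives the form factor of a
  digitized circle to ≈ 0.9 (or ≈ 0.8 for cruder estimators). We instead
  extract the 0.5-level marching-squares contour of a Gaussian-smoothed
  copy of the binary mask (σ = 2 px, configurable) and sum its segment
  lengths. On disks, ellipses and squares with linear size ≥ 100 px this
  keeps the perimeter within ≈ 1% of the analytic value, in both
  axis-aligned and rotated orientations — the property the downstream
  form-factor anchor (circle → 1) requires. The smoothing scale is fixed,
  so objects much smaller than ~20 px are measured less accurately; the
  minimum-area filter should be used to exclude them.
- **Compactness.** Defined as 2π·MSD/A with MSD the mean squared pixel
  distance from the intensity centroid. The 2π normalisation makes a
  filled disk score exactly 1 (MSD of a disk is r²/2, A = πr²), matching
  the circle anchor; an un-normalised MSD/A would score 1/2π. An ellipse
  with semi-axes a, b scores (a²+b²)/(2ab).
- **Eccentricity** comes from the second central moments
  (inter-focal-distance over major-axis of the moment-matched ellipse);
  degenerate one-pixel-wide objects are clipped just below 1.
- **Solidity** is area over convex-hull area (1 for convex shapes).

Spheroid invasion is the mean radial distance of peripheral cells from
the spheroid centre; the fold change divides each ECM-treated spheroid's
mean distance by the average of the no-ECM control spheroids' means. An
empty peripheral set yields NaN (undefined), not an error, so batch
summaries can carry non-invading spheroids.

## Motility metrics

Speed is total path length over elapsed time, i.e. uses the distance
actually travelled, not the net displacement. Persistence is net
displacement over total path length. Tracks whose path length falls below
ε = 1 µm (configurable) are flagged stationary and given persistence 0 —
the ratio is numerically meaningless at that scale. Missed frames are
handled implicitly: steps are taken between recorded positions whatever
their time gap, with no interpolation. Per-line summaries are means ± SEM
(n−1 convention; SEM is NaN for a single cell) over per-cell values —
persistence is averaged per cell, not computed as a ratio of means.

## In vivo metrics

Caliper volume uses the modified-ellipsoid convention V = L·W²/2
(axes swapped with a warning if width exceeds length). Latency is the
first week above a 50 mm³ palpability proxy (configurable). The
metastatic index (lesions per mm³) is undefined for mice without a
palpable tumour; such mice contribute 0 to growth curves but are excluded
from index means, since the index is a ratio with their volume in the
denominator. Lesion "size" is treated as an area; the unit is a label
only and never enters a computation.

## Association layer

- Pairwise OLS per feature×outcome: slope, intercept, R², F-test p with
  (1, n−2) df. R² equals the squared Pearson r by construction and the
  tests enforce agreement to 1e−10. Constant features are flagged
  degenerate (NaN) rather than fitted.
- Spearman ρ is Pearson on average ranks. For n ≤ 8 the two-sided p
  enumerates all n! rank permutations exactly (720 permutations at n = 6,
  where a t-approximation is poor); larger n uses the t-approximation
  with n−2 df.
- ANOVA + Tukey: Tukey–Kramer studentized-range p-values
  (scipy's studentized-range distribution provides the quantile
  integration); groups with < 2 observations are excluded with a warning.
  Letter annotations follow the multi-group figure convention: each group
  lists the letters of the *other* groups it differs from at α = 0.05, so
  the relation is symmetric by construction. A vectorised
  familywise-error simulation (shared statistic, single critical
  quantile) confirms 5% calibration under a six-group null.
- PCA standardizes columns (mixed units) and reports all components, so
  explained-variance fractions sum to 1; loadings are orthonormal.
- PLS2 is a NIPALS implementation with X-deflation: per component,
  iterate w ∝ X'u, t = Xw, q = Y't/t't, u = Yq/q'q to convergence, then
  deflate both blocks by the t-rank-one terms. X-scores are mutually
  orthogonal; the first weight equals the dominant left singular vector
  of X'Y (checked to 1e−8 against an SVD oracle). Both blocks are
  z-scored by default — Y mixes mm³ and lesion counts, so unscaled
  covariance would be dominated by volume. The inner-loop tolerance is
  deliberately strict (relative squared score change < 1e−26, i.e. at
  numerical convergence) because the small matrices make iterations
  cheap. Default components k = 2, matching two-axis score/loading
  plots. No multiple-testing correction is applied across the grid by
  default (each cell is reported with its raw p, as such grids are
  conventionally displayed); a Benjamini–Hochberg option exists.

## Synthetic-data generators (what they emulate, and what not)

- **Silhouettes** are star-shaped polar regions (disk, ellipse,
  rectangle, lobed ellipse mimicking protrusive cells) rasterized by
  pixel-centre containment with no anti-aliasing, so the binary mask has
  a well-defined analytic truth (closed forms for disk/ellipse/rectangle;
  dense polar integration cross-checked against a polygon oracle for the
  lobed shape). The nucleus channel holds a smaller disk inside each
  silhouette, guaranteeing one segmentation seed per cell. Not emulated:
  noise, PSF blur, illumination gradients, intensity texture — passing
  tests validate the measurement chain, not robustness to imaging
  artefacts.
- **Tracks** are constant-speed persistent random walks with wrapped
  Cauchy turning angles; the concentration equals the persistence
  parameter p (p = 0 uniform turning, p = 1 straight lines), the
  simplest one-parameter bridge between the regimes. Default cadence
  20 min over 48 steps (~16 h), a typical overnight live-imaging
  session. In 3D the same turning angle tilts the direction about a
  random perpendicular axis. Not emulated: speed fluctuations, drift,
  confinement, cell–cell collisions.
- **Spheroids** place peripheral cells at planted radial distances,
  uniform in angle, so the downstream mean invasion distance is known
  exactly.
- **Cohorts** draw a latent per-line "metastatic potential"
  u ~ N(0, 1); every feature/outcome column is effect·u + N(0, sd²).
  The default effects encode the qualitative structure such panels
  report — shape irregularity (form factor, solidity: ±0.95) loading
  strongest, size negatively (−0.6), elongation negatively (−0.5), and
  all motility/invasion metrics weakly (|0.3|), with outcome loadings
  0.9–0.95 and noise sd 0.4. Under this model the population
  |correlation| is e_f·e_o/√((e_f²+sd²)(e_o²+sd²)) ≈ 0.85 for shape and
  ≈ 0.55 for motility against liver count, a separation chosen (by this
  power calculation, a priori) so that a faithful analysis recovers the
  planted ordering at n_lines = 50 with high probability while noise
  still visibly scrambles a six-line panel. A single latent factor is
  the simplest structure that reproduces clustered loadings in the PLS
  plane; it cannot represent multi-factor phenotypes (e.g. a motility
  axis independent of shape).

## Problem sizes in tests and scripts

Rasterization checks use 512² canvases with shapes of linear size
100–300 px, where descriptor truth is accurate to ≲ 1%. Monte-Carlo
checks use 10,000 tracks per persistence level, 2,000 null simulations
for the Tukey familywise error, 60 null cohorts of 500 lines for the
Fisher-z spread, and 200 replicate cohorts of 50 lines for the planted
recovery experiment — sizes at which the Monte-Carlo error is several
times smaller than the tolerance being asserted.

## Known limitations

- The perimeter estimator's fixed smoothing scale biases very small
  objects (≲ 20 px); descriptors are accurate only well above that scale.
- The 3D turning model is isotropic about the previous direction and not
  a uniform spherical step distribution at p = 0.
- Segmentation assumes nuclei are reliable single seeds; fragmenting or
  merged nuclei produce over/under-segmentation that only the IoU tests
  on touching-cell fixtures probe.
- The association layer performs no cross-validation of the PLS model;
  with a handful of lines the scores/loadings are descriptive, not
  predictive.
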