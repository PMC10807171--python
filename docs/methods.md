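# Methods

This note documents the models, estimators and numerical choices behind
each analysis stage, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the procedure was genuinely
open. All empirical figures quoted here are the ones the test suite and
`scripts/acceptance.py` themselves compute.

## Coordinate and unit conventions

Rasters are indexed `(row, col) = (y, x)`; stacks `(z, y, x)`. Lateral
calibration is µm/px, axial spacing µm (0.5 µm default). Angles are
degrees from the image x-axis in array coordinates, reduced to [0, 180)
wherever only orientation matters; acute angles to an axis live in
[0, 90]. Times are hours (migration) or seconds (volume traces);
areas µm²; speeds µm/h.

## Cell regions

*Shrink-by-area.* The "X % smaller outline (by area)" is computed on the
Euclidean distance transform of the cell mask: the pixels are ranked by
their distance to the outline and the innermost `round(f·A)` are kept.
Level sets of the EDT are exactly the erosions of the outline by disks,
so this is erosion-to-target-area with sub-pixel adjustment — the
achieved area ratio is exact to one pixel (max deviation ~1e-4 over the
50 acceptance shapes), and it is robust on concave outlines where polygon
offsetting self-intersects. The subplasmalemmal band is the complement of
the shrunk outline inside the cell, so band and inner region partition
the cell exactly.

*Perinuclear region.* Grown from the nucleus by adding candidate pixels
in order of distance until the region reaches twice the nuclear area,
clipped to the cell; if the cell cannot hold 2×, the maximal region is
returned with a `clipped` flag. The shape of the 2× region is not
prescribed anywhere; distance-ordered growth (equivalent to dilation with
a sub-pixel final step) is the natural choice and reproduces the
√2-radius disk for a centered circular nucleus.

*Occupancy.* Percentage of region pixels above threshold in the z-merged
image. Merging is maximum-intensity projection by default (a `sum` switch
exists); the threshold defaults to Otsu's method on the in-region
intensity histogram and is overridable — the assays define that a
threshold exists, not how it is chosen.

*Long axis.* Principal axis of the pixel-coordinate covariance. When the
two eigenvalues agree within 1 % the orientation is meaningless; the
angle is still returned, flagged degenerate.

## Puncta detection and sizing

Objects are connected components (26-connectivity default, 6/18
available) of supra-threshold voxels, filtered by a minimum voxel count
(default 4) and given intensity-weighted centroids. Auto-thresholds:
`otsu` (default) on the in-mask histogram, or `mad` — median + 5 robust
SDs (1.4826·MAD) of the background — which is the right tool for sparse
spots, where the foreground is a negligible histogram fraction and Otsu
splits the background mode instead.

For low-SNR stacks an optional matched filter (Gaussian pre-smoothing at
roughly the spot scale) is applied before thresholding; centroids and
FWHM always use raw intensities. Smoothing correlates the noise, so a
supra-threshold noise excursion carries the kernel's footprint rather
than single voxels; the minimum-size filter therefore scales to
`2π·σ_f²` voxels under smoothing (a genuine spot's smoothed half-max
footprint is several times that; observed noise excursions reach only
4–10 voxels). With this, spot counts at SNR 5 and 8σ separation are
recovered exactly in 100/100 seeded stacks.

*FWHM.* The equatorial plane maximizes the object's in-plane integrated
intensity. Profiles are taken through the intensity-weighted centroid as
3-px-wide averaged lines — width-neutral for separable spots, noise
reduced by √3. Local background is the median in a 2-px shell around the
padded analysis window (a shell hugging the half-max bounding box would
sit on the spot's own flanks and bias the width low). The peak is
estimated by quadratic interpolation through the three samples at the
centroid (the raw maximum of a noisy profile is biased high, which
narrows the apparent width), and the half-maximum crossings are located
by linear interpolation walking outward, requiring the crossing to hold
for two consecutive samples to suppress first-passage noise bias on
shallow flanks. Net bias at SNR 10: under 1 % at σ = 1.5 px, about −3 %
at σ = 3 px. The reported diameter is the mean of the horizontal and
vertical FWHM; whether a single-direction width was ever intended is not
determinable, so the averaged value is the documented convention.

*Density.* `100·N / cell area (µm²)` — exact arithmetic, no estimation.

## Colocalization

Object-based: the percentage of reference-channel objects sharing at
least one voxel with any object of the other channel (100 % for identical
label maps by construction). Pixel-based: Pearson's r over in-mask voxels
and Manders' M1 = ΣA over voxels with B above threshold / ΣA (M2
symmetric), thresholds Otsu per channel unless given. A zero-variance
channel flags Pearson undefined. Which coefficient a published
"percentage of colocalization" refers to varies between studies; both
routes are provided and the object-based one is treated as the primary
per-cell readout.

## Cytoskeletal architecture

The filament mask (Otsu within the cell on the z-merged image, threshold
overridable) is skeletonized; the skeleton is split at branch points
(pixels with more than two skeleton neighbors), each branch is fitted by
a total-least-squares line (PCA of its pixel coordinates), and branches
shorter than 5 px are discarded as spurs.

- `avgTheta`: length-weighted mean of the acute angle between branch
  orientation and the cell long axis; 45° under uniform orientations
  (the mean of an acute angle uniform on [0°, 90°]).
- Parallelness: the circular mean resultant length on doubled angles,
  R = |Σ wᵢ e^{i2θᵢ}|/Σ wᵢ — 1 iff all orientations coincide mod 180°, 0
  for balanced orthogonal families or uniform spread. The plugin-specific
  index it stands in for is defined only as "an index showing the
  variations in the angle distribution"; the doubled-angle resultant
  length is the standard circular-statistics quantity with exactly that
  meaning and is documented here as an analogue, not a reimplementation.
- Bundling: Fisher's moment coefficient g₁ = m₃/m₂^1.5 of in-region
  intensities (population moments); brighter, heavier-tailed histograms
  indicate filaments stacked into bundles. Computed over the whole cell
  by default, per-region on request.

Length weighting is the default for the orientation statistics
(unweighted mode available).

## Migration

Gap area is pixel count × pixel size². The closure slope is OLS of area
on time over the first four samples (0–12 h at 4-h sampling) —
configurable; then v = |slope|/(2l) and t½ = A(0)/(2|slope|), flagged
undefined for non-closing gaps. Gap segmentation from raw DIC images is
deliberately out of the computational core (outlining is manual in
practice); the pipeline consumes binary gap masks or area series.
Track mobility sums Euclidean nucleus displacements; an optional filter
keeps cells within a stated distance band of the leading edge. Replicate
speeds are aggregated by median.

## Volume dynamics

Model: F/F₀(t) = F_max/(1 + e^{−k(t−t₀)}). The exponent is written with
−k so that k > 0 describes the rising swelling phase; with the opposite
sign printed elsewhere the two parameterizations are equivalent under
k ↔ −k. "Swelling rate" is reported as the logistic k; the realized
maximal slope F_max·k/4 (attained at t₀) is emitted alongside, since the
two are different quantities and either may be meant by a prose
description.

Pipeline: (1) Savitzky–Golay smoothing (window 11 samples, polyorder 3 —
conventional defaults, config-exposed); (2) photobleaching correction —
an OLS line is fitted to the pre-stimulus baseline and its *slope*
component subtracted (subtracting the full line would zero the baseline
and destroy the F/F₀ normalization); (3) normalization to the corrected
baseline mean, × 100 %; (4) logistic fit of the swelling phase from
stimulus onset to the smoothed-trace peak, excluding the RVD segment;
(5) RVD half-time: first time after the peak at which the trace falls to
100 + (F_peak − 100)/2, linearly interpolated, censored-flagged if never
reached.

Two estimator details matter. The bleach slope and F₀ are estimated on
the **raw** baseline, and the smoothed copy serves only for rise/peak
detection and the RVD readout: smoothing across a sharp stimulus
response bleeds into the last baseline samples and corrupts a
baseline fit made on smoothed data. And the least squares runs on the
**unsmoothed** normalized samples — fitting pre-smoothed data biases the
parameters; smoothing's job here is event detection. Savitzky–Golay is
linear and exact on straight lines, so this ordering is equivalent to
smoothing first whenever the baseline is clean.

The fit uses bounded trust-region least squares (tolerances 1e-8), three
deterministic jittered initializations with best-RMSE selection, and
initial values F_max ← observed max, t₀ ← observed half-rise time,
k ← 4·(max observed slope)/F_max. Traces whose excursion is below 2 % of
F₀ are flagged no-swelling and not fitted. t_s,max is measured from
stimulus onset (a `rise` switch measures from the detected rise
instead). All outputs are invariant under scaling the raw trace by any
positive constant.

## Statistics

Mann–Whitney U reports U = min(U_a, U_b). The p-value is exact (full
null distribution of U) for tie-free samples with n_a + n_b ≤ 12,
two-sided by doubling the smaller tail, capped at 1; otherwise the
normal approximation with midrank tie correction and continuity
correction. The exact mode agrees with brute-force enumeration over all
rank arrangements for every tie-free case with n_a + n_b ≤ 10 (2026
cases, checked exhaustively), and the realized type-I error at α = 0.05
over 2000 null simulations (n = 10 per group) is ~0.035–0.04 — the exact
test is conservative because the discrete null distribution rarely admits
a rejection region of mass exactly 0.05. Group summaries are median ±
bootstrap SE of the median (1000 seeded resamples) — "SE of a median" has
no standard closed form, so the bootstrap is the documented convention.
Expression rows are z-scored with sample SD (n−1), zero-variance rows
flagged and excluded; gene-pair regression is plain OLS with R² and the
two-sided slope p-value (on standardized pairs the slope equals
Pearson's r).

## Synthetic data: what it emulates, and what it does not

All generators draw from one explicitly passed seeded generator;
identical seeds give bit-identical outputs.

- *Cell masks*: star-convex outlines (circles, ellipses, harmonically
  modulated "blobs" that can be concave) with a concentric scaled-down
  nucleus. Real cell shapes are rougher and nuclei off-center.
- *Puncta*: isotropic 2D Gaussians with a Gaussian axial profile,
  sub-pixel positions, pairwise minimum separation by rejection sampling
  (bounded retries, explicit failure), additive Gaussian noise with a
  Poisson option. No confocal PSF, no spectral bleed-through, no
  background structure — so passing recovery tests demonstrates
  correctness of the estimators, not robustness to optics.
- *Filaments*: straight segments, orientations von Mises on doubled
  angles about a mean (κ = 0 uniform), per-filament gamma-distributed
  intensities whose Fisher skewness is the `intensity_skew` parameter,
  additive accumulation where strokes overlap. Real filaments curve and
  cross densely.
- *Gap series*: both fronts advance at v_true, area
  max(0, (w − 2·v_true·t))·l plus Gaussian noise, sampled at 4-h
  intervals for 28 h. Proliferation and front roughening are not modeled.
- *Calcein traces*: 30 s baseline + 90 s post-stimulus at 1 frame/s;
  after onset the relative response follows the pure logistic over its
  full range (F_max_pct = 100 means no response), then decays
  exponentially once the logistic reaches 99 % of its plateau, giving a
  closed-form true swelling duration and RVD half-time; linear bleach
  and Gaussian noise (% of F₀) are added on the intensity scale. The
  post-onset curve is the fitting model itself by design — the
  generator's purpose is ground-truth closure, not emulating perfusion
  transients.
- *Tracks*: uniform-direction random walk with constant or user-drawn
  step lengths; truth is the sum of drawn steps.
- *Expression*: one designated gene pair with y = slope·x + noise on the
  z-score scale, all other rows independent standard normal.

Noise defaults are conventions, not reproductions of any instrument:
imaging noise statistics for these assays are simply not published.

## Problem sizes and tolerances used in verification

Acceptance-grade checks run at: 4 noiseless gap speeds (exact to 1e-9
relative); a 27-condition × 20-seed swelling grid (median relative error
~0.4 % for F_max, ~0.8 % for k, both monotone in noise); 100 puncta
stacks at SNR 5 (100 % exact counts), 50-seed FWHM sweeps at SNR 10
(|bias| < 5 %); 50 random shapes for region contracts (area ratios to
±0.5 %, perinuclear 2.00 ± 0.02); 10⁴ segments / 10⁵ pixels for the
orientation and skewness calibrations; exhaustive Mann–Whitney
enumeration to n_a + n_b = 10 and 2000 null simulations. These sizes were
chosen so each check is statistically decisive while the whole suite
remains fast on a single CPU.

## Known limitations

- The detector merges spots closer than ~1σ (documented, tested); no
  declumping or deconvolution is attempted.
- FWHM is meaningful only for spots a few pixels across; below σ ≈ 1 px
  the discrete profile undersamples the peak.
- The parallelness index is a circular-statistics analogue of a
  plugin-defined quantity, not a bit-compatible reimplementation.
- Bleach correction assumes linear bleaching over the record and a
  stationary baseline; strongly nonlinear bleaching will leak into F_max.
- The logistic swelling fit assumes a single monotone swelling phase; a
  double-swelling response will be fitted to its dominant rise.
- Gap segmentation from raw DIC movies and nucleus tracking from movies
  are out of scope; masks, area series and tracks are inputs.
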