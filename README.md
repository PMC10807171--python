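# gliaquant

Quantification toolkit for the image-based assays used in astrocyte and
glioblastoma cell biology: counting and sizing plasmalemmal protein
aggregates (e.g. AQP4 clusters and surface plectin microdomains) in
confocal z-stacks, scoring where the cytoskeleton sits inside a cell and
how it is arranged, object- and pixel-based colocalization, wound-healing
migration kinetics, and cell-volume dynamics from calcein fluorescence.
Every stage ships with a seeded synthetic-data generator carrying known
ground truth, so the whole pipeline is verifiable by parameter recovery —
no external data needed.

Intended users: cell biologists and image analysts who would otherwise
stitch these measurements together from Fiji plugins and one-off scripts,
and who want the same measurements as reproducible, tested Python calls.

## What it computes

**Puncta.** 3D objects are connected components of supra-threshold voxels
(26-connectivity, minimum size filter; Otsu or robust-background
thresholds, optional matched-filter smoothing for low SNR). Abundance is
normalized to 100 µm² of cell area: `density = 100·N/A`. Each object's
diameter is the mean of the horizontal and vertical full widths at half
maximum (FWHM) of intensity profiles through its equatorial plane (for a
Gaussian spot, FWHM = 2√(2 ln 2)·σ ≈ 2.3548 σ).

**Regions and occupancy.** The subplasmalemmal band is the area between
the cell outline and an outline shrunk to 80% (filaments) or 90%
(intracellular plectin) of the cell *area*; the perinuclear region covers
twice the nuclear area including the nucleus. Occupancy is the percentage
of supra-threshold pixels in a region of the z-merged image.

**Cytoskeletal architecture.** Skeletonized filament branches give
avgTheta (length-weighted mean acute angle to the cell long axis), a
parallelness index R = |Σ wᵢ e^{i2θᵢ}|/Σ wᵢ on doubled orientations, and
bundling as the Fisher skewness g₁ of the in-region intensity histogram.

**Migration.** From the linear phase of gap closure (OLS over the first
four time points by default):

    v_migration = |slope| / (2 l),    t_1/2 = A(0) / (2 |slope|)

with slope = dA/dt and l the gap length. Single-cell mobility is the sum
of nucleus-center displacements and the average speed.

**Volume dynamics.** Calcein traces (30 s baseline + 90 s post-stimulus
at 1 frame/s by default) are Savitzky–Golay smoothed, bleach-corrected
(baseline-fitted linear trend removed), normalized to F/F₀ × 100 %, and
the swelling phase is fitted with the logistic

    F/F₀(t) = F_max / (1 + e^{−k (t − t₀)})

giving the amplitude F_max, swelling rate k (maximal slope F_max·k/4 at
the midpoint t₀), swelling duration t_s,max, and the regulatory volume
decrease half-time t_RVD,50% (time after the peak to recover half-way to
baseline).

**Statistics.** Mann–Whitney U (exact for small tie-free samples, normal
approximation with tie/continuity correction otherwise), median ±
bootstrap SE summaries, per-gene z-scoring and OLS regression between
expression rows.

## Worked example

Simulate a noisy calcein trace (true F_max = 140 %, k = 0.3 /s, t₀ = 45 s,
RVD rate 0.03 /s, 1 % noise) and analyze it:

```bash
$ gliaquant simulate trace --out tr.csv --seed 3
$ gliaquant volume --trace tr.csv
     f_max       k        t0  t_s_max  t_rvd_50  max_slope     rmse  peak_time  rise_time  converged  no_swelling  rvd_censored
137.498829 0.31396 44.974248     30.0 22.729868  10.792273 0.996619       60.0       49.0       True        False         False
```

The fit recovers the generating parameters within a few percent: the cell
swelled to 137 % of its baseline volume-proxy fluorescence (truth 140 %),
with rate constant 0.314 /s (truth 0.3), midpoint 45.0 s, a 30-s swelling
phase, and a 22.7-s RVD half-time (truth ln 2/0.03 ≈ 23.1 s).

The same round trip for a wound-healing assay (gap 500 × 1000 µm closing
at a true 10 µm/h per front):

```bash
$ gliaquant simulate gap --out gap.csv --v-true 10
$ gliaquant migrate --series gap.csv --gap-length 1000
   slope  intercept  r_squared  v_migration  t_half  fit_points  closing
-20000.0   500000.0        1.0         10.0    12.5           4     True
```

The fitted area slope of −20 000 µm²/h gives v = |−20000|/(2·1000) =
10 µm/h exactly, and t½ = 500000/(2·20000) = 12.5 h.

The same operations are available as library calls (`gliaquant.analyze_trace`,
`gliaquant.analyze_gap_series`, `gliaquant.detect_objects`, ...); see the
docstrings and `docs/methods.md`.

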