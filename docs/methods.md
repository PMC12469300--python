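# Methods

This note documents the models, estimators, numerical choices and
limitations behind `cellmorph`, in the order a dataset flows through the
package.

## Coordinate and angle conventions

Images are row-major, 0-based, with pixel centers at integer coordinates;
a pixel is in or out of a mask (no sub-pixel membership). The stretch axis
is the image x-axis (columns). Orientation angles φ are measured
counterclockwise from +x with the mathematical y-axis pointing up (i.e.
against the row direction) and folded into (−90°, 90°]. Since nuclei are
axisymmetric, φ and φ + 180° are the same orientation; the orientation
parameter cos(2φ) is invariant to that ambiguity, which is why population
statistics are computed on cos(2φ) rather than φ. Pixel sizes always come
from configuration (defaults 0.025 µm/px for confocal images, 0.010 µm =
10 nm/px for AFM height maps), never from TIFF tags, whose conventions
vary across instruments.

## Nuclear morphometry

Each segmented nucleus is summarized by its **moment-equivalent ellipse**:
the ellipse with the same area, centroid and second central moments as the
pixel region (computed via `skimage.measure.regionprops`). This is what
ImageJ's *Fit Ellipse* actually computes, and it is the deliberate choice
here even though the quantity is sometimes loosely called a "minimum
enclosing ellipse" in the literature — the two differ, and the moment
ellipse reproduces the tool practitioners run. Area is the raw pixel count
times pixel_size² (not πab of the fitted ellipse); for rendered test
ellipses the two agree within rasterization error (<3% down to ~15 px
semi-minor axes).

Orientation classes use the standard ranges: cos(2φ) ≤ −0.5 perpendicular,
≥ 0.5 parallel, otherwise oblique. Because the major axis of a
near-circular region is numerically meaningless, regions with eccentricity
below 0.2 (configurable) are classed `undefined`, counted in the summary's
`fraction_undefined`, and excluded from mean cos(2φ). Both oblique and
undefined fractions are always reported, so either inclusion convention
can be reconstructed downstream. Regions under 25 px (configurable) are
flagged invalid as segmentation debris and excluded from summaries.

## Box-counting fractal dimension

The edge pipeline is: optional percentile contrast enhancement (linear
rescale clipping at the p_low/p_high intensity percentiles) → threshold
(Otsu by default; fixed threshold for height maps with a known plateau) →
keep the largest 8-connected component → fill holes → edge = foreground
minus its 8-connected erosion. The result is a one-pixel-wide perimeter
raster with no isolated pixels.

N(ε) is the number of cells of an ε×ε grid, anchored at the image origin,
containing at least one edge pixel, for dyadic ε = 2, 4, …, ⌊min(H,W)/4⌋.
FD is the least-squares slope of log N versus log(1/ε). Two choices are
deliberate and exposed rather than hidden:

* **Fit range.** ε = 2 is tallied but excluded from the default
  regression (`fit_min = 4`): at the pixel scale the one-pixel-wide mask
  saturates toward counting its own pixels and biases the slope. The fit
  range is always reported with the estimate, and at least 4 scales are
  required (`insufficient scale range` error otherwise).
* **Grid offsets.** A single origin-anchored grid keeps counts exactly
  reproducible (they match a brute-force double loop bit-for-bit, which is
  a test). Four-offset averaging over half-box shifts is available behind
  a flag; grid-placement sensitivity is surfaced by
  `translation_diagnostic` (FD spread under integer mask translations,
  typically ≲0.03 for well-resolved 1024-px masks) instead of being
  silently averaged away.

Validation anchors: a 512-px straight line spanning the grid measures
exactly 1.0; a 4-iteration triadic Koch curve at 729-px base measures
within ±0.05 of log4/log3 ≈ 1.2619 with the default fit range.

## Peripheral roughness

The peripheral band is the set of mask pixels within `band_width`
(Euclidean distance, default 10 px ≈ 100 nm at 10 nm/px — the scale of the
boundary protrusions the band is meant to capture) of the boundary.
Peripheral RMS is computed about the band's median height (median-plane
removal, robust to a tilted or offset plateau); the global RMS about the
full-mask median; max height over the mask. Whether published "peripheral
roughness" values were computed on raw or plane-flattened data is
generally unstated; median removal is this package's declared convention.

## CTCF

CTCF = (nuclear mean intensity × nuclear area) − (background mean
intensity × nuclear area), computed exactly as written — no smoothing, no
outlier rejection. Consequences (all tested): a uniform image gives 0,
adding a constant to the whole image cancels to machine precision, scaling
the image scales CTCF linearly, and CTCF is additive over any partition of
the nucleus sharing one background. Background is the mean over an annulus
gap < d ≤ gap + width outside the cell (defaults gap 2 px, width 5 px),
excluding pixels of neighboring cells; a per-image background is available
where a per-cell ring is clipped. Areas are in pixels unless a pixel size
is supplied, in which case both terms convert consistently.

## Group statistics

`compare_groups` is the unpaired two-sided Student's t-test with pooled
variance (df = n₁ + n₂ − 2), matching the convention of reporting
"mean difference ± SEM"; Welch is available behind a flag. Star thresholds
are strict inequalities at 0.05 / 0.01 / 0.001 / 0.0001. Zero pooled
variance with unequal means is reported as p = 0 with a `degenerate` flag
rather than an exception. No multiple-testing correction is applied by
default; Benjamini–Hochberg is provided. Detachment % is
100·n_remaining/n_initial. Wound closure % is 100·(A₀ − Aₜ)/A₀ — the
standard definition, adopted explicitly because the quantity is often
named without a formula; a widening wound yields a negative value with a
warning instead of an error.

## Synthetic data generator

The generator exists so every estimator can be validated closed-loop
against exact ground truth, at the conditions the shipped presets encode.

**Nucleus fields.** Areas are normal (mean/SD per preset, redrawn at the
negligible-mass lower tail); aspect ratios 1 + Gamma(k=4) scaled to the
preset mean; orientations either uniform on (−90°, 90°] or, for the
stretch condition, drawn by sampling 2φ from a von Mises density centered
at 180° with concentration κ (default 3) so cos(2φ) piles up near −1 — any
unimodal angular family reproducing the published class fractions would
do, and κ is an explicit knob because only class fractions, not the
angular law, are ever reported. Nuclei are placed by rejection sampling
with a 2-px separation guard and at most 1000 retries each (the analysis
counts isolated nuclei); exceeding the retry budget raises a
`PlacementError` naming the density limit. The field auto-sizes to ~25%
coverage. The preset SDs not printed in the source conditions
(nuclear-area SD 110 µm², N/C SD 0.05) were back-derived once from the
published standard errors of the mean differences at n≈30/group and fixed
before any validation was run.

**Fractal contours.** Radial spectral synthesis
r(θ) = R₀(1 + s(θ)) with s built from Fourier modes k = 2…512 with
amplitudes k^(−β/2), independent standard-normal coefficients, normalized
to RMS 0.12 and clipped at −0.85 so r stays positive — the contour is
star-shaped, hence closed and non-self-intersecting by construction. The
interior is filled exactly by the polar inequality ρ ≤ r(θ) (with a
largest-component/fill-holes cleanup, since sub-pixel radial oscillations
can alias into detached islands on coarse grids). The mapping from β to
measured box-counting FD has no useful closed form at finite resolution,
so it is calibrated once against the package's own estimator: 16 seeds per
β knot on 1024-px grids, pool-adjacent-violators to enforce monotonicity,
frozen as package data (`data/fd_calibration.json`) and inverted by linear
interpolation. The calibrated range covers measured FD ≈ 1.013–1.52;
targets at the smooth limit clamp to the largest β (a perfectly smooth
digital contour still measures ≈1.013, comfortably inside the ±0.05
recovery tolerance used throughout). Calibration is resolution-specific:
generating at grids far from 1024 px shifts measured FD by a few
hundredths.

**Height maps.** Plateau of the given height inside the contour, zero
outside, zero-mean Gaussian texture of stated SD confined to the
peripheral band, optional global noise — so peripheral RMS has the texture
SD as its closed-form expectation.

**Fluorescence cells.** Cell = ellipse (aspect 1.3); nucleus = concentric
co-oriented ellipse with area = drawn N/C × cell area, strictly inside by
construction. Src channel = background + cytoplasmic level in the cell +
(fold − 1) × cytoplasmic level in the nucleus + noise, so CTCF measured
with a ring has closed-form expectation fold × cytoplasmic level × nuclear
area, recorded per cell in the ground-truth table.

All randomness in a generator call comes from one `numpy` Generator
seeded by the call's integer seed; identical (preset, seed) pairs are
bit-identical, and there is no global random state.

### What the generator does not emulate

No point-spread function, shot noise, illumination gradients, 3-D
structure, touching/confluent cells, or segmentation ambiguity: nuclei are
ideal ellipses and the DNA channel is trivially segmentable. Passing the
closed-loop tests therefore demonstrates that the *estimators* are
correct and unbiased at realistic geometries and noise levels — not that
the full pipeline is robust to the segmentation failure modes of real
micrographs, which enter upstream of this package's contract (it consumes
masks and label images).

## Problem sizes

Validation uses 1024-px contour grids with 20 seeds per condition,
200-nucleus fields at 0.25 µm/px, 100-cell replicates for CTCF and N/C,
and n = 3000 angle draws for distributional checks — sizes at which the
recovery tolerances (±0.05 FD, 3·SEM elsewhere) are meaningful while a
full run stays interactive on a laptop.

## Known limitations

* The β→FD lookup is calibrated for the default measurement settings
  (origin-anchored single grid, fit from ε = 4); measuring generated
  contours with other settings can shift recovered FD by ~0.01–0.03.
* Box-counting FD on finite rasters is an estimate with grid-placement
  noise of a few hundredths; single-cell FDs should be compared only in
  groups, as the statistics layer does.
* `fit_ellipse` assumes one 8-connected component per region; touching
  nuclei must be separated upstream.
* The N/C ratio uses projected 2-D areas, as in the imaging protocol it
  models; it is not a volumetric ratio.
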