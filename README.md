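# cellmorph

Quantitative image analysis of how cells change shape under mechanical and
chemical stimulation, built for osteosarcoma / osteoblast mechanobiology
studies but generic to any single-cell microscopy of the same kind. The
package quantifies, from fluorescence images and AFM height maps:

* **Nuclear morphometry** — per-nucleus moment-equivalent ellipse fits
  (the ellipse matching a region's area, centroid and second central
  moments, as ImageJ's *Fit Ellipse* computes), nuclear area in µm², and
  the nuclear-to-cytoplasmic (N/C) area ratio.
* **Stretch re-orientation** — the orientation parameter cos(2φ), where φ
  is the angle between a nucleus's major axis and the uniaxial stretch
  axis; cos(2φ) = +1 means parallel, −1 perpendicular, and it is invariant
  to the 180° axis ambiguity. Populations are classified with the standard
  ranges (−1 ≤ cos 2φ ≤ −0.5 perpendicular, 0.5 ≤ cos 2φ ≤ 1 parallel).
* **Edge complexity** — one-pixel cell-boundary masks extracted from AFM
  scans, and their box-counting (Minkowski–Bouligand) fractal dimension:
  the slope of log N(ε) versus log(1/ε) over a dyadic ladder of box sizes,
  ≈1 for smooth outlines and rising toward 1.3–1.5 for boundaries dense
  with lamellipodia-like protrusions. Peripheral RMS roughness of height
  maps is measured in a band just inside the boundary.
* **Nuclear Src fluorescence** — corrected total cell fluorescence,
  CTCF = integrated density − background mean × area, with an automatic
  annular background ring per cell.
* **Group statistics** — mean ± SEM summaries, unpaired pooled-variance
  Student's t-tests with significance stars, orientation-distribution
  summaries, detachment and wound-closure percentages.

Because such studies rarely deposit raw images, the package ships a
**synthetic generator** (`cellmorph.syngen`) that renders nucleus fields,
fractal cell contours with a *prescribed* box-counting dimension,
pseudo-AFM height maps and two-channel fluorescence cells — each with an
exact ground-truth table — so every estimator is validated closed-loop.
Named presets are calibrated to published per-condition means (e.g.
`u2os_capsaicin`: nuclear area 749.1 µm², N/C 0.4376, edge FD 1.272).

## Worked example

```python
import numpy as np
from cellmorph import (load_preset, make_fractal_contour, make_nucleus_field,
                       extract_edge_mask, box_count, measure_labels,
                       orientation_summary, compare_groups)

# 1. edge complexity of a capsaicin-like cell contour
p = load_preset("u2os_capsaicin")          # calibrated edge FD 1.272
fc = make_fractal_contour(p, grid_size=1024, seed=1)
em = extract_edge_mask(fc.filled.astype(float), method="fixed", threshold=0.5)
res = box_count(em)
print(f"FD = {res.fd:.3f}  (R² = {res.r_squared:.4f}, fit ε {res.fit_range})")
# FD = 1.273  (R² = 0.9997, fit ε (4, 256))

# 2. nuclear areas: treated vs control, with the standard unpaired t-test
areas = {}
for name, seed in [("u2os_control", 7), ("u2os_capsaicin", 8)]:
    nf = make_nucleus_field(load_preset(name), n=200, seed=seed)
    recs = measure_labels(nf.labels, pixel_size=0.25)
    areas[name] = np.array([r.area_um2 for r in recs])
cmp = compare_groups(areas["u2os_capsaicin"], areas["u2os_control"])
print(f"mean diff = {cmp.mean_difference:.1f} ± {cmp.se_difference:.1f} µm², "
      f"t({cmp.degrees_of_freedom:.0f}) = {cmp.t_statistic:.2f}, "
      f"p = {cmp.p_two_sided:.2e} {cmp.stars}")
# mean diff = 193.9 ± 10.7 µm², t(398) = 18.09, p = 7.84e-54 ****
```

The FD line says the synthesized boundary measures within a few
thousandths of its 1.272 calibration; the comparison line reproduces the
treated-versus-control nuclear-area difference (calibrated to
749.1 − 553.7 = 195.4 µm²) within sampling error of a 200-nucleus draw.

A CLI mirrors the library: `cellmorph simulate nuclei --preset
u2os_stretch --seed 3 --out sim/`, then `cellmorph orient --labels
sim/labels.tiff --pixel-size 0.25 --out orient.csv`, then
`cellmorph orient-summary --in orient.csv --out summary.json`; also
`fd`, `roughness`, `ctcf`, `ncratio`, `compare`. Every run writes a
manifest (config hash, seed, inputs, outputs) for reproducibility.

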