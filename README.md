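# padscan

Automated detection and measurement of colorimetric output zones in
scanned images of paper-based microfluidic devices (µPADs).

µPADs route fluid through wax-patterned paper to readout zones where
colorimetric signal develops. Because device geometries are not
standardized, well-plate-style grid tools cannot measure them, and manual
region-of-interest workflows are slow and operator-dependent. `padscan`
finds the zones itself — regardless of their number, shape, or placement
— and batch-measures each one in RGB, HSV, and CIELAB.

## Method

Given an 8-bit sRGB scan (≥300 dpi recommended), the pipeline runs:

1. **Masking** — convert to HSV and keep pixels with saturation
   S ≥ s_min and value V ≥ v_min. Dark hydrophobic barrier (low V) and
   gray paper (low S) drop out, leaving the colored zones.
2. **Smoothing** — box-blur the binary mask with a k×k kernel and
   re-binarize at 0.5; optional 3×3 dilation/erosion refines edges.
3. **Contours** — extract one contour per 8-connected foreground
   component (Moore-neighbor border following); components under 5 px are
   discarded. Each contour carries its area A, centroid (x̄, ȳ), and the
   seven Hu moment invariants h₁…h₇ (translation-, rotation-, and
   scale-invariant) computed from the filled pixel region.
4. **Matching** — a reference contour (picked by a seed coordinate, or
   the largest zone) selects all contours with |A − A_ref|/A_ref within
   the size tolerance and shape distance
   d = Σᵢ |t(hᵢ) − t(hᵢ_ref)|, t(h) = sign(h)·log₁₀|h|,
   within the shape tolerance.
5. **Zone refinement** — a circle or regular polygon of fixed radius,
   displaced by (dx, dy) from the centroid and rotated by a fixed angle,
   is propagated identically to every matched contour. This excludes
   barrier edges and printed contrast rings, and reaches detection zones
   at the ends of fluid channels.
6. **Measurement & export** — per zone: mean and population SD per
   channel in the requested color spaces, 256-bin RGB histograms (CSV +
   PNG), a cropped zone image, and a tidy `results.csv`.

All settings live in a named YAML **preset**, so replicate images are
analyzed identically and reproducibly.

The package also ships a synthetic µPAD renderer (`padscan.synth`) that
draws devices with known zone positions and fills — circular/polygonal
zones, contrast rings, channel-end layouts, device rotation, Gaussian
scanner noise — so every stage can be validated against exact ground
truth.

## Worked example

```python
import padscan as ps
from padscan.synth import four_device_strip

img, truth = four_device_strip(seed=7, noise_sd=3.0)   # 4 devices x 6 zones
results, matched, mask = ps.analyze_image(img, ps.default_preset())
for res in results[:2]:
    print(res.zone_index, [round(res.stats["RGB"][c]["mean"], 2) for c in "RGB"])
```

prints

```
8 [211.95, 214.08, 152.98]
9 [192.04, 110.08, 102.08]
```

— 24 zones are matched, and each recovered mean sits within ~0.1
intensity units of the true fill (212, 214, 153) etc.; the residual is
the sampling error of averaging σ = 3 noise over ~1800 pixels. See
`examples/` for runnable scripts covering the full pipeline, color
conversions, shape matching, and channel-end zones.

The same analysis from a shell:

```bash
padscan synth --preset strip --seed 7 --noise-sd 3 --out strip.png
padscan preset init my.yaml
padscan analyze strip.png --preset my.yaml --out results/
```

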