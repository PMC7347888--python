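# Methods

This note documents the models, conventions, and numerical choices behind
`padscan`, and what the synthetic fixtures do and do not establish about
real scans.

## Color model

Input images are 8-bit sRGB. HSV uses the hexcone model: V = max/255,
S = (max−min)/max (0 when max = 0), H by the piecewise sector formula in
degrees [0, 360). The hue of achromatic pixels is defined as 0 so that
histograms and means are deterministic. Many 8-bit imaging libraries
store hue in [0, 180]; every threshold in this package uses the
degree/fraction convention and the preset layer documents it.

CIELAB assumes the sRGB primaries and transfer function and the D65
reference white (X, Y, Z) = (0.95047, 1, 1.08883) with the 7-digit IEC
sRGB→XYZ matrix. No ICC handling is attempted. The choice of working
space/white point is ours; scanner output that is not sRGB will carry a
systematic (but zone-independent) offset. Conversions agree with
scikit-image's within 5·10⁻³ Lab units and 10⁻¹³ HSV units on random
colors; the HSV inverse exists only for round-trip testing.

## Masking

Foreground = {S ≥ s_min ∧ V ≥ v_min}. Defaults 0.15/0.15 separate
colored signal from near-black wax (V ≈ 0.08) and gray paper (S ≈ 0.01)
with a margin of several noise standard deviations on typical scans.

The box blur operates on the binary mask (not the color image) with
zero-padding and re-binarization at exactly one half of the window,
implemented with integer window sums so the threshold comparison is
exact; k = 1 is the identity and even k is rejected. The 0.5 threshold is
symmetric (foreground and background are treated alike) and idempotent on
solid regions.

Dilation and erosion use a fixed 3×3 square element, one iteration per
step. Erosion treats pixels outside the image as foreground; with the
conventional background border, the closing of a region touching the
image edge loses pixels and the adjunction laws
(erode∘dilate ⊇ id, dilate∘erode ⊆ id) fail there. With the foreground
border both laws hold on the whole finite grid, which the property tests
assert for arbitrary masks.

## Contours and moments

Components are 8-connected; holes do not split a component and only the
outer boundary is traced (Moore-neighbor border following from the
raster-first pixel, terminating when the trace leaves the start pixel
toward the same second pixel again — this handles 1-px-thin shapes whose
boundary legitimately passes through pixels twice). Components under
5 px are discarded; this cutoff sets the minimum detectable feature
size. Indices follow raster order of first pixels.

`central_moments` sums (x−x̄)ᵖ(y−ȳ)ᑫ over the filled pixel set, written
as Σ(nx−Σx)ᵖ(ny−Σy)ᑫ / nᵖ⁺ᑫ so the centered coordinates stay
integer-valued: for blobs up to a few hundred pixels every intermediate
is exactly representable in float64 and the result is bit-identical to
an exact rational brute-force double loop (the oracle the tests use).

Hu invariants are computed from these moments with one refinement: pixels
are modeled as unit squares rather than point masses, which for central
moments up to order 3 adds exactly n/12 to μ₂₀ and μ₀₂ and nothing else.
This makes the invariants of rasterized shapes track their continuous
values closely — a 60×20 rectangle re-rasterized after a 37° rotation
reproduces its invariants to ~1–2%, versus ~8% on h₂ with point masses.
A filled disk gives h₁ = 1/(2π) to within 1%, matching the continuous
closed form.

## Shape distance

d(a, b) = Σᵢ |t(aᵢ) − t(bᵢ)| with t(h) = sign(h)·log₁₀|h| and t(h) = 0
for |h| ≤ 10⁻⁵. The log transform is the common shape-matching
convention: the raw invariants span many orders of magnitude and raw
differences are dominated by h₁ (the raw variant remains available via
`log_scale=False`). The 10⁻⁵ floor is essential: for near-symmetric
shapes h₂…h₇ are rasterization noise (10⁻⁸…10⁻¹⁶), and differences of
their logarithms would otherwise swamp the real signal — with the floor,
a disk and a re-rasterized disk score ~3·10⁻⁵ apart while a disk and an
equal-area 10:1 rectangle score ~0.9, a separation of four orders of
magnitude. Matching gates on relative area difference and shape distance
jointly; the reference always matches itself.

## Zone refinement and measurement

The analysis region (circle or regular n-gon of fixed circumradius) is
anchored at each matched contour's centroid plus a common (dx, dy), with
the polygon rotated by a common angle about its own center after
displacement (the alternative — orbiting the region about the centroid —
was considered and rejected as less predictable for users). Per-contour
orientation estimation is deliberately not attempted: devices in one scan
share an orientation. Displacement is not clipped to the contour, which
is precisely what allows measuring a zone at the end of a fluid channel
whose pale pixels merged with the zone during masking.

A pixel belongs to the region iff its center satisfies the shape
inequality (circle: ≤ r²; polygon: within every edge half-plane, with a
10⁻⁹ slack on the boundary). Angles are measured from +x toward +y
(clockwise on screen, y down).

Statistics are the arithmetic mean and population SD (divide by n) per
channel per space, on native scales (RGB 0–255, H degrees, S/V 0–1, Lab
native). The hue mean is arithmetic by default and therefore biased for
distributions straddling the 0/360 wrap; `circular_hue=True` switches to
the circular mean. Histograms are 256 unit-width bins of the raw 8-bit
RGB values and always sum to the pixel count. Conversion-then-average
equals average-then-conversion only for uniform zones, and is asserted
only there.

## Presets and export

Presets are YAML with a `schema_version`; loading is strict (missing
blocks, unknown fields, unsupported versions, and out-of-range values all
raise, naming the field). Numbers in `results.csv` carry 6 significant
digits; rows sort by zone index, making repeated runs byte-identical.
The manifest (timestamp, version, zone count) is the only
non-deterministic output.

## Synthetic fixtures

The renderer rasterizes analytic geometry (after rotating the device
layout about the image center) rather than resampling a raster, so with
noise off every zone is an exact uniform or radial-gradient fill and the
recorded ground-truth means are exact. Noise is iid Gaussian per channel,
seeded, added after ground truth is recorded, and clipped to [0, 255].

Defaults model the imaging conditions the pipeline targets: near-black
background (20, 20, 20) — dark enough to mask out, light enough that
thresholds are non-trivially exercised; the canonical strip of 4
replicate devices × 6 circular zones of radius 30 px with the six
distinct fills listed in `padscan.synth.STRIP_FILLS`; saturated contrast
rings of 4 px separated from each zone by a 3 px background gap so they
form their own annular contours and the matching stage must genuinely
reject them; σ = 3 noise for the noisy variant (~1% of full scale,
typical of consumer flatbed scans); and a channel-end device whose pale
tinted channels merge with their zones during masking, exercising the
(dx, dy) refinement.

What passing these fixtures does **not** show: robustness to paper
texture, ink bleed, illumination gradients, scanner PSF blur, JPEG
artifacts, or zones with low contrast against the substrate — none of
which the renderer models. Threshold and tolerance defaults will need
adjustment per real device design; that is what presets are for.

## Problem sizes

The test suite and acceptance script run on the 775×300 px strip (24
zones of ~2800 px each), 100-seed noise ensembles on a 100×100 single-zone
device, 1000-color conversion panels, and 50–200 px random blobs for the
moment oracle — sizes at which every check completes in seconds while
leaving zone statistics well out of the small-sample regime.

## Known limitations

* No background (blank-paper) subtraction or calibration to analyte
  concentration — outputs are raw intensities.
* Contour hierarchies are not modeled; a zone inside another zone's hole
  is not separately detected (ring interiors are handled by refinement
  instead).
* The arithmetic hue mean near the red wrap, as noted above.
* 16-bit and CMYK inputs are out of scope; files are converted to 8-bit
  RGB on load.
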