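"""Color-space conversions used for zone measurement.

Converts a handful of 8-bit sRGB colors to HSV (hue in degrees,
saturation/value as fractions) and CIELAB (D65 white point). Saturation
and value are what the masking stage thresholds: note how the dark wax
barrier has near-zero value and plain paper near-zero saturation, while
colorimetric signal scores high on both.
"""

from padscan import rgb_to_hsv, rgb_to_lab

colors = {
    "wax barrier (near-black)": (20, 20, 20),
    "blank paper (light gray)": (230, 230, 228),
    "assay signal (yellow-green)": (212, 214, 153),
    "assay signal (magenta)": (223, 84, 204),
    "pure red": (255, 0, 0),
}

print(f"{'sample':<28} {'RGB':>15} {'H deg':>7} {'S':>6} {'V':>6} {'L*':>7} {'a*':>7} {'b*':>7}")
for name, rgb in colors.items():
    h, s, v = rgb_to_hsv(rgb)
    L, a, b = rgb_to_lab(rgb)
    print(
        f"{name:<28} {str(rgb):>15} {h:7.1f} {s:6.3f} {v:6.3f} {L:7.2f} {a:7.2f} {b:7.2f}"
    )
print("\nmasking keeps pixels with S and V above their thresholds: only the")
print("assay colors (and pure red) pass the default 0.15 / 0.15 preset.")
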