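"""Measuring detection zones at the ends of fluid channels.

Channel-fed zones mask together with their pale channel, so the contour
centroid is pulled into the channel and a region centered on it would
average channel pixels into the signal. Displacing the analysis region by
a fixed (dx, dy) — set once on the reference contour — moves every
region onto its zone. The same displacement applies to all matched
contours, which is what makes replicate channel devices measurable in
batch.
"""

import padscan as ps
from padscan.synth import channel_device

img, truth = channel_device(seed=4)
mask = ps.refine_mask(img, ps.default_preset().mask)
contours = ps.extract_contours(mask)
print(f"contours found: {len(contours)} (each = zone + its channel, merged)")

# displacement from the merged centroid back to the zone center,
# read off the reference contour once
dx = truth.zones[0].center[0] - contours[0].centroid[0]
print(f"centroid sits {-dx:.1f} px into the channel; using dx = {dx:.1f}\n")

for shifted, label in ((False, "centered on contour"), (True, "displaced to zone")):
    g = ps.RegionGeometry(shape="circle", radius=14.0, dx=dx if shifted else 0.0)
    print(label)
    for c, reg in zip(contours, ps.propagate(contours, g, img.shape)):
        res = ps.measure_zone(img, reg, spaces=("RGB",))
        got = [res.stats["RGB"][ch]["mean"] for ch in "RGB"]
        z = truth.zones[c.index]
        print(
            f"  zone {c.index}: measured "
            + ", ".join(f"{v:6.1f}" for v in got)
            + f"   true fill {z.mean_rgb}"
        )
    print()
print("without the displacement the means mix channel color into the signal;")
print("with it they equal the true fills exactly (noiseless render).")
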