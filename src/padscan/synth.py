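"""Synthetic device-scan renderer with analytic ground truth.

Emulates a flatbed scan of a paper microfluidic device: colored output
zones (circles, regular polygons, or channel-end layouts) on a near-black
wax-barrier background, optionally surrounded by printed contrast rings,
with additive Gaussian scanner noise. The whole device layout can be
rotated to mimic arbitrary placement on the scanner bed.

Rendering rasterizes the *analytic* geometry after rotating zone centers
and shapes — no raster resampling — so with noise off every zone is a
uniform (or analytically graded) fill and ground-truth means are exact.
Ground truth (true center, pixel area, mean RGB over the zone interior)
is recorded before noise is added.

What this emulates and what it does not: flat fields, hard zone edges and
iid per-pixel noise stand in for real scans; paper texture, ink bleed,
illumination gradients and scanner PSF blur are not modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import SpecError

__all__ = [
    "ZoneSpec",
    "DeviceSpec",
    "ZoneTruth",
    "GroundTruth",
    "render_device",
    "four_device_strip",
    "channel_device",
    "STRIP_FILLS",
    "min_area_ladder",
]

#: Six distinct zone fills used by the canonical four-device strip fixture
#: (one per assay spot: yellow-green, tan, magenta, brick, lavender, amber).
STRIP_FILLS = (
    (212, 214, 153),
    (212, 181, 128),
    (223, 84, 204),
    (192, 110, 102),
    (180, 150, 184),
    (218, 190, 102),
)

#: Saturated contrast-ring color, distinct from every strip fill.
RING_RGB = (60, 170, 200)

#: Pale but saturated fluid-channel tint (passes S/V masking like real
#: channels wetted with sample do).
CHANNEL_RGB = (205, 190, 160)


@dataclass(frozen=True)
class ZoneSpec:
    """One output zone of a synthetic device.

    shape: ``circle``, ``regular_polygon`` or ``channel_end``. ``radius``
    is the circle/terminal-zone radius or polygon circumradius in px.
    ``gradient`` is ``None`` (uniform fill) or ``("radial", inner_rgb,
    outer_rgb)`` interpolating with radial distance. ``ring`` is ``None``
    or ``(ring_rgb, thickness)``; the ring is separated from the zone edge
    by ``ring_gap`` px of background so it forms its own contour. For
    ``channel_end``, a channel of ``channel_length`` x ``channel_width`` px
    extends from the zone center at ``channel_angle`` degrees.
    """

    center: tuple
    radius: float
    fill_rgb: tuple
    shape: str = "circle"
    n_sides: int = 6
    angle: float = 0.0
    gradient: tuple | None = None
    ring: tuple | None = None
    ring_gap: float = 3.0
    channel_length: float = 60.0
    channel_width: float = 12.0
    channel_angle: float = 0.0


@dataclass(frozen=True)
class DeviceSpec:
    """A full synthetic scan: image size, background, zones, noise."""

    image_size: tuple  # (W, H)
    zones: tuple
    background_rgb: tuple = (20, 20, 20)
    rotation_deg: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class ZoneTruth:
    center: tuple  # true (x, y) after layout rotation
    area: int  # interior pixel count
    mean_rgb: tuple  # exact mean over the interior, before noise


@dataclass
class GroundTruth:
    zones: list = field(default_factory=list)

    def to_json(self, path) -> None:
        doc = [
            {"center": list(z.center), "area": z.area, "mean_rgb": list(z.mean_rgb)}
            for z in self.zones
        ]
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            zones=[
                ZoneTruth(tuple(d["center"]), int(d["area"]), tuple(d["mean_rgb"]))
                for d in doc
            ]
        )


def _rotate(pt, pivot, deg):
    th = np.deg2rad(deg)
    dx, dy = pt[0] - pivot[0], pt[1] - pivot[1]
    return (
        pivot[0] + dx * np.cos(th) - dy * np.sin(th),
        pivot[1] + dx * np.sin(th) + dy * np.cos(th),
    )


def _disk_pixels(center, r, shape):
    cx, cy = center
    H, W = shape
    x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r))
    y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r))
    if x0 < 0 or y0 < 0 or x1 >= W or y1 >= H:
        raise SpecError(f"zone geometry at ({cx:.0f}, {cy:.0f}) exceeds image bounds")
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    d2 = (xs - cx) ** 2 + (ys - cy) ** 2
    keep = d2 <= r * r
    return xs[keep], ys[keep], np.sqrt(d2[keep])


def _polygon_pixels(center, r, n, angle_deg, shape):
    cx, cy = center
    H, W = shape
    x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r))
    y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r))
    if x0 < 0 or y0 < 0 or x1 >= W or y1 >= H:
        raise SpecError(f"zone geometry at ({cx:.0f}, {cy:.0f}) exceeds image bounds")
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    px, py = (xs - cx).ravel(), (ys - cy).ravel()
    apothem = r * np.cos(np.pi / n)
    normals = np.deg2rad(angle_deg) + (np.arange(n) + 0.5) * 2 * np.pi / n
    proj = px[:, None] * np.cos(normals) + py[:, None] * np.sin(normals)
    keep = (proj <= apothem + 1e-9).all(axis=1)
    d = np.sqrt(px[keep] ** 2 + py[keep] ** 2)
    return xs.ravel()[keep], ys.ravel()[keep], d


def _channel_pixels(center, length, width, angle_deg, start_r, shape):
    """Pixels of a channel rectangle extending from a zone edge."""
    cx, cy = center
    H, W = shape
    th = np.deg2rad(angle_deg)
    ux, uy = np.cos(th), np.sin(th)  # along-channel unit vector
    nx, ny = -uy, ux
    corners = np.array(
        [
            (cx + ux * a + nx * b, cy + uy * a + ny * b)
            for a in (start_r - 1, start_r + length)
            for b in (-width / 2, width / 2)
        ]
    )
    x0, x1 = int(np.floor(corners[:, 0].min())), int(np.ceil(corners[:, 0].max()))
    y0, y1 = int(np.floor(corners[:, 1].min())), int(np.ceil(corners[:, 1].max()))
    if x0 < 0 or y0 < 0 or x1 >= W or y1 >= H:
        raise SpecError(f"channel at ({cx:.0f}, {cy:.0f}) exceeds image bounds")
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    px, py = (xs - cx).ravel(), (ys - cy).ravel()
    along = px * ux + py * uy
    across = -px * uy + py * ux
    keep = (along >= start_r - 1) & (along <= start_r + length) & (np.abs(across) <= width / 2)
    # exclude pixels already inside the zone disk
    keep &= px**2 + py**2 > start_r**2
    return xs.ravel()[keep], ys.ravel()[keep]


def render_device(spec: DeviceSpec):
    """Render a device spec to an 8-bit RGB image plus ground truth.

    Deterministic for a fixed ``spec.seed``. Zones (including rings and
    channels) must be pairwise non-overlapping; overlap raises
    :class:`SpecError`. Noise is iid Gaussian per channel, added after
    ground truth is recorded, and clipped to [0, 255].
    """
    W, H = spec.image_size
    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = np.asarray(spec.background_rgb, dtype=np.float64)
    owner = np.full((H, W), -1, dtype=np.int64)
    truth = GroundTruth()
    pivot = (W / 2.0, H / 2.0)

    def claim(xs, ys, zone_id):
        if np.any(owner[ys, xs] != -1):
            raise SpecError(f"zone {zone_id} overlaps a previously rendered feature")
        owner[ys, xs] = zone_id

    for zid, z in enumerate(spec.zones):
        center = _rotate(z.center, pivot, spec.rotation_deg)
        if z.shape in ("circle", "channel_end"):
            xs, ys, dist = _disk_pixels(center, z.radius, (H, W))
        elif z.shape == "regular_polygon":
            xs, ys, dist = _polygon_pixels(
                center, z.radius, z.n_sides, z.angle + spec.rotation_deg, (H, W)
            )
        else:
            raise SpecError(f"unknown zone shape {z.shape!r}")
        claim(xs, ys, zid)

        if z.gradient is None:
            img[ys, xs] = np.asarray(z.fill_rgb, dtype=np.float64)
        else:
            kind, inner, outer = z.gradient
            if kind != "radial":
                raise SpecError(f"unknown gradient kind {kind!r}")
            t = np.clip(dist / z.radius, 0.0, 1.0)[:, None]
            img[ys, xs] = (1 - t) * np.asarray(inner, float) + t * np.asarray(outer, float)
        # ground truth from the pre-noise float render, rounded as stored
        vals = np.rint(img[ys, xs])
        truth.zones.append(
            ZoneTruth(
                center=(float(center[0]), float(center[1])),
                area=int(len(xs)),
                mean_rgb=tuple(float(v) for v in vals.mean(axis=0)),
            )
        )
        img[ys, xs] = vals

        if z.ring is not None:
            ring_rgb, thickness = z.ring
            r_in = z.radius + z.ring_gap
            rx, ry, rd = _disk_pixels(center, r_in + thickness, (H, W))
            keep = rd > r_in
            rx, ry = rx[keep], ry[keep]
            claim(rx, ry, zid)
            img[ry, rx] = np.asarray(ring_rgb, dtype=np.float64)

        if z.shape == "channel_end":
            chx, chy = _channel_pixels(
                center, z.channel_length, z.channel_width,
                z.channel_angle + spec.rotation_deg, z.radius, (H, W)
            )
            claim(chx, chy, zid)
            img[chy, chx] = np.asarray(CHANNEL_RGB, dtype=np.float64)

    img = np.rint(img)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, truth


def four_device_strip(seed: int = 0, noise_sd: float = 0.0, rotation_deg: float = 0.0):
    """The canonical end-to-end fixture: a strip of four replicate devices.

    Each device carries six circular output zones (radius 30 px, one fill
    per assay position, identical across replicates) surrounded by
    contrast rings, on a near-black wax background — 24 zones total.
    """
    r = 30.0
    cell = 95
    margin = 55
    fills = STRIP_FILLS
    zones = []
    for dev in range(4):
        ox = margin + dev * 2 * cell
        for k in range(6):
            col, row = divmod(k, 3)
            zones.append(
                ZoneSpec(
                    center=(ox + col * cell, margin + row * cell),
                    radius=r,
                    fill_rgb=fills[k],
                    ring=(RING_RGB, 4.0),
                )
            )
    W = 2 * margin + (4 * 2 - 1) * cell
    H = 2 * margin + 2 * cell
    if rotation_deg:
        # pad so the rotated layout stays inside the image
        th = np.deg2rad(abs(rotation_deg) % 360.0)
        half_diag = np.hypot(W / 2.0, H / 2.0)
        pad = int(np.ceil(half_diag * (np.sin(min(th, np.pi / 2)) + 1.0 - np.cos(min(th, np.pi / 2)))))
        zones = [
            ZoneSpec(**{**z.__dict__, "center": (z.center[0] + pad, z.center[1] + pad)})
            for z in zones
        ]
        W += 2 * pad
        H += 2 * pad
    spec = DeviceSpec(
        image_size=(W, H),
        zones=tuple(zones),
        rotation_deg=rotation_deg,
        noise_sd=noise_sd,
        seed=seed,
    )
    return render_device(spec)


def channel_device(seed: int = 0, noise_sd: float = 0.0):
    """Three channel-end detection zones fed by pale fluid channels.

    Each colored terminal zone (radius 18 px) sits at the end of a tinted
    channel pointing away from it; masking merges channel and zone into one
    elongated contour, so measuring the zone requires displacing the
    analysis region toward the channel end — the geometry the (dx, dy)
    refinement controls exist for.
    """
    fills = ((210, 120, 60), (120, 190, 80), (90, 130, 220))
    zones = tuple(
        ZoneSpec(
            center=(70.0, 60.0 + 90.0 * i),
            radius=18.0,
            fill_rgb=fills[i],
            shape="channel_end",
            channel_length=80.0,
            channel_width=14.0,
            channel_angle=0.0,  # channel extends toward +x
        )
        for i in range(3)
    )
    spec = DeviceSpec(image_size=(260, 300), zones=zones, noise_sd=noise_sd, seed=seed)
    return render_device(spec)


def min_area_ladder(areas=range(1, 11), gap: int = 12):
    """A mask containing one compact blob of each requested pixel area.

    Used to probe the minimum-feature-size cutoff of contour extraction.
    Returns (mask, list_of_areas) with blobs well separated.
    """
    areas = list(areas)
    W = gap * (len(areas) + 1) + 6 * len(areas)
    mask = np.zeros((20, W), dtype=bool)
    x = gap
    for a in areas:
        # fill a raster of up to 3 columns per row to keep blobs compact
        placed = 0
        row, col = 8, 0
        while placed < a:
            mask[row + col // 3, x + col % 3] = True
            placed += 1
            col += 1
        x += gap + 6
    return mask, areas
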