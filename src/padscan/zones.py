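"""Analysis regions and per-zone color measurement.

The matched contours delimit where signal *was detected*; the analysis
region defines where it is *measured*. A circle or regular polygon of fixed
size, offset (dx, dy) from the contour centroid and rotated by a fixed
angle, is placed identically on every matched contour. This excludes
undesired pixels (wax barrier edges, printed contrast rings) and lets a
region sit at the end of a fluid channel, outside the detected contour
entirely.

Geometry conventions: x right, y down, angles in degrees measured from the
+x axis toward +y (i.e. clockwise in the displayed image). The region shape
is rotated about its own center after displacement. A pixel belongs to a
region iff its integer center satisfies the shape inequality (circle:
(x-cx)^2 + (y-cy)^2 <= r^2; polygon: inside or on every edge).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .color import CHANNEL_NAMES, image_to_space
from .errors import ConfigError, DegenerateRegionError

__all__ = [
    "RegionGeometry",
    "AnalysisRegion",
    "ZoneResult",
    "place_region",
    "propagate",
    "measure_zone",
    "crop_zone",
]


@dataclass(frozen=True)
class RegionGeometry:
    """Shape of the analysis region, relative to a contour centroid.

    shape: ``"circle"`` or ``"regular_polygon"``; ``n_sides >= 3`` applies
    to polygons only. ``radius`` is the circle radius or polygon circumradius
    in pixels. ``dx, dy`` displace the region center from the contour
    centroid; ``angle`` rotates the polygon about the region center.
    """

    shape: str = "circle"
    radius: float = 10.0
    n_sides: int = 6
    dx: float = 0.0
    dy: float = 0.0
    angle: float = 0.0

    def validate(self) -> None:
        if self.shape not in ("circle", "regular_polygon"):
            raise ConfigError(
                f"geometry.shape must be 'circle' or 'regular_polygon', got {self.shape!r}"
            )
        if not self.radius > 0:
            raise ConfigError(f"geometry.radius must be positive, got {self.radius!r}")
        if self.shape == "regular_polygon" and (
            not isinstance(self.n_sides, int) or self.n_sides < 3
        ):
            raise ConfigError(f"geometry.n_sides must be an integer >= 3, got {self.n_sides!r}")
        for name in ("dx", "dy", "angle"):
            if not isinstance(getattr(self, name), (int, float)):
                raise ConfigError(f"geometry.{name} must be a number")


@dataclass
class AnalysisRegion:
    """A rasterized measurement region anchored to one contour."""

    center: tuple
    geometry: RegionGeometry
    pixels: np.ndarray  # (n, 2) int (x, y), clipped to image bounds
    zone_index: int


@dataclass
class ZoneResult:
    """Statistics for one measured zone.

    ``stats[space][channel]`` is ``{"mean": float, "sd": float}`` with the
    population SD (divide by n). ``histograms`` maps R/G/B to 256 integer
    counts of the raw 8-bit values. ``crop_bounds`` is the inclusive
    bounding rectangle of the anchoring contour, (x0, y0, x1, y1).
    """

    zone_index: int
    stats: dict
    histograms: dict
    crop_bounds: tuple
    n_pixels: int
    crop: np.ndarray | None = None  # cropped zone image, filled in by the pipeline


def _rasterize(geometry: RegionGeometry, center, image_shape) -> np.ndarray:
    cx, cy = center
    r = float(geometry.radius)
    H, W = image_shape[:2]
    x0 = max(int(np.floor(cx - r)), 0)
    x1 = min(int(np.ceil(cx + r)), W - 1)
    y0 = max(int(np.floor(cy - r)), 0)
    y1 = min(int(np.ceil(cy + r)), H - 1)
    if x1 < x0 or y1 < y0:
        return np.empty((0, 2), dtype=np.int64)
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    px = xs.ravel().astype(np.float64) - cx
    py = ys.ravel().astype(np.float64) - cy
    if geometry.shape == "circle":
        inside = px * px + py * py <= r * r
    else:
        n = geometry.n_sides
        # Regular n-gon, vertices at angle + k*360/n on the circumcircle.
        # A point is inside iff its projection on every edge's outward
        # normal (at angle + (k + 1/2)*360/n) does not exceed the apothem.
        apothem = r * np.cos(np.pi / n)
        normals = np.deg2rad(geometry.angle) + (np.arange(n) + 0.5) * 2.0 * np.pi / n
        proj = px[:, None] * np.cos(normals) + py[:, None] * np.sin(normals)
        inside = (proj <= apothem + 1e-9).all(axis=1)
    return np.column_stack([xs.ravel()[inside], ys.ravel()[inside]]).astype(np.int64)


def place_region(contour, geometry: RegionGeometry, image_shape) -> AnalysisRegion:
    """Rasterize the region for one contour.

    The center is the contour centroid plus (dx, dy); displacement is not
    clipped to the contour, so a region may lie wholly outside it (the
    channel-end case). Pixels falling outside the image are dropped; an
    empty result raises :class:`DegenerateRegionError`.
    """
    geometry.validate()
    center = (contour.centroid[0] + geometry.dx, contour.centroid[1] + geometry.dy)
    pixels = _rasterize(geometry, center, image_shape)
    if len(pixels) == 0:
        raise DegenerateRegionError(
            f"analysis region for contour {contour.index} at center "
            f"({center[0]:.1f}, {center[1]:.1f}) covers no in-bounds pixels"
        )
    return AnalysisRegion(center=center, geometry=geometry, pixels=pixels, zone_index=contour.index)


def propagate(contours, geometry: RegionGeometry, image_shape) -> list:
    """Place the identical geometry on every contour, preserving order."""
    if not contours:
        raise ConfigError("cannot propagate a region over an empty contour list")
    return [place_region(c, geometry, image_shape) for c in contours]


def _circular_mean_deg(deg: np.ndarray) -> float:
    ang = np.deg2rad(deg)
    return float(np.rad2deg(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())) % 360.0)


def measure_zone(img, region: AnalysisRegion, spaces=("RGB", "HSV", "LAB"),
                 crop_bounds=None, circular_hue: bool = False) -> ZoneResult:
    """Mean and population SD per channel per requested color space.

    RGB histograms use 256 unit-width bins over the raw 8-bit values. The
    HSV hue mean is the plain arithmetic mean of degrees by default, which
    is biased for hue distributions straddling the 0/360 wrap; pass
    ``circular_hue=True`` for the circular mean (SD stays linear).
    """
    img = np.asarray(img)
    xs, ys = region.pixels[:, 0], region.pixels[:, 1]
    raw = img[ys, xs, :].astype(np.float64)  # (n, 3) RGB
    n = len(raw)

    stats = {}
    for space in spaces:
        key = space.upper()
        vals = image_to_space(raw, key) if key != "RGB" else raw
        ch_stats = {}
        for j, ch in enumerate(CHANNEL_NAMES[key]):
            col = vals[:, j]
            if key == "HSV" and ch == "H" and circular_hue:
                mean = _circular_mean_deg(col)
            else:
                mean = float(col.mean())
            ch_stats[ch] = {"mean": mean, "sd": float(col.std())}
        stats[key] = ch_stats

    histograms = {
        ch: np.bincount(raw[:, j].astype(np.int64), minlength=256)
        for j, ch in enumerate(CHANNEL_NAMES["RGB"])
    }
    if crop_bounds is None:
        crop_bounds = (int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max()))
    return ZoneResult(
        zone_index=region.zone_index,
        stats=stats,
        histograms=histograms,
        crop_bounds=tuple(crop_bounds),
        n_pixels=n,
    )


def crop_zone(img, contour) -> np.ndarray:
    """Sub-image spanning the inclusive bounding rectangle of a contour."""
    x0, y0, x1, y1 = contour.bounds
    return np.asarray(img)[y0 : y1 + 1, x0 : x1 + 1].copy()
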