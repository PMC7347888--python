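"""Color-space conversions from 8-bit sRGB to HSV and CIELAB.

Conventions used throughout the package:

* **RGB** — integer channels in [0, 255], sRGB-encoded, as stored in the
  image file.
* **HSV** — hexcone model. Hue in degrees [0, 360); saturation and value as
  fractions in [0, 1]. The hue of an achromatic pixel (S = 0) is defined to
  be 0 so that histograms and means are deterministic. Note that many 8-bit
  image libraries store hue in [0, 180]; every threshold in this package is
  expressed in the degree/fraction convention above.
* **CIELAB** — CIE 1976 L*a*b* under the D65 reference white and the sRGB
  primaries/transfer function. L* in [0, 100] for in-gamut input; a*, b*
  unbounded (practically within about +/-128).

All conversions are total functions of valid 8-bit input: no clipping or
exceptional cases arise.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rgb_to_hsv",
    "rgb_to_lab",
    "hsv_to_rgb",
    "image_to_space",
    "SPACES",
    "CHANNEL_NAMES",
]

SPACES = ("RGB", "HSV", "LAB")

CHANNEL_NAMES = {
    "RGB": ("R", "G", "B"),
    "HSV": ("H", "S", "V"),
    "LAB": ("L", "a", "b"),
}

# IEC 61966-2-1 sRGB -> CIE XYZ (D65, 2-degree observer), 7-digit form.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_D65_WHITE = np.array([0.95047, 1.0, 1.08883])

_EPS = (6.0 / 29.0) ** 3          # CIE threshold between cube-root and linear branch
_KAPPA_INV = 1.0 / (3.0 * (6.0 / 29.0) ** 2)


def _as_float_rgb(arr) -> np.ndarray:
    """Validate 8-bit RGB input and scale to [0, 1] float64."""
    a = np.asarray(arr, dtype=np.float64)
    if a.shape[-1] != 3:
        raise ValueError("RGB input must have 3 channels in the last axis")
    if a.min() < 0 or a.max() > 255:
        raise ValueError("RGB channels must lie in [0, 255]")
    return a / 255.0


def rgb_to_hsv(rgb) -> np.ndarray:
    """Convert 8-bit sRGB to hexcone HSV.

    Parameters
    ----------
    rgb : array-like, shape (..., 3)
        Integer channel values in [0, 255]. A single triple is accepted.

    Returns
    -------
    ndarray, shape (..., 3)
        ``(h, s, v)`` with h in degrees [0, 360), s and v in [0, 1].
        V = max/255; S = (max-min)/max, or 0 where max = 0; H follows the
        usual piecewise sector formula and is 0 for achromatic input.
    """
    c = _as_float_rgb(rgb)
    r, g, b = c[..., 0], c[..., 1], c[..., 2]
    v = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    delta = v - mn

    s = np.where(v > 0, delta / np.where(v > 0, v, 1.0), 0.0)

    # Sector formula; division guarded where delta == 0 (hue defined as 0).
    safe = np.where(delta > 0, delta, 1.0)
    h = np.where(
        v == r,
        (g - b) / safe,
        np.where(v == g, 2.0 + (b - r) / safe, 4.0 + (r - g) / safe),
    )
    h = np.where(delta > 0, (h * 60.0) % 360.0, 0.0)
    return np.stack([h, s, v], axis=-1)


def hsv_to_rgb(hsv) -> np.ndarray:
    """Inverse hexcone conversion, back to 8-bit integer sRGB.

    Provided for testing round-trips; the analysis pipeline never needs it.
    """
    a = np.asarray(hsv, dtype=np.float64)
    h, s, v = a[..., 0], a[..., 1], a[..., 2]
    h6 = (h % 360.0) / 60.0
    i = np.floor(h6).astype(int) % 6
    f = h6 - np.floor(h6)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    choices = [
        (v, t, p),
        (q, v, p),
        (p, v, t),
        (p, q, v),
        (t, p, v),
        (v, p, q),
    ]
    r = np.select([i == k for k in range(6)], [c[0] for c in choices])
    g = np.select([i == k for k in range(6)], [c[1] for c in choices])
    b = np.select([i == k for k in range(6)], [c[2] for c in choices])
    out = np.stack([r, g, b], axis=-1) * 255.0
    return np.rint(out).astype(np.int64)


def rgb_to_lab(rgb) -> np.ndarray:
    """Convert 8-bit sRGB to CIE 1976 L*a*b* (D65 white point).

    The sRGB transfer function is inverted (linear segment below 0.04045,
    gamma 2.4 branch above), linear RGB is mapped to XYZ with the standard
    sRGB matrix, and L*a*b* uses the cube-root/linear-segment f() of the
    CIE definition.
    """
    c = _as_float_rgb(rgb)
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    xyz = lin @ _SRGB_TO_XYZ.T
    t = xyz / _D65_WHITE
    f = np.where(t > _EPS, np.cbrt(t), t * _KAPPA_INV + 4.0 / 29.0)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def image_to_space(img, space: str) -> np.ndarray:
    """Convert a whole H x W x 3 8-bit image to the requested color space.

    ``space`` is one of ``"RGB"`` (identity, returned as float64), ``"HSV"``
    or ``"LAB"`` (case-insensitive). Unknown names raise
    :class:`~padscan.errors.ConfigError`.
    """
    from .errors import ConfigError

    key = space.upper()
    if key == "RGB":
        return np.asarray(img, dtype=np.float64)
    if key == "HSV":
        return rgb_to_hsv(img)
    if key == "LAB":
        return rgb_to_lab(img)
    raise ConfigError(f"unknown color space {space!r}; expected one of {SPACES}")
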