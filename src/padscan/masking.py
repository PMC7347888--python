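"""Foreground masking: isolate color-containing pixels of a device scan.

A scanned device shows colored output zones against a dark hydrophobic
barrier (near-black wax) and near-gray paper. Dark pixels have low HSV
*value*; gray pixels have low *saturation*. Thresholding both channels
therefore keeps exactly the colored zones. The raw mask is then smoothed
with a box blur and optionally refined by morphological dilation/erosion
before contour extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .color import rgb_to_hsv
from .errors import ConfigError

__all__ = ["MaskParams", "build_mask", "box_blur_binarize", "dilate", "erode", "refine_mask"]

# 3x3 square structuring element; one dilate/erode step moves boundaries by
# one pixel in the chessboard metric.
_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class MaskParams:
    """Masking stage parameters.

    Attributes
    ----------
    v_min, s_min : float
        Minimum HSV value / saturation, fractions of full scale in [0, 1].
        Pixels below either threshold are background.
    blur_kernel : int
        Odd box-blur kernel side in pixels; 1 disables blurring.
    dilate_iters, erode_iters : int
        Iterations of 3x3 morphological dilation / erosion applied after
        the blur (dilation first).
    """

    v_min: float = 0.15
    s_min: float = 0.15
    blur_kernel: int = 3
    dilate_iters: int = 0
    erode_iters: int = 0

    def validate(self) -> None:
        for name in ("v_min", "s_min"):
            x = getattr(self, name)
            if not (isinstance(x, (int, float)) and 0.0 <= x <= 1.0):
                raise ConfigError(f"mask.{name} must be a fraction in [0, 1], got {x!r}")
        k = self.blur_kernel
        if not (isinstance(k, int) and k >= 1 and k % 2 == 1):
            raise ConfigError(f"mask.blur_kernel must be an odd integer >= 1, got {k!r}")
        for name in ("dilate_iters", "erode_iters"):
            n = getattr(self, name)
            if not (isinstance(n, int) and n >= 0):
                raise ConfigError(f"mask.{name} must be a non-negative integer, got {n!r}")


def build_mask(img, v_min: float, s_min: float) -> np.ndarray:
    """Binarize an RGB image by saturation and value thresholds.

    A pixel is foreground iff ``S >= s_min`` and ``V >= v_min`` in HSV.
    Returns an H x W boolean array.
    """
    if not (0.0 <= v_min <= 1.0 and 0.0 <= s_min <= 1.0):
        raise ConfigError("thresholds must lie in [0, 1]")
    hsv = rgb_to_hsv(img)
    return (hsv[..., 1] >= s_min) & (hsv[..., 2] >= v_min)


def box_blur_binarize(mask: np.ndarray, k: int) -> np.ndarray:
    """Mean-filter a binary mask with a k x k box and re-binarize at 0.5.

    The image border is zero-padded, so foreground shrinks where fewer than
    half of a border pixel's window is foreground. Implemented with integer
    window sums so the 0.5 comparison is exact: a pixel stays foreground iff
    at least ceil(k*k / 2) of its window is foreground. ``k = 1`` is the
    identity. Even ``k`` is rejected.
    """
    if k < 1 or k % 2 == 0:
        raise ConfigError(f"blur kernel must be odd and >= 1, got {k}")
    if k == 1:
        return mask.copy()
    kern = np.ones(k, dtype=np.int64)
    counts = ndimage.convolve1d(mask.astype(np.int64), kern, axis=0, mode="constant", cval=0)
    counts = ndimage.convolve1d(counts, kern, axis=1, mode="constant", cval=0)
    # exact integer window sums; foreground iff at least half the window is
    return 2 * counts >= k * k


def dilate(mask: np.ndarray, iters: int) -> np.ndarray:
    """Iterated morphological dilation with a 3x3 square element."""
    if iters <= 0:
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=_SQUARE3, iterations=iters)


def erode(mask: np.ndarray, iters: int) -> np.ndarray:
    """Iterated morphological erosion with a 3x3 square element.

    Pixels outside the image are treated as foreground, so a region
    touching the border keeps its border pixels. This convention makes
    dilation/erosion a proper adjunction on the finite grid:
    erode(dilate(m)) always contains m and dilate(erode(m)) is always
    contained in m, edges included.
    """
    if iters <= 0:
        return mask.copy()
    return ndimage.binary_erosion(mask, structure=_SQUARE3, iterations=iters, border_value=1)


def refine_mask(img, params: MaskParams) -> np.ndarray:
    """Full masking stage: threshold, blur, dilate, erode (in that order)."""
    params.validate()
    m = build_mask(img, params.v_min, params.s_min)
    m = box_blur_binarize(m, params.blur_kernel)
    m = dilate(m, params.dilate_iters)
    m = erode(m, params.erode_iters)
    return m
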