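"""The ordered analysis pipeline, from image file to exported results.

Stage order is fixed: threshold mask -> box blur -> dilate/erode ->
contour extraction -> reference selection -> similarity matching ->
region propagation -> per-zone measurement -> export. Each stage logs its
outcome (pixel and contour counts) through the ``padscan`` logger. The
whole run is deterministic: the same image and preset always produce the
same ``results.csv``, byte for byte.
"""

from __future__ import annotations

import logging
import os

import numpy as np
from PIL import Image

from .contours import extract_contours, find_similar, pick_reference
from .errors import NoZonesError
from .export import RunManifest, write_results
from .masking import refine_mask
from .presets import Preset
from .zones import crop_zone, measure_zone, propagate

__all__ = ["load_image", "analyze_image", "run_pipeline"]

log = logging.getLogger("padscan")


def load_image(path) -> np.ndarray:
    """Read a raster image (PNG/TIFF/JPEG/BMP, ...) as H x W x 3 uint8 RGB."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def analyze_image(img, preset: Preset, seed_point=None):
    """Run the in-memory pipeline on an RGB array.

    Returns ``(results, matched_contours, mask)`` where ``results`` is a
    list of :class:`~padscan.zones.ZoneResult` (crops attached) in zone
    index order. Raises :class:`~padscan.errors.NoZonesError` if no
    contour survives masking and area filtering; the exception carries the
    mask for inspection.
    """
    preset.validate()
    img = np.asarray(img)

    mask = refine_mask(img, preset.mask)
    log.info("mask: %d foreground pixels", int(mask.sum()))

    contours = extract_contours(mask)
    log.info("contours: %d candidates of area >= 5 px", len(contours))
    if not contours:
        raise NoZonesError(
            "no contours found; thresholds may exclude all zones", mask=mask
        )

    ref = pick_reference(contours, seed_point)
    log.info("reference: contour %d, area %d px", ref.index, ref.area)

    matched = find_similar(contours, ref, preset.match)
    log.info("matched: %d of %d contours similar to reference", len(matched), len(contours))
    if not matched:  # unreachable (ref always matches); guards future edits
        raise NoZonesError("similarity tolerances matched no contours", mask=mask)

    regions = propagate(matched, preset.geometry, img.shape)
    results = []
    for contour, region in zip(matched, regions):
        zr = measure_zone(img, region, spaces=preset.spaces, crop_bounds=contour.bounds)
        zr.crop = crop_zone(img, contour)
        results.append(zr)
    log.info("measured %d zones in spaces %s", len(results), ",".join(preset.spaces))
    return results, matched, mask


def run_pipeline(image_path, preset: Preset, seed_point=None, out_dir=None) -> RunManifest:
    """File-to-files pipeline: load, analyze, export.

    ``out_dir`` defaults to ``<image stem>_results`` next to the image. If
    no zones are found, the binarized mask is saved there as ``mask.png``
    to aid threshold tuning, and :class:`NoZonesError` propagates.
    """
    img = load_image(image_path)
    if out_dir is None:
        out_dir = os.path.splitext(str(image_path))[0] + "_results"
    try:
        results, _, _ = analyze_image(img, preset, seed_point)
    except NoZonesError as exc:
        if exc.mask is not None:
            os.makedirs(out_dir, exist_ok=True)
            Image.fromarray((exc.mask * np.uint8(255))).save(
                os.path.join(out_dir, "mask.png")
            )
            log.error("no zones; mask saved to %s", os.path.join(out_dir, "mask.png"))
        raise
    return write_results(
        results, out_dir, image_path=str(image_path), preset_name=preset.name
    )
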