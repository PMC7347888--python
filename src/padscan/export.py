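"""Result export: CSV tables, histogram plots, zone crops, manifest.

Layout of an output directory:

* ``results.csv`` — one row per (zone_index, color_space, channel) with
  mean and population SD on the native scale of each space (RGB 0-255,
  H degrees, S/V fractions, Lab native units); rows sorted by zone index.
* ``zone_<i>_hist.csv`` — 256-bin histograms of the raw 8-bit R, G, B
  values of zone i; ``zone_<i>_hist.png`` — the same as a bar plot.
* ``zone_<i>.png`` — crop of the zone's bounding rectangle.
* ``manifest.json`` — run provenance (image, preset, version, zone count).

Numbers are written with 6 significant digits.
"""

from __future__ import annotations

import datetime
import json
import os
from dataclasses import dataclass, asdict

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .color import CHANNEL_NAMES

__all__ = ["RunManifest", "write_results", "results_frame"]

_HIST_COLORS = {"R": "#c0392b", "G": "#27ae60", "B": "#2980b9"}


@dataclass
class RunManifest:
    image_path: str
    preset_name: str
    timestamp: str
    software_version: str
    n_zones: int
    output_dir: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def results_frame(results) -> pd.DataFrame:
    """Tidy per-channel statistics table, sorted by zone index.

    SD is the population standard deviation (divide by n).
    """
    rows = []
    for zr in sorted(results, key=lambda r: r.zone_index):
        for space, chans in zr.stats.items():
            for ch in CHANNEL_NAMES[space]:
                st = chans[ch]
                rows.append(
                    {
                        "zone_index": zr.zone_index,
                        "color_space": space,
                        "channel": ch,
                        "mean": _fmt(st["mean"]),
                        "sd_population": _fmt(st["sd"]),
                        "n_pixels": zr.n_pixels,
                    }
                )
    return pd.DataFrame(rows)


def write_results(results, out_dir, image_path="", preset_name="",
                  write_hist_plots: bool = True) -> RunManifest:
    """Write all result files for a run; returns the manifest.

    The directory is created if needed; an unwritable target raises
    ``OSError`` before any file is produced.
    """
    if not results:
        raise ValueError("no zone results to write")
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory {out_dir!r} is not writable")

    results = sorted(results, key=lambda r: r.zone_index)
    results_frame(results).to_csv(os.path.join(out_dir, "results.csv"), index=False)

    for zr in results:
        i = zr.zone_index
        hist = pd.DataFrame({"value": np.arange(256)})
        for ch in CHANNEL_NAMES["RGB"]:
            hist[ch] = zr.histograms[ch]
        hist.to_csv(os.path.join(out_dir, f"zone_{i}_hist.csv"), index=False)

        if write_hist_plots:
            fig, ax = plt.subplots(figsize=(4, 2.5))
            edges = np.arange(257)
            for ch in CHANNEL_NAMES["RGB"]:
                ax.stairs(zr.histograms[ch], edges, fill=True,
                          color=_HIST_COLORS[ch], alpha=0.55, label=ch)
            ax.set_xlabel("8-bit intensity")
            ax.set_ylabel("pixel count")
            ax.set_title(f"zone {i}")
            ax.legend(frameon=False, fontsize=8)
            fig.tight_layout()
            fig.savefig(os.path.join(out_dir, f"zone_{i}_hist.png"), dpi=100)
            plt.close(fig)

        if zr.crop is not None:
            Image.fromarray(zr.crop).save(os.path.join(out_dir, f"zone_{i}.png"))

    manifest = RunManifest(
        image_path=str(image_path),
        preset_name=preset_name,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        software_version=__version__,
        n_zones=len(results),
        output_dir=str(out_dir),
    )
    manifest.to_json(os.path.join(out_dir, "manifest.json"))
    return manifest
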