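import numpy as np
import pytest

from padscan import default_preset
from padscan.synth import four_device_strip


def disk_mask(r, size=None, cx=None, cy=None):
    """Boolean disk rasterized by the pixel-center-inside rule."""
    size = size or (2 * int(np.ceil(r)) + 9)
    cx = size // 2 if cx is None else cx
    cy = size // 2 if cy is None else cy
    ys, xs = np.mgrid[0:size, 0:size]
    return (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r


def rect_mask(w, h, angle_deg=0.0, size=200):
    """Rotated filled rectangle, center offset by a quarter pixel so that
    edges never fall exactly on pixel centers (keeps the effective size
    identical across rotations)."""
    ys, xs = np.mgrid[0:size, 0:size]
    px, py = xs - (size / 2 + 0.25), ys - (size / 2 + 0.25)
    t = np.deg2rad(angle_deg)
    u = px * np.cos(t) + py * np.sin(t)
    v = -px * np.sin(t) + py * np.cos(t)
    return (np.abs(u) <= w / 2) & (np.abs(v) <= h / 2)


def random_blob(rng, max_px=200, lo=5, box=64):
    """Random 8-connected blob grown by a seeded walk; coords within box."""
    n_target = int(rng.integers(lo, max_px + 1))
    pts = {(box // 2, box // 2)}
    while len(pts) < n_target:
        x, y = list(sorted(pts))[rng.integers(len(pts))]
        dx, dy = rng.integers(-1, 2, size=2)
        nx, ny = x + dx, y + dy
        if 0 <= nx < box and 0 <= ny < box:
            pts.add((nx, ny))
    return np.array(sorted(pts), dtype=np.int64)


@pytest.fixture(scope="session")
def strip_clean():
    """Noiseless four-device strip render with ground truth."""
    return four_device_strip(seed=11, noise_sd=0.0)


@pytest.fixture(scope="session")
def strip_noisy():
    """Strip render with sigma = 3 scanner noise."""
    return four_device_strip(seed=11, noise_sd=3.0)


@pytest.fixture(scope="session")
def preset():
    return default_preset()


def match_truth(centroid, truth):
    """Ground-truth zone record nearest to a measured centroid."""
    return min(
        truth.zones,
        key=lambda z: (z.center[0] - centroid[0]) ** 2 + (z.center[1] - centroid[1]) ** 2,
    )
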