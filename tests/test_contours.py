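"""Contour extraction, moment invariants, and similarity matching."""

from fractions import Fraction

import numpy as np
import pytest
from skimage import measure as skmeasure

from padscan import (
    MatchParams,
    extract_contours,
    find_similar,
    pick_reference,
    shape_distance,
)
from padscan.contours import central_moments, hu_from_pixels
from padscan.errors import NoZonesError, UsageError, ZoneNotFoundError
from padscan.synth import min_area_ladder
from tests.conftest import disk_mask, random_blob, rect_mask


def brute_force_moments(pixels, order=3):
    """Independent oracle: exact rational double-loop central moments."""
    n = len(pixels)
    xb = Fraction(sum(int(x) for x, _ in pixels), n)
    yb = Fraction(sum(int(y) for _, y in pixels), n)
    mu = np.zeros((order + 1, order + 1))
    for p in range(order + 1):
        for q in range(order + 1):
            acc = Fraction(0)
            for x, y in pixels:
                acc += (Fraction(int(x)) - xb) ** p * (Fraction(int(y)) - yb) ** q
            mu[p, q] = float(acc)
    return mu


class TestExtractContours:
    def test_two_disjoint_disks(self):
        m = disk_mask(5, size=60, cx=15, cy=30) | disk_mask(8, size=60, cx=45, cy=30)
        cs = extract_contours(m)
        assert len(cs) == 2
        # the radius-8 disk reaches a lower row first, so raster order puts it first
        assert [c.area for c in cs] == sorted((c.area for c in cs), reverse=True)

    def test_minimum_area_cutoff_is_five_pixels(self):
        """Blobs of area 1..10 px: only those of at least 5 px survive."""
        mask, areas = min_area_ladder(range(1, 11))
        cs = extract_contours(mask)
        assert sorted(c.area for c in cs) == [5, 6, 7, 8, 9, 10]
        assert min(c.area for c in cs) == 5

    def test_four_pixel_blob_dropped(self):
        m = np.zeros((10, 10), dtype=bool)
        m[4:6, 4:6] = True
        assert extract_contours(m) == []

    def test_empty_mask(self):
        assert extract_contours(np.zeros((5, 5), dtype=bool)) == []

    def test_indices_in_raster_order(self):
        m = np.zeros((40, 40), dtype=bool)
        m[2:5, 30:36] = True   # first row-wise
        m[20:26, 2:8] = True
        cs = extract_contours(m)
        assert [c.index for c in cs] == [0, 1]
        assert cs[0].centroid[1] < cs[1].centroid[1]

    def test_count_matches_ground_truth_on_random_masks(self):
        """100 random masks of well-separated blobs >= 5 px each."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n_blobs = int(rng.integers(1, 6))
            m = np.zeros((140, 140), dtype=bool)
            for k in range(n_blobs):
                cx, cy = 14 + 28 * (k % 5), 14 + 28 * (k // 5)
                r = float(rng.uniform(1.5, 9))
                m |= disk_mask(r, size=140, cx=cx, cy=cy)
            assert len(extract_contours(m)) == n_blobs

    def test_boundary_is_closed_8_connected_and_inside(self):
        for r in (3, 10):
            c = extract_contours(disk_mask(r, size=40))[0]
            b = c.boundary
            diffs = np.abs(np.diff(np.vstack([b, b[:1]]), axis=0))
            assert diffs.max() <= 1  # consecutive points 8-adjacent, closed
            assert set(map(tuple, b)) <= c.pixel_set
            x0, y0, x1, y1 = c.bounds
            assert x0 <= c.centroid[0] <= x1 and y0 <= c.centroid[1] <= y1

    def test_hole_does_not_split_component(self):
        ring = disk_mask(12, size=40) & ~disk_mask(6, size=40)
        cs = extract_contours(ring)
        assert len(cs) == 1
        # only the outer boundary is traced
        radii = np.hypot(cs[0].boundary[:, 0] - 20, cs[0].boundary[:, 1] - 20)
        assert radii.min() > 10


class TestMoments:
    def test_production_equals_brute_force_exactly(self):
        """50 random blobs (<= 200 px): every mu_pq (p+q <= 3) identical."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            blob = random_blob(rng, max_px=200)
            got = central_moments(blob)
            want = brute_force_moments(blob)
            for p in range(4):
                for q in range(4):
                    if p + q <= 3:
                        assert got[p, q] == want[p, q]

    def test_disk_h1_matches_closed_form(self):
        # continuous disk: mu20 = mu02 = pi r^4 / 4, so h1 = 1/(2 pi)
        hu = extract_contours(disk_mask(30, size=70))[0].hu
        assert hu[0] == pytest.approx(1.0 / (2.0 * np.pi), rel=0.01)
        assert np.abs(hu[1:]).max() < 1e-4  # rotational symmetry

    def test_rotation_invariance_rectangle(self):
        a = extract_contours(rect_mask(60, 20, 0))[0].hu
        b = extract_contours(rect_mask(60, 20, 37))[0].hu
        rel = np.abs(a - b) / np.maximum(np.abs(a), 1e-12)
        assert np.all(rel[np.abs(a) > 1e-12] < 0.02)

    def test_translation_invariance(self):
        rng = np.random.default_rng(21)
        blob = random_blob(rng, max_px=150)
        shifted = blob + np.array([17, -9])
        assert hu_from_pixels(blob) == pytest.approx(hu_from_pixels(shifted), abs=1e-12)

    def test_scale_invariance_disks(self):
        a = extract_contours(disk_mask(20, size=50))[0].hu
        b = extract_contours(disk_mask(40, size=90))[0].hu
        assert abs(a[0] - b[0]) / a[0] < 0.02

    def test_agreement_with_skimage_hu(self):
        """Cross-check h1/h2 against skimage on an asymmetric blob.

        skimage uses point-mass moments while padscan models pixels as
        unit squares, so agreement is approximate on large blobs.
        """
        m = rect_mask(80, 30, 25)
        mine = extract_contours(m)[0].hu
        ref = skmeasure.moments_hu(
            skmeasure.moments_normalized(skmeasure.moments_central(m.astype(float)))
        )
        assert mine[:2] == pytest.approx(ref[:2], rel=0.02)


class TestShapeDistance:
    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            a, b = rng.normal(size=7) * 10.0 ** rng.integers(-8, 0, 7), rng.normal(size=7)
            assert shape_distance(a, a) == 0.0
            assert shape_distance(a, b) == shape_distance(b, a)

    def test_disk_vs_rectangle_separation(self):
        """Equal-area 10:1 rectangle is >= 10x farther from a disk than a
        re-rasterized (jittered-center) disk is."""
        d = extract_contours(disk_mask(30, size=70))[0]
        d2 = extract_contours(disk_mask(30, size=80, cx=34.3, cy=34.7))[0]
        # equal area to pi * 30^2
        r = extract_contours(rect_mask(168.1, 16.81, 0))[0]
        near = shape_distance(d.hu, d2.hu)
        far = shape_distance(d.hu, r.hu)
        assert far >= 10 * near

    def test_raw_variant(self):
        a = extract_contours(disk_mask(20, size=50))[0].hu
        b = extract_contours(rect_mask(60, 20, 0))[0].hu
        raw = shape_distance(a, b, log_scale=False)
        assert raw == pytest.approx(np.abs(a - b).sum())


class TestFindSimilar:
    def _disks(self):
        # three replicate disks + one equal-area 10:1 rectangle
        m = np.zeros((120, 460), dtype=bool)
        for i in range(3):
            ys, xs = np.mgrid[0:120, 0:460]
            m |= (xs - (60 + 100 * i)) ** 2 + (ys - 60) ** 2 <= 15 * 15
        ys, xs = np.mgrid[0:120, 0:460]
        # area pi*225 ~ 707 -> 10:1 rectangle 84.1 x 8.41
        m |= (np.abs(xs - 390) <= 84.1 / 2) & (np.abs(ys - 60.25) <= 8.41 / 2)
        return extract_contours(m)

    def test_selects_replicate_disks_only(self):
        cs = self._disks()
        assert len(cs) == 4
        ref = cs[1]
        rect = cs[0]  # raster order: rectangle row starts later; find it by shape
        rect = max(cs, key=lambda c: shape_distance(c.hu, ref.hu))
        half = shape_distance(ref.hu, rect.hu) / 2
        out = find_similar(cs, ref, MatchParams(size_tolerance=0.1, shape_tolerance=half))
        assert len(out) == 3 and rect not in out
        assert ref in out

    def test_zero_tolerances_keep_reference(self):
        cs = self._disks()
        out = find_similar(cs, cs[0], MatchParams(0.0, 0.0))
        assert cs[0] in out

    def test_size_gate(self):
        m = disk_mask(10, size=90, cx=20, cy=45) | disk_mask(
            np.sqrt(1.2) * 10, size=90, cx=60, cy=45
        )
        cs = extract_contours(m)
        ref = cs[0] if cs[0].area < cs[1].area else cs[1]
        out = find_similar(cs, ref, MatchParams(size_tolerance=0.1, shape_tolerance=10.0))
        assert out == [ref]

    def test_reference_must_be_member(self):
        cs = self._disks()
        with pytest.raises(UsageError):
            find_similar(cs[:2], cs[3], MatchParams())

    def test_order_preserved(self):
        cs = self._disks()
        out = find_similar(cs, cs[2], MatchParams(size_tolerance=0.2, shape_tolerance=1.0))
        assert [c.index for c in out] == sorted(c.index for c in out)


class TestPickReference:
    def _three(self):
        m = np.zeros((60, 200), dtype=bool)
        ys, xs = np.mgrid[0:60, 0:200]
        for i, r in enumerate((6, 12, 9)):
            m |= (xs - (30 + 70 * i)) ** 2 + (ys - 30) ** 2 <= r * r
        return extract_contours(m)

    def test_seed_inside(self):
        # raster order: the tallest disk (r=12, at x=100) is index 0
        cs = self._three()
        target = max(cs, key=lambda c: c.area)
        assert pick_reference(cs, (100, 30)) is target

    def test_no_seed_takes_largest(self):
        cs = self._three()
        assert pick_reference(cs) is max(cs, key=lambda c: c.area)

    def test_seed_near_centroid(self):
        cs = self._three()
        # (30, 38) lies outside the radius-6 disk centered (30, 30) but its
        # centroid is 8 px away, inside the 10 px snap window
        small = min(cs, key=lambda c: c.area)
        assert pick_reference(cs, (30, 38)) is small

    def test_seed_nowhere(self):
        cs = self._three()
        with pytest.raises(ZoneNotFoundError):
            pick_reference(cs, (180, 5))

    def test_empty_list(self):
        with pytest.raises(NoZonesError):
            pick_reference([])
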