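"""Contour extraction and the slice validity-filter chain."""

import numpy as np
import pytest
from scipy import ndimage
from shapely.geometry import Point, Polygon

from ct2skin.binarize import BinaryMask
from ct2skin.contours import (
    Contour,
    FilterConfig,
    RejectReason,
    centroid_gate,
    connect_first_row,
    equipment_region_check,
    extract_contours,
    four_direction_check,
    row_crossing_check,
    solidity_check,
    strip_connection_row,
    validate_slice,
)

CFG = FilterConfig()


def mask_from(arr) -> BinaryMask:
    arr = np.asarray(arr, dtype=bool)
    return BinaryMask(pixels=np.where(arr, 255, 0).astype(np.uint8), orientation="axial", index=0)


def disc_mask(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def ring_mask(shape, center, r_outer, r_inner):
    return disc_mask(shape, center, r_outer) & ~disc_mask(shape, center, r_inner)


class TestExtractContours:
    def test_filled_square_single_contour_with_pixel_area(self):
        arr = np.zeros((120, 120), dtype=bool)
        arr[10:110, 10:110] = True  # 100x100 filled square
        contours = extract_contours(mask_from(arr))
        assert len(contours) == 1
        assert contours[0].area_px == pytest.approx(10_000, rel=0.02)

    def test_two_disjoint_discs_two_contours(self):
        arr = disc_mask((80, 80), (25, 25), 10) | disc_mask((80, 80), (55, 55), 6)
        contours = extract_contours(mask_from(arr))
        assert len(contours) == 2
        assert contours[0].area_px > contours[1].area_px  # sorted largest first

    def test_areas_match_connected_component_pixel_counts(self):
        rng = np.random.default_rng(2)
        arr = np.zeros((90, 90), dtype=bool)
        for _ in range(5):
            r, c = rng.integers(12, 78, size=2)
            arr |= disc_mask((90, 90), (r, c), rng.integers(4, 10))
        labels, n = ndimage.label(arr, structure=np.ones((3, 3), int))
        pixel_counts = sorted(ndimage.sum_labels(arr, labels, range(1, n + 1)), reverse=True)
        contours = extract_contours(mask_from(arr))
        assert len(contours) == n
        # 0.5-level tracing puts the boundary half a pixel outside foreground
        # centres, so contour area matches the filled pixel count to a few %
        for contour, count in zip(contours, pixel_counts):
            assert contour.area_px == pytest.approx(count, rel=0.12, abs=4)

    def test_empty_mask_yields_no_contours(self):
        assert extract_contours(mask_from(np.zeros((10, 10), bool))) == []


class TestCentroidGate:
    def test_central_centroid_passes(self):
        contours = extract_contours(mask_from(disc_mask((100, 100), (50, 50), 20)))
        assert centroid_gate(contours, (100, 100), CFG) is None

    def test_bottom_slab_centroid_rejected(self):
        arr = np.zeros((100, 100), dtype=bool)
        arr[92:99, 10:90] = True  # table-like slab in the bottom 10% of rows
        contours = extract_contours(mask_from(arr))
        assert centroid_gate(contours, (100, 100), CFG) == RejectReason.CENTROID

    def test_whole_image_box_is_vacuous(self):
        arr = np.zeros((100, 100), dtype=bool)
        arr[92:99, 2:8] = True
        cfg = FilterConfig(centroid_valid_box=(0.0, 1.0, 0.0, 1.0))
        contours = extract_contours(mask_from(arr))
        assert centroid_gate(contours, (100, 100), cfg) is None


class TestConnectFirstRow:
    def test_line_drawn_between_first_and_last_white_pixels(self):
        arr = np.zeros((20, 60), dtype=bool)
        arr[5, 10] = arr[5, 50] = True
        connected, row = connect_first_row(mask_from(arr))
        assert row == 5
        assert connected.foreground[5, 10:51].all()
        assert connected.foreground.sum() == 41

    def test_all_zero_mask_unchanged(self):
        m = mask_from(np.zeros((10, 10), bool))
        connected, row = connect_first_row(m)
        assert row is None
        assert not connected.foreground.any()

    def test_growth_matches_row_scan_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            arr = rng.random((30, 40)) < 0.08
            m = mask_from(arr)
            connected, row = connect_first_row(m)
            if row is None:
                continue
            cols = np.flatnonzero(arr[row])
            expected_growth = (cols[-1] - cols[0] + 1) - len(cols)
            assert connected.foreground.sum() - arr.sum() == expected_growth
            # the edit is confined to the connection row
            diff = connected.foreground ^ arr
            assert set(np.nonzero(diff)[0]) <= {row}


class TestStripConnectionRow:
    def test_points_on_row_removed(self):
        pts = np.array([[5.0, 1], [5.0, 2], [5.0, 3], [5.0, 4], [5.0, 5],
                        [10.0, 5], [15.0, 3], [10.0, 1]])
        contour = Contour.from_points(pts)
        stripped = strip_connection_row(contour, 5)
        assert len(stripped) == 3
        assert (stripped.points[:, 0] > 5.5).all()

    def test_no_points_on_row_is_identity(self):
        contour = Contour.from_points([[10.0, 0], [10.0, 8], [20.0, 4]])
        assert strip_connection_row(contour, 2) is contour

    def test_degenerate_result_signalled(self):
        contour = Contour.from_points([[5.0, 0], [5.0, 8], [5.4, 4], [20.0, 4]])
        assert strip_connection_row(contour, 5) is None


class TestSolidity:
    def test_convex_square_has_solidity_one(self):
        # exact polygon: 300x300 square, well above the area gate
        contour = Contour.from_points([[0, 0], [0, 300], [300, 300], [300, 0]])
        assert contour.area_px == pytest.approx(90_000)
        assert solidity_check(contour, CFG) is None
        hull = contour.polygon().convex_hull.area
        assert contour.area_px / hull == pytest.approx(1.0, abs=1e-6)

    def test_large_L_shape_rejected_with_shoelace_oracle(self):
        # L = 3 of the 4 quadrants of a 600x600 square: area 3*300^2
        pts = [[0, 0], [0, 600], [300, 600], [300, 300], [600, 300], [600, 0]]
        contour = Contour.from_points(pts)

        def shoelace(p):
            p = np.asarray(p, float)
            x, y = p[:, 0], p[:, 1]
            return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

        area = shoelace(pts)
        hull_pts = [[0, 0], [0, 600], [300, 600], [600, 300], [600, 0]]
        hull_area = shoelace(hull_pts)
        assert contour.area_px == pytest.approx(area, abs=1e-9)
        solidity = area / hull_area
        assert solidity == pytest.approx(3 / 3.5, abs=1e-9)
        assert solidity < CFG.solidity_threshold
        assert solidity_check(contour, CFG) == RejectReason.SOLIDITY

    def test_small_irregular_contour_not_tested(self):
        # same L shape scaled to area 1000 px — below the gate, passes
        pts = np.array([[0, 0], [0, 36.5], [18.25, 36.5], [18.25, 18.25],
                        [36.5, 18.25], [36.5, 0]])
        contour = Contour.from_points(pts)
        assert contour.area_px < 40_000
        assert solidity_check(contour, CFG) is None


class TestFourDirection:
    @pytest.fixture
    def head(self):
        arr = disc_mask((120, 120), (60, 60), 30)
        contour = extract_contours(mask_from(arr))[0]
        return arr, contour

    def test_clean_mask_passes(self, head):
        arr, contour = head
        assert four_direction_check(mask_from(arr), contour, contour.area_px, CFG) is None

    def test_blob_on_cardinal_ray_fails(self, head):
        arr, contour = head
        arr = arr.copy()
        arr[58:63, 100:110] = True  # on the +col ray, outside the disc
        blob_center = Point(60.0, 105.0)
        assert not contour.polygon().contains(blob_center)  # outside-ness oracle
        assert (
            four_direction_check(mask_from(arr), contour, contour.area_px, CFG)
            == RejectReason.FOUR_DIRECTION
        )

    def test_diagonal_blob_passes_cardinal_blind_spot(self, head):
        """A blob off all four rays is invisible to the filter — the
        documented blind spot of cardinal-ray scanning."""
        arr, contour = head
        arr = arr.copy()
        arr[100:108, 100:108] = True  # diagonal from the centroid
        rays_rows = {int(round(contour.centroid_px[0]))}
        assert not (set(range(100, 108)) & rays_rows)
        assert four_direction_check(mask_from(arr), contour, contour.area_px, CFG) is None

    def test_not_triggered_when_area_changed(self, head):
        arr, contour = head
        arr = arr.copy()
        arr[58:63, 100:110] = True
        # previous area differs by far more than the trigger -> check skipped
        assert four_direction_check(mask_from(arr), contour, contour.area_px * 2.0, CFG) is None

    def test_first_slice_skips_check(self, head):
        arr, contour = head
        arr = arr.copy()
        arr[58:63, 100:110] = True
        assert four_direction_check(mask_from(arr), contour, None, CFG) is None


def comb_mask(shape, n_teeth, tooth_height, top=10):
    """Comb: vertical teeth rising from a base bar (classic multi-crossing shape)."""
    arr = np.zeros(shape, dtype=bool)
    base_top = top + tooth_height
    arr[base_top : base_top + 8, 8 : 8 + n_teeth * 12] = True
    for t in range(n_teeth):
        c = 8 + t * 12
        arr[top:base_top, c : c + 6] = True
    return arr


class TestRowCrossing:
    def test_convex_contour_passes(self):
        contour = extract_contours(mask_from(disc_mask((100, 100), (50, 50), 35)))[0]
        assert row_crossing_check(contour, (100, 100), CFG) is None

    def test_tall_comb_rejected(self):
        # 6 teeth spanning > 5 * row_step rows -> > bad_row_limit bad rows
        arr = comb_mask((120, 120), n_teeth=6, tooth_height=40)
        contour = extract_contours(mask_from(arr))[0]
        # oracle: count well-separated boundary pixels per scanned row
        bad = 0
        bpx = np.unique(np.round(contour.points).astype(int), axis=0)
        for r in range(0, 120, CFG.row_step):
            cols = np.sort(bpx[bpx[:, 0] == r, 1])
            if cols.size == 0:
                continue
            count, last = 1, cols[0]
            for c in cols[1:]:
                if c - last >= CFG.min_pixel_gap:
                    count += 1
                last = c
            bad += count >= CFG.crossings_per_row_trigger
        assert bad > CFG.bad_row_limit
        assert row_crossing_check(contour, (120, 120), CFG) == RejectReason.ROW_CROSSING

    def test_short_comb_passes(self):
        # teeth confined to <= bad_row_limit scanned rows
        arr = comb_mask((120, 120), n_teeth=6, tooth_height=12, top=12)
        contour = extract_contours(mask_from(arr))[0]
        assert row_crossing_check(contour, (120, 120), CFG) is None


class TestEquipmentRegion:
    def test_empty_region_list_always_passes(self):
        arr = np.ones((50, 50), dtype=bool)
        cfg = FilterConfig(equipment_regions=())
        assert equipment_region_check(mask_from(arr), cfg) is None

    def test_foreground_in_bottom_band_rejected(self):
        arr = np.zeros((100, 100), dtype=bool)
        arr[95, 50] = True
        assert equipment_region_check(mask_from(arr), CFG) == RejectReason.EQUIPMENT

    def test_head_clear_of_band_passes(self):
        arr = disc_mask((100, 100), (45, 50), 30)
        assert equipment_region_check(mask_from(arr), CFG) is None


class TestValidateSlice:
    def test_clean_ring_accepted_with_outer_boundary(self):
        arr = ring_mask((120, 120), (60, 60), 40, 30) | disc_mask((120, 120), (60, 60), 22)
        verdict = validate_slice(mask_from(arr))
        assert verdict.accepted and verdict.reason == RejectReason.OK
        # accepted contour is the outer skin boundary: radius ~40 from centre
        radii = np.linalg.norm(verdict.contour.points - np.array([60.0, 60.0]), axis=1)
        assert radii.min() > 38.5 and radii.max() < 41.5

    def test_broken_ring_recovered_by_pixel_connection(self):
        arr = ring_mask((120, 120), (60, 60), 40, 32)
        arr[:35, 55:65] = False  # carve a gap through the top of the ring
        raw_largest = extract_contours(mask_from(arr))[0]
        verdict = validate_slice(mask_from(arr))
        assert verdict.accepted
        # the re-closed contour encloses the full head; the raw broken one
        # traced the open C-shape with much smaller enclosed area
        assert verdict.contour.area_px > raw_largest.area_px * 1.5

    def test_all_air_mask_is_no_contour(self):
        verdict = validate_slice(mask_from(np.zeros((40, 40), bool)))
        assert not verdict.accepted and verdict.reason == RejectReason.NO_CONTOUR

    def test_verdicts_are_deterministic_and_nonmutating(self):
        arr = ring_mask((120, 120), (60, 60), 40, 30)
        m = mask_from(arr)
        before = m.pixels.copy()
        v1 = validate_slice(m, prev_area_px=5000.0)
        v2 = validate_slice(m, prev_area_px=5000.0)
        assert np.array_equal(m.pixels, before)  # raw data preserved
        assert v1.reason == v2.reason
        assert np.array_equal(v1.contour.points, v2.contour.points)

    def test_phantom_mid_slice_contour_matches_analytic_circle(
        self, small_sphere_spec, small_sphere_volume
    ):
        from ct2skin import binarize_slice, reslice

        spec = small_sphere_spec
        k = int(spec.head_center_mm[2])
        sl = reslice(small_sphere_volume, "axial")[k]
        verdict = validate_slice(binarize_slice(sl))
        assert verdict.accepted
        center = np.array([spec.head_center_mm[1], spec.head_center_mm[0]])  # (row, col)
        radii = np.linalg.norm(verdict.contour.points - center, axis=1)
        assert np.abs(radii - 45.0).max() < 1.0  # within 1 px of the analytic circle
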